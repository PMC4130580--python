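"""In-silico model of a plasmidome (metamobilome) isolation protocol.

The wet protocol this module emulates isolates community plasmid DNA for
sequencing in four stages: (1) bulk plasmid purification from a microbial
community whose DNA is overwhelmingly linear chromosomal fragments (gDNA)
with a small circular-plasmid fraction; (2) exonuclease digestion, which
degrades linear DNA and spares circular molecules; (3) optionally, gel
electrophoresis followed by electroelution of the upper size range, a size
selection that removes small plasmids before amplification; (4) multiple
displacement amplification (MDA) with the rolling-circle Φ29 polymerase,
followed by shearing and short single-end Illumina sequencing (~77 bp).

Each stage is a pure transformation of a :class:`MoleculePool` — a
molecule/mass ledger of circular and linear DNA species — so that the size
bias introduced by MDA (initiation is proportional to molar concentration,
which at equal mass favours small circles) and its correction by size
selection can be measured against ground truth. Reads are emitted with a
per-read truth table of source species and coordinates, which downstream
modules consume in place of an external aligner's output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import MappingRecord

logger = logging.getLogger(__name__)

__all__ = [
    "NG_PER_BASE",
    "DEFAULT_EXO_RATE_PER_HOUR",
    "DEFAULT_ELUTION_CALIBRATION",
    "PlasmidSpec",
    "CommunitySample",
    "Species",
    "MoleculePool",
    "ReadSet",
    "random_dna",
    "sample_community",
    "to_pool",
    "digest_exonuclease",
    "make_logistic_recovery",
    "electroelute",
    "amplify_mda",
    "shear_and_read",
]

#: Mass of one base pair of double-stranded DNA in nanograms (650 g/mol/bp).
NG_PER_BASE = 650.0 / 6.02214076e23 * 1e9

#: Default exonuclease decay constant: ten decades of linear-DNA removal
#: over a 48 h digestion, after which reactions are indistinguishable from
#: a non-template control.
DEFAULT_EXO_RATE_PER_HOUR = 10.0 * math.log(10.0) / 48.0

#: Measured gel-recovery calibration points (length_bp, recovery fraction)
#: for the default electroelution curve: 12.4 % at 56 kb, 0.07 % at 4.4 kb.
DEFAULT_ELUTION_CALIBRATION = ((4400, 0.0007), (56000, 0.124))

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA sequence of ``length`` bases."""
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


@dataclass
class PlasmidSpec:
    """One plasmid species in the ground-truth community.

    ``copy_number`` is plasmids per host cell; ``host_abundance`` the
    fraction of community cells carrying it (need not sum to 1 across the
    community, since hosts may carry several plasmids).
    """

    id: str
    length_bp: int
    copy_number: float = 1.0
    host_abundance: float = 1.0
    sequence: str | None = None
    is_circular: bool = True

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.id}: length must be positive")
        if self.copy_number <= 0:
            raise ValueError(f"{self.id}: copy number must be positive")
        if not 0.0 <= self.host_abundance <= 1.0:
            raise ValueError(f"{self.id}: host abundance must lie in [0, 1]")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValueError(f"{self.id}: sequence length != length_bp")


@dataclass
class CommunitySample:
    """A plasmid community plus its linear chromosomal contamination."""

    plasmids: list[PlasmidSpec]
    gdna_mass_fraction: float = 0.95
    total_dna_ng: float = 4.0

    def __post_init__(self) -> None:
        if not self.plasmids:
            raise ValueError("community must contain at least one plasmid")
        if not (math.isfinite(self.gdna_mass_fraction) and 0 <= self.gdna_mass_fraction <= 1):
            raise ValueError("gdna_mass_fraction must be a finite value in [0, 1]")
        if self.total_dna_ng <= 0:
            raise ValueError("total_dna_ng must be positive")


@dataclass
class Species:
    """One DNA species in a molecule pool."""

    id: str
    length_bp: int
    topology: str  # "circular" | "linear"
    molecules: float
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"{self.id}: zero-length species")
        if self.molecules < 0:
            raise ValueError(f"{self.id}: negative molecule count")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"{self.id}: topology must be circular or linear")

    @property
    def mass_ng(self) -> float:
        return self.molecules * self.length_bp * NG_PER_BASE


@dataclass
class MoleculePool:
    """Mass/molecule bookkeeping of DNA species between protocol stages."""

    species: list[Species]
    stage_label: str = ""

    @property
    def total_mass_ng(self) -> float:
        return sum(s.mass_ng for s in self.species)

    def get(self, species_id: str) -> Species:
        for s in self.species:
            if s.id == species_id:
                return s
        raise KeyError(species_id)

    def mass_fractions(self) -> dict[str, float]:
        total = self.total_mass_ng
        return {s.id: (s.mass_ng / total if total > 0 else 0.0) for s in self.species}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.id, s.length_bp, s.topology, s.molecules, s.mass_ng, self.stage_label)
             for s in self.species],
            columns=["species_id", "length_bp", "topology", "molecules", "mass_ng", "stage"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ReadSet:
    """Simulated single-end reads with per-read ground truth."""

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    truth: list[MappingRecord]
    library_label: str = ""

    def __post_init__(self) -> None:
        if len(self.reads) != len(self.truth):
            raise ValueError("each read must have exactly one truth record")

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for read_id, seq, qual in self.reads:
                fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        from .coverage import write_mappings_tsv

        write_mappings_tsv(self.truth, path)


# ---------------------------------------------------------------------------
# Community construction


def sample_community(
    n_plasmids: int,
    size_range_bp: tuple[int, int] = (1000, 100_000),
    size_distribution: str = "log_uniform",
    copy_number_model: str = "log_uniform_anticorrelated",
    gdna_mass_fraction: float = 0.95,
    total_dna_ng: float = 4.0,
    seed: int = 0,
    sizes: Sequence[int] | None = None,
    copy_numbers: Sequence[float] | None = None,
    motifs: Mapping[int, str] | None = None,
) -> CommunitySample:
    """Draw a synthetic plasmid community with sequences and copy numbers.

    Plasmid sizes span ``size_range_bp`` (default 1–100 kb, log-uniform, the
    natural span of small cloning-vector-like through large conjugative
    plasmids); copy numbers default to log-uniform in 1–20 and
    anti-correlated with size, mirroring the empirical pattern that small
    ColE1-type plasmids replicate at 15–20 copies per cell while large
    conjugative plasmids are maintained at 4–7. Explicit ``sizes`` /
    ``copy_numbers`` override the draws (e.g. the 4.4 kb / 56 kb two-plasmid
    model mixture). ``motifs`` embeds a marker subsequence (such as a gfp
    gene) into selected plasmids by index. Deterministic given ``seed``.
    """
    if n_plasmids < 1:
        raise ValueError("n_plasmids must be >= 1")
    lo, hi = size_range_bp
    if sizes is None:
        if lo < 1000:
            raise ValueError("minimum plasmid size must be >= 1000 bp")
        if hi <= lo:
            raise ValueError("empty size range")
    if not (math.isfinite(gdna_mass_fraction) and 0 <= gdna_mass_fraction <= 1):
        raise ValueError("gdna_mass_fraction must be a finite value in [0, 1]")

    rng = np.random.default_rng(seed)
    if sizes is not None:
        if len(sizes) != n_plasmids:
            raise ValueError("sizes must have n_plasmids entries")
        lengths = [int(s) for s in sizes]
    elif size_distribution == "log_uniform":
        lengths = np.exp(rng.uniform(math.log(lo), math.log(hi), n_plasmids))
        lengths = [int(round(x)) for x in lengths]
    elif size_distribution == "uniform":
        lengths = [int(x) for x in rng.integers(lo, hi + 1, n_plasmids)]
    else:
        raise ValueError(f"unknown size distribution: {size_distribution!r}")

    if copy_numbers is not None:
        if len(copy_numbers) != n_plasmids:
            raise ValueError("copy_numbers must have n_plasmids entries")
        cns = [float(c) for c in copy_numbers]
    elif copy_number_model == "log_uniform_anticorrelated":
        # log-uniform 1-20, anti-correlated with log-size plus jitter
        log_lo = math.log(max(min(lengths), 1000))
        log_hi = math.log(max(max(lengths), min(lengths) + 1))
        span = max(log_hi - log_lo, 1e-9)
        t = (np.log(lengths) - log_lo) / span
        noise = rng.uniform(-0.5, 0.5, n_plasmids)
        cns = np.exp(np.clip((1.0 - t) * math.log(20.0) + noise, 0.0, math.log(20.0)))
        cns = [float(c) for c in cns]
    elif copy_number_model == "log_uniform":
        cns = [float(c) for c in np.exp(rng.uniform(0.0, math.log(20.0), n_plasmids))]
    else:
        raise ValueError(f"unknown copy number model: {copy_number_model!r}")

    abundances = np.power(10.0, rng.uniform(-3.0, -1.0, n_plasmids))
    plasmids = []
    for i, (length, cn) in enumerate(zip(lengths, cns)):
        seq = random_dna(length, rng)
        if motifs and i in motifs:
            motif = motifs[i].upper()
            if len(motif) > length:
                raise ValueError(f"motif longer than plasmid {i}")
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        plasmids.append(
            PlasmidSpec(
                id=f"plasmid_{i:03d}",
                length_bp=length,
                copy_number=cn,
                host_abundance=float(abundances[i]),
                sequence=seq,
            )
        )
    return CommunitySample(plasmids, gdna_mass_fraction, total_dna_ng)


def to_pool(
    community: CommunitySample,
    volume_uL: float = 20.0,
    conc_ng_per_uL: float = 0.2,
    mass_split: str = "equal",
    gdna_fragment_bp: int = 10_000,
    seed: int = 0,
) -> MoleculePool:
    """Convert a community into a molecule pool at a given DNA concentration.

    Total pool mass is ``volume_uL × conc_ng_per_uL`` (default 20 µL at
    0.2 ng/µL, the digestion input concentration). The plasmid share of the
    mass (1 − gdna fraction) is divided equally per plasmid by default —
    matching 1:1 mixing by mass — or proportional to copy_number × length ×
    host_abundance under ``mass_split="abundance"``. gDNA enters as one
    linear species of sheared ~10 kb fragments. Mass is conserved:
    molecules_i = mass_i / (length_i × mass-per-base).
    """
    if volume_uL <= 0 or conc_ng_per_uL <= 0:
        raise ValueError("volume and concentration must be positive")
    total_ng = volume_uL * conc_ng_per_uL
    gdna_ng = total_ng * community.gdna_mass_fraction
    plasmid_ng = total_ng - gdna_ng

    n = len(community.plasmids)
    if mass_split == "equal":
        weights = [1.0] * n
    elif mass_split == "abundance":
        weights = [p.copy_number * p.length_bp * p.host_abundance for p in community.plasmids]
    else:
        raise ValueError(f"unknown mass split: {mass_split!r}")
    wsum = sum(weights)
    if wsum <= 0:
        raise ValueError("mass split weights are all zero")

    species = []
    for p, w in zip(community.plasmids, weights):
        mass = plasmid_ng * w / wsum
        species.append(
            Species(
                id=p.id,
                length_bp=p.length_bp,
                topology="circular" if p.is_circular else "linear",
                molecules=mass / (p.length_bp * NG_PER_BASE),
                sequence=p.sequence,
            )
        )
    if gdna_ng > 0:
        rng = np.random.default_rng(seed)
        species.append(
            Species(
                id="gdna",
                length_bp=gdna_fragment_bp,
                topology="linear",
                molecules=gdna_ng / (gdna_fragment_bp * NG_PER_BASE),
                sequence=random_dna(gdna_fragment_bp, rng),
            )
        )
    return MoleculePool(species, stage_label="input")


# ---------------------------------------------------------------------------
# Protocol stages


def digest_exonuclease(
    pool: MoleculePool,
    hours: float = 48.0,
    decay_rate_per_hour: float = DEFAULT_EXO_RATE_PER_HOUR,
    detection_limit_molecules: float = 1.0,
) -> tuple[MoleculePool, pd.DataFrame]:
    """Exonuclease digestion: linear DNA decays, circular DNA is untouched.

    Linear species decay exponentially, count(t) = count(0)·exp(−rate·t);
    the default rate removes ten decades of linear DNA over 48 h, at which
    point a reaction is indistinguishable from a non-template control.
    Returns the digested pool and a monitor table sampled every 12 h (the
    in-silico analogue of tracking residual gDNA by 16S qPCR) with the
    remaining linear molecule count and whether it is below the detection
    limit.
    """
    if hours < 0:
        raise ValueError("hours must be non-negative")
    if decay_rate_per_hour <= 0:
        raise ValueError("decay rate must be positive")

    def linear_total(t: float) -> float:
        return sum(
            s.molecules * math.exp(-decay_rate_per_hour * t)
            for s in pool.species
            if s.topology == "linear"
        )

    times = [float(t) for t in np.arange(0.0, hours + 1e-9, 12.0)]
    if not times or times[-1] < hours:
        times.append(hours)
    monitor = pd.DataFrame(
        {
            "hours": times,
            "linear_molecules": [linear_total(t) for t in times],
        }
    )
    monitor["below_detection"] = monitor["linear_molecules"] < detection_limit_molecules

    out = []
    for s in pool.species:
        factor = math.exp(-decay_rate_per_hour * hours) if s.topology == "linear" else 1.0
        out.append(Species(s.id, s.length_bp, s.topology, s.molecules * factor, s.sequence))
    return MoleculePool(out, stage_label="digested"), monitor


def make_logistic_recovery(
    calibration: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_ELUTION_CALIBRATION,
) -> Callable[[float], float]:
    """Two-parameter logistic recovery curve, logit-linear in log length.

    Fit through two (length, recovery) calibration points; the default
    reproduces the measured electroelution recoveries of the 4.4 kb and
    56 kb model plasmids (0.07 % and 12.4 %).
    """
    (l1, r1), (l2, r2) = calibration
    if not (0 < r1 < 1 and 0 < r2 < 1):
        raise ValueError("calibration recoveries must lie strictly in (0, 1)")
    if l1 <= 0 or l2 <= 0 or l1 == l2:
        raise ValueError("calibration lengths must be positive and distinct")

    def logit(p: float) -> float:
        return math.log(p / (1.0 - p))

    slope = (logit(r2) - logit(r1)) / (math.log(l2) - math.log(l1))
    intercept = logit(r1) - slope * math.log(l1)

    def recovery(length_bp: float) -> float:
        return 1.0 / (1.0 + math.exp(-(intercept + slope * math.log(length_bp))))

    return recovery


def electroelute(
    pool: MoleculePool,
    recovery_curve: Callable[[float], float] | None = None,
    carryover: float = 0.0,
) -> MoleculePool:
    """Gel size selection by electroelution of the upper size range.

    Each species retains ``recovery(length) + carryover`` of its molecules
    (capped at 1, so mass never increases). ``carryover`` models the
    length-independent cross-contamination that gel electroelution is
    vulnerable to; it defaults to 0.
    """
    if not 0.0 <= carryover <= 1.0:
        raise ValueError("carryover must lie in [0, 1]")
    curve = recovery_curve if recovery_curve is not None else make_logistic_recovery()
    out = []
    for s in pool.species:
        r = curve(s.length_bp)
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"recovery {r} outside [0, 1] for {s.id}")
        frac = min(1.0, r + carryover)
        out.append(Species(s.id, s.length_bp, s.topology, s.molecules * frac, s.sequence))
    return MoleculePool(out, stage_label="eluate")


def amplify_mda(
    pool: MoleculePool,
    dntp_budget_bases: float,
    processivity_bp: int = 70_000,
    hours: float = 7.0,
    background_onset_hours: float = 9.0,
    mode: str = "deterministic",
    seed: int = 0,
    efficiency: Mapping[str, float] | None = None,
) -> MoleculePool:
    """Φ29 rolling-circle amplification with molar-concentration allocation.

    Initiation events land on circular templates with probability
    proportional to their molar concentration (molecule count, optionally
    scaled by a per-species ``efficiency`` multiplier), and each initiation
    synthesizes ``processivity_bp`` bases — i.e. ``processivity_bp/L``
    tandem copies of a length-L template. The polymerase re-initiates until
    the dNTP budget is exhausted, so at equal input mass a small circle
    (more molecules) draws proportionally more synthesis: two equal-mass
    species of lengths L1 < L2 gain mass in ratio L2/L1. Linear species are
    carried through without amplification. Incubations reaching
    ``background_onset_hours`` divert the post-onset share of synthesis,
    ``(hours − onset)/hours``, into a template-independent "background"
    species (the default 7 h incubation stays below the 9 h onset).
    Total synthesized bases never exceed the budget; in stochastic mode the
    initiations are multinomial draws given ``seed`` and their expectation
    equals the deterministic allocation.
    """
    if dntp_budget_bases < 0:
        raise ValueError("dNTP budget must be non-negative")
    if hours < 0:
        raise ValueError("hours must be non-negative")
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode: {mode!r}")
    eff = efficiency or {}

    out = [Species(s.id, s.length_bp, s.topology, s.molecules, s.sequence)
           for s in pool.species]
    if dntp_budget_bases == 0 or hours == 0:
        return MoleculePool(out, stage_label="amplified")

    circ = [s for s in out if s.topology == "circular" and s.molecules > 0]
    bg_share = max(0.0, (hours - background_onset_hours) / hours)
    template_budget = dntp_budget_bases * (1.0 - bg_share)
    bg_budget = dntp_budget_bases * bg_share

    if not circ:
        if bg_budget == 0:
            logger.warning(
                "amplify_mda: no amplifiable circular template in stage %r; "
                "returning pool unchanged", pool.stage_label,
            )
            return MoleculePool(out, stage_label="amplified")
        template_budget, bg_budget = 0.0, dntp_budget_bases

    if circ and template_budget > 0:
        weights = np.array([s.molecules * eff.get(s.id, 1.0) for s in circ], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("all circular species have zero initiation weight")
        probs = weights / weights.sum()
        if mode == "deterministic":
            synth = template_budget * probs
        else:
            rng = np.random.default_rng(seed)
            n_initiations = int(template_budget // processivity_bp)
            draws = rng.multinomial(n_initiations, probs)
            synth = draws.astype(float) * processivity_bp
        for s, bases in zip(circ, synth):
            s.molecules += bases / s.length_bp

    if bg_budget > 0:
        rng_bg = np.random.default_rng(seed)
        out.append(
            Species(
                id="background",
                length_bp=processivity_bp,
                topology="linear",
                molecules=bg_budget / processivity_bp,
                sequence=random_dna(processivity_bp, rng_bg),
            )
        )
    return MoleculePool(out, stage_label="amplified")


def shear_and_read(
    pool: MoleculePool,
    n_reads: int,
    read_length_bp: int = 77,
    seed: int = 0,
    library_label: str = "lib",
    quality_char: str = "I",
) -> ReadSet:
    """Shear the pool and sequence short single-end reads with ground truth.

    Reads are drawn from species with probability proportional to mass;
    start positions are uniform. Reads running off the end of a circular
    species wrap the origin and are recorded as one truth record with
    ``end0 > length`` (normalised downstream); linear species shorter than
    the read length are rejected as sources. Coordinates are 0-based
    half-open on the forward strand; minus-strand reads carry the reverse
    complement. Byte-identical output for identical seeds.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if read_length_bp < 1:
        raise ValueError("read length must be >= 1")

    eligible = [
        s for s in pool.species
        if s.sequence is not None and s.mass_ng > 0
        and (s.topology == "circular" or s.length_bp >= read_length_bp)
    ]
    if not eligible:
        raise ValueError("no species with sequence and sufficient length to read from")
    masses = np.array([s.mass_ng for s in eligible], dtype=float)
    probs = masses / masses.sum()

    rng = np.random.default_rng(seed)
    choices = rng.choice(len(eligible), size=n_reads, p=probs)
    strands = rng.choice(np.array(["+", "-"]), size=n_reads)

    reads: list[tuple[str, str, str]] = []
    truth: list[MappingRecord] = []
    qual = quality_char * read_length_bp
    for i, (idx, strand) in enumerate(zip(choices, strands)):
        sp = eligible[idx]
        L = sp.length_bp
        if sp.topology == "circular":
            start = int(rng.integers(0, L))
            end = start + read_length_bp
            if end <= L:
                seq = sp.sequence[start:end]
            else:
                wrap = end - L
                seq = sp.sequence[start:] + (sp.sequence * (1 + wrap // L))[:wrap]
        else:
            start = int(rng.integers(0, L - read_length_bp + 1))
            end = start + read_length_bp
            seq = sp.sequence[start:end]
        if strand == "-":
            seq = reverse_complement(seq)
        read_id = f"{library_label}_r{i:07d}"
        reads.append((read_id, seq, qual))
        truth.append(
            MappingRecord(read_id=read_id, ref_id=sp.id, start0=start, end0=end,
                          library_label=library_label, strand=str(strand))
        )
    return ReadSet(reads, truth, library_label)
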