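# Methods

## Scope and intent

`plaskew` models the computational content of a plasmidome (metamobilome)
isolation protocol so the size bias of multiple displacement amplification
(MDA), and its correction by gel size selection, can be quantified without
wet-lab work or external data. The package has two halves: a protocol
simulator (`simulate`) that tracks DNA species as molecule/mass ledgers
through digestion, electroelution, amplification, and read generation; and
the downstream analyses (`ampmodel`, `coverage`, `skew`, `summarize`) that
operate on alignments — either the simulator's ground-truth mappings or
user-supplied SAM files from a real experiment.

## The amplification model

Rolling-circle amplification by the Φ29 polymerase is modelled as
initiation-limited synthesis with a processivity cap:

- Each initiation on a circular template of length `L` synthesizes
  `P` = 70,000 bases of tandem concatemer, i.e. `P/L` template copies.
  Copies per initiation are kept as a real number (no flooring), so
  `P`=70 kb on a 3.5 kb circle gives exactly 20 copies.
- Initiations land on circular species in proportion to molar
  concentration (molecule count), optionally scaled by a per-species
  efficiency multiplier. The polymerase re-initiates until the dNTP budget
  is exhausted, so the **entire budget is consumed** whenever an
  amplifiable template exists and total synthesized bases equal
  `min(budget, synthesis)` exactly.
- Linear species are carried through without amplification; incubations
  past the background-onset time (default 9 h; default incubation 7 h)
  divert the post-onset share of synthesis, `(hours − onset)/hours`, into
  a template-independent "background" species, mirroring the observation
  that non-template products appear only in over-long incubations.

This is deliberately *not* a branching/hyperbranching kinetic model. The
single mechanism — molar-proportional allocation of a fixed synthesis
budget — reproduces the analytic facts the protocol turns on: equal fold
amplification of any template amplified alone with the same input mass and
budget; and, in an equal-mass mixture of lengths `L₁ < L₂`, synthesized
mass splitting `L₂/L₁` in favour of the small circle (12.7× for the
4.4/56 kb pair). The *measured* mixed-reaction advantage of that pair is
34 (±4)×, larger than the molar prediction; no parameter here is tuned to
reproduce 34, and the gap (plausibly compounded re-initiation on already
amplified product) is exposed only through the per-species efficiency
multiplier for users who wish to fit it. The closed-form composition
calculators in `ampmodel` take measured folds as inputs, so the 34-fold
figure enters there as data, not as model output.

In stochastic mode the initiation count `⌊budget/P⌋` is allocated
multinomially with the same probabilities; its expectation equals the
deterministic allocation (verified over 100 seeds in the tests).

## Other protocol stages

- **Exonuclease digestion**: linear species decay as
  `N(t) = N(0)·exp(−kt)`; circular species are invariant. Default
  `k = 10·ln10/48 ≈ 0.48 h⁻¹`, chosen so a 48 h digestion removes ten
  decades of linear DNA — enough to push any realistic gDNA load below
  single-molecule detection, matching the criterion that digested
  reactions become indistinguishable from a no-template control. The
  returned monitor table samples remaining linear molecules every 12 h, an
  in-silico stand-in for 16S qPCR monitoring. The reported 62–80 %
  total-DNA removal during digestion is not targeted: it depends on the
  unknown initial linear/circular mass split of the real samples.
- **Electroelution**: per-species recovery `r(L) + carryover`, capped at
  1. `r(L)` is a logistic in log-length through the two measured
  calibration points (0.07 % at 4.4 kb, 12.4 % at 56 kb); both points are
  user-overridable, and `carryover` (default 0) models the
  length-independent cross-contamination the gel step is vulnerable to.
- **gDNA** is one linear species of 10 kb sheared fragments (mass share
  0.95 of community DNA by default, reflecting that plasmids are a
  negligible fraction of total community DNA). Fragment length only sets
  molecule counts; gDNA is removed by digestion before it matters
  downstream.
- **Reads**: single-end 77 bp (the read length of the HiSeq libraries this
  tooling is patterned on), drawn from species by mass, uniform start
  positions, uniform high quality. Reads off the end of a circular species
  wrap the origin and are recorded as one truth record with
  `end0 > length`; the coverage module splits such records at the origin.
  Mass-per-base uses 650 g/mol per bp of dsDNA.

## Analysis conventions

- **Coverage**: depth by difference-array accumulation (exact, verified
  against per-position counting on ≤10 kb references). Two depth means are
  emitted — over covered positions only and over the whole reference —
  because published coverage tables do not always say which convention
  they use; per-10-million-read normalisation uses the whole-reference
  mean. Duplicate read placements count toward depth (MDA output is
  inherently duplicated; no dedup step exists in the protocol).
  Secondary/supplementary SAM alignments are ignored by default.
- **Recovery classification**: partial requires, within a single library,
  ≥1,500 covered bases (inclusive), breadth ≥10 % (inclusive), and mean
  depth over covered positions strictly >1×; near-complete additionally
  requires breadth ≥85 %. The covered-bases floor exists to screen out
  references recruited only via shared repeats. Boundary semantics are
  configurable.
- **LS-skew**: implemented as `nb_L/(nb_L + c·nb_S)`. The placement of `c`
  is a convention: this form anchors the endpoints (0 = all S, 1 = all L)
  and, with `c = bases(L)/bases(S) ≈ 0.95`, down-weights the slightly
  larger S library, which is the constant's stated purpose. The mirrored
  form merely replaces `c` by `1/c`; `c` is a free parameter and the swap
  duality `skew(S↔L, c→1/c) = 1 − skew` is property-tested. Alignment
  segments are clipped to the entity span when counting `nb`
  (configurable); genes use their own span, contigs theirs. Entities with
  no mapped bases in either library get a *missing* skew, never 0 or 1.
  Exclusivity thresholds are strict (<0.05, >0.95); the boundary values
  count as shared.
- **Quartiles**: linear interpolation between order statistics (numpy
  `method="linear"`, type 7), configurable — the convention matters only
  for comparability, and is therefore explicit.
- **Replicons**: a gene carrying ≥1 replication-initiator Pfam domain
  (default set: Rep_1, Rep_2, Rep_3, Rep_trans, RHH_1, RepL, RepC, RPA,
  TrfA, Replicase) counts once, and no correction for multi-replicon
  plasmids is applied, keeping the count an "at least" estimate and the
  derived average plasmid size an upper bound.
- **Circularity**: longest exact, case-insensitive terminal overlap in
  [14, 100] bp, verified against an all-k scan. Homopolymeric or otherwise
  degenerate termini force a hit at the maximum; output is labelled
  putative — no read-pair or PCR-style confirmation is modelled.

## What the simulator does and does not emulate

The generator reproduces the *mechanisms* that drive the protocol's size
bias: molar-vs-mass composition, topology-selective digestion,
length-selective recovery, molar-proportional amplification, and
mass-proportional read sampling. It does not emulate chimera formation,
strand-displacement branching structure, polymerase error, quality-score
realism, GC or motif-dependent initiation, assembly, or a realistic
taxonomic background. Passing tests therefore demonstrate that the
analyses recover the engineered size-selection signal under the modelled
mechanisms — not that they are robust to artifacts (chimeras, repeats,
mosaicism) that real MDA libraries contain.

One consequence of the deterministic recovery curve is worth spelling out:
because every species retains a strictly positive recovery, exclusivity in
the simulated data is a matter of *relative* depletion, and a plasmid pair
is simultaneously S- and L-exclusive (skew <0.05 and >0.95 at c≈1) only
when their recovery fractions differ by more than ~19² ≈ 361×. The
4.4/56 kb model pair spans only ~177×, which is precisely why the real
4.4 kb vector remained visibly present in real size-selected libraries.
The end-to-end tests therefore place the community modes at 1.2–2.5 kb and
55–90 kb — small cryptic plasmids against conjugative plasmids — where the
calibrated curve spans ~10³ and both exclusive fractions are non-empty.

## Problem sizes and defaults

Demo and test runs use communities of 2–50 plasmids, 5,000–20,000 reads
per library, and a dNTP budget of 2×10¹⁴ bases (~216 ng of synthesis from
4 ng of template, matching the 200–500 ng yields typical of the kit
protocol). These sizes were chosen because every bias statement the
package makes is already exact or statistically decisive at this scale;
all generators are linear in reads and reference length, so users can
scale up freely. All randomness flows from a single integer seed per
operation (pipeline stages derive per-stage seeds from the run seed);
identical seeds give byte-identical FASTA/FASTQ/TSV output.

## Known limitations

- The 34-fold measured mixed-reaction advantage is an input, never a
  prediction (see above).
- The logistic recovery curve is calibrated on two points; its shape
  between and beyond them is an assumption.
- Background (template-independent) synthesis is a single lumped species
  with a linear-in-time onset model; real onset kinetics are nonlinear.
- SAM ingestion trusts the aligner's primary-alignment choice; multimapped
  reads are not reassigned.
- The CLI `summarize` replicon table treats each annotated gene
  independently; it does not parse gene coordinates back to contigs for
  per-fraction length sums when the skew table lacks them.
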