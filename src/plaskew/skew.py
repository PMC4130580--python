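"""The LS-skew statistic: two-library contribution skew per entity.

When the same community is sequenced through two isolation protocols — a
standard plasmidome prep (the S library) and a size-selected prep targeting
upper size range plasmids (the L library) — the relative contribution of
each library to a reference, contig, or gene is summarised by

    LS_skew = nb_L / (nb_L + c * nb_S)

where nb is the number of bases mapped between the first and last bases of
the entity from each library and c corrects for the small difference in
library sizes (c = total bases in L / total bases in S, ~0.95 for the
libraries this statistic was designed around). A skew of 0 means all mapped
bases came from S, 1 means all came from L. Entities with skew < 0.05 are
called S-exclusive and > 0.95 L-exclusive; the boundaries themselves count
as shared.

Gene-level skews can be aggregated into per-Pfam-cluster skews, weighting
each gene by its coverage, to compare the library affiliation of protein
families (e.g. plasmid-selfish replication and conjugation domains versus
cargo functions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coverage import MappingRecord

__all__ = [
    "DEFAULT_C",
    "REPLICATION_PFAMS",
    "DEFAULT_SELFISH_PFAMS",
    "SKEW_CATEGORIES",
    "GeneRecord",
    "PfamClusterSkew",
    "mapped_bases_in_span",
    "compute_c",
    "ls_skew",
    "categorize_skew",
    "filter_genes_by_coverage",
    "weighted_pfam_skew",
    "skew_table",
]

#: Library-size correction constant for the reference S/L library pair.
DEFAULT_C = 0.95

SKEW_CATEGORIES = ("S_exclusive", "shared", "L_exclusive")

#: Pfam domains marking replication initiator proteins of circular
#: replicons; counting genes that carry at least one of these estimates the
#: number of distinct plasmid replicons in an assembly.
REPLICATION_PFAMS = frozenset({
    "Rep_1", "Rep_2", "Rep_3", "Rep_trans", "RHH_1", "RepL", "RepC",
    "RPA", "TrfA", "Replicase",
})

#: Default plasmid-selfish Pfam set: replication initiators, mobilisation
#: (MOB-type relaxases), toxin-antitoxin stability systems, partitioning,
#: and conjugative mate-pair formation / coupling domains. User-overridable.
DEFAULT_SELFISH_PFAMS = REPLICATION_PFAMS | frozenset({
    "MobA_MobL", "Mob_Pre", "Relaxase", "MobC",
    "RelB", "Plasmid_Txe", "CcdA", "CcdB",
    "CbiA", "ParBc",
    "T4SS-DNA_transf", "TraG-D_C", "AAA_10", "TrwB_AAD_bind",
})


@dataclass
class GeneRecord:
    """A predicted gene on a contig, with coverage and Pfam annotations.

    ``pfam_domains`` holds (pfam_id, class) pairs where class is "selfish"
    or "non_selfish".
    """

    gene_id: str
    contig_id: str
    start0: int
    end0: int
    coverage: float = 0.0
    pfam_domains: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if self.end0 <= self.start0:
            raise ValueError(f"{self.gene_id}: empty gene span")
        if self.coverage < 0:
            raise ValueError(f"{self.gene_id}: negative coverage")
        if self.pfam_domains is None:
            self.pfam_domains = []

    @property
    def pfam_ids(self) -> set[str]:
        return {p for p, _ in self.pfam_domains}


@dataclass(frozen=True)
class PfamClusterSkew:
    """Coverage-weighted skew of all genes carrying one Pfam domain."""

    pfam_id: str
    n_genes: int
    weighted_skew: float
    mean_gene_coverage: float
    pfam_class: str = "non_selfish"


def mapped_bases_in_span(
    mappings: Iterable[MappingRecord],
    entity: tuple[str, int, int],
    library_label: str | None = None,
    clip: bool = True,
) -> float:
    """Bases mapped between the first and last base of an entity span.

    Sums, over mapping records on the entity's reference (optionally
    restricted to one library), the length of each aligned segment's
    intersection with the half-open span. With ``clip=False`` a record
    merely touching the span contributes its full aligned length.
    """
    ref_id, start0, end0 = entity
    if end0 <= start0:
        raise ValueError("entity span is empty")
    total = 0
    for rec in mappings:
        if rec.ref_id != ref_id:
            continue
        if library_label is not None and rec.library_label != library_label:
            continue
        overlap = min(rec.end0, end0) - max(rec.start0, start0)
        if overlap > 0:
            total += overlap if clip else rec.span
    return float(total)


def compute_c(total_bases_L: float, total_bases_S: float) -> float:
    """Library-size correction constant c = bases(L) / bases(S).

    With c multiplying the S-library base count, a slightly larger S
    library (c < 1) is down-weighted so neither protocol is favoured simply
    by sequencing depth.
    """
    if total_bases_L <= 0 or total_bases_S <= 0:
        raise ValueError("library base totals must be positive")
    return total_bases_L / total_bases_S


def ls_skew(nb_L: float, nb_S: float, c: float = DEFAULT_C) -> float | None:
    """LS-skew = nb_L / (nb_L + c·nb_S); None when no bases map at all.

    0 means every mapped base came from the S library, 1 means every mapped
    base came from the L library.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    if nb_L < 0 or nb_S < 0:
        raise ValueError("mapped base counts must be non-negative")
    if nb_L == 0 and nb_S == 0:
        return None
    return nb_L / (nb_L + c * nb_S)


def categorize_skew(skew: float, lo: float = 0.05, hi: float = 0.95) -> str:
    """Exclusivity category: strict thresholds, boundaries count as shared."""
    if not 0.0 <= skew <= 1.0 or not math.isfinite(skew):
        raise ValueError(f"skew {skew} outside [0, 1]")
    if skew < lo:
        return "S_exclusive"
    if skew > hi:
        return "L_exclusive"
    return "shared"


def filter_genes_by_coverage(
    genes: Iterable[GeneRecord], min_coverage: float = 1.0
) -> list[GeneRecord]:
    """Keep genes whose coverage strictly exceeds ``min_coverage`` (>1×)."""
    return [g for g in genes if g.coverage > min_coverage]


def weighted_pfam_skew(
    genes_with_skew: Sequence[tuple[GeneRecord, float]],
    pfam_classes: Mapping[str, str] | None = None,
) -> list[PfamClusterSkew]:
    """Coverage-weighted mean skew per Pfam cluster.

    For each Pfam, weighted_skew = Σ cov_g·skew_g / Σ cov_g over member
    genes; a gene carrying domains of k distinct Pfams contributes to all k
    clusters (once each). ``pfam_classes`` maps pfam_id → class, defaulting
    to membership of :data:`DEFAULT_SELFISH_PFAMS`.
    """
    clusters: dict[str, list[tuple[float, float]]] = {}
    for gene, skew in genes_with_skew:
        if skew is None or not math.isfinite(skew):
            raise ValueError(f"{gene.gene_id}: undefined skew")
        for pfam_id in sorted(gene.pfam_ids):
            clusters.setdefault(pfam_id, []).append((gene.coverage, skew))
    out = []
    for pfam_id, members in sorted(clusters.items()):
        total_w = sum(w for w, _ in members)
        if total_w <= 0:
            raise ValueError(f"Pfam cluster {pfam_id} has zero total coverage weight")
        wskew = sum(w * s for w, s in members) / total_w
        if pfam_classes is not None:
            cls = pfam_classes.get(pfam_id, "non_selfish")
        else:
            cls = "selfish" if pfam_id in DEFAULT_SELFISH_PFAMS else "non_selfish"
        out.append(
            PfamClusterSkew(
                pfam_id=pfam_id,
                n_genes=len(members),
                weighted_skew=wskew,
                mean_gene_coverage=total_w / len(members),
                pfam_class=cls,
            )
        )
    return out


def skew_table(
    mappings_S: Sequence[MappingRecord],
    mappings_L: Sequence[MappingRecord],
    entities: Sequence[tuple[str, int, int]] | Mapping[str, int],
    c: float | str = "auto",
    lo: float = 0.05,
    hi: float = 0.95,
) -> pd.DataFrame:
    """Per-entity skew table from two libraries' mappings.

    ``entities`` is either (ref_id, start0, end0) spans or a mapping
    ref_id → length (whole-reference entities). With ``c="auto"`` the
    correction constant is computed from the total mapped bases of the two
    libraries. Entities with no mapped bases get a missing skew and
    category.
    """
    if isinstance(entities, Mapping):
        spans = [(ref, 0, length) for ref, length in entities.items()]
    else:
        spans = list(entities)
    if c == "auto":
        total_L = sum(r.span for r in mappings_L)
        total_S = sum(r.span for r in mappings_S)
        c_val = compute_c(total_L, total_S) if total_L > 0 and total_S > 0 else 1.0
    else:
        c_val = float(c)

    rows = []
    for ref_id, start0, end0 in spans:
        nb_S = mapped_bases_in_span(mappings_S, (ref_id, start0, end0))
        nb_L = mapped_bases_in_span(mappings_L, (ref_id, start0, end0))
        skew = ls_skew(nb_L, nb_S, c_val)
        cat = categorize_skew(skew, lo, hi) if skew is not None else None
        rows.append((ref_id, start0, end0, nb_S, nb_L, c_val, skew, cat))
    return pd.DataFrame(
        rows,
        columns=["entity_id", "start0", "end0", "nb_S", "nb_L", "c", "skew", "category"],
    )
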