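"""Fraction-level summaries of plasmid size and replicon content.

Once entities (recovered reference plasmids or assembled contigs) carry an
exclusivity category from the two-library skew analysis, this module
summarises each fraction: size quartiles per category, replicon counts from
replication-initiator Pfam domains, the resulting upper bound on average
plasmid size (total fraction length / replicon count, under the assumption
that most plasmids carry a single replication gene), and putative
circularity from exact terminal overlaps of contig ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .skew import GeneRecord, REPLICATION_PFAMS, SKEW_CATEGORIES

__all__ = [
    "FractionSummary",
    "fraction_size_summary",
    "estimate_replicons",
    "max_average_plasmid_size",
    "detect_terminal_overlap",
]


@dataclass(frozen=True)
class FractionSummary:
    """Size summary of one exclusivity fraction (or the whole set)."""

    fraction: str
    n: int
    median_kbp: float | None
    q1_kbp: float | None
    q3_kbp: float | None
    total_contig_length_bp: int
    replicon_count: int | None = None
    max_avg_plasmid_size_kbp: float | None = None


def fraction_size_summary(
    entities: Iterable[tuple[str, int, str]],
    quartile_method: str = "linear",
) -> list[FractionSummary]:
    """Median and quartile sizes (kb) per exclusivity fraction plus overall.

    ``entities`` yields (entity_id, length_bp, category) with category in
    S_exclusive / shared / L_exclusive. Quartiles use linear interpolation
    between order statistics by default (numpy's ``method="linear"``,
    type-7); pass any numpy percentile method to change the convention.
    Empty fractions report n=0 with missing quartiles.
    """
    by_cat: dict[str, list[int]] = {cat: [] for cat in SKEW_CATEGORIES}
    all_lengths: list[int] = []
    for entity_id, length_bp, category in entities:
        if length_bp <= 0:
            raise ValueError(f"{entity_id}: non-positive length")
        if category not in by_cat:
            raise ValueError(f"{entity_id}: unknown category {category!r}")
        by_cat[category].append(length_bp)
        all_lengths.append(length_bp)

    out = []
    for fraction in (*SKEW_CATEGORIES, "all"):
        lengths = all_lengths if fraction == "all" else by_cat[fraction]
        if lengths:
            q1, med, q3 = np.percentile(lengths, [25, 50, 75], method=quartile_method)
            out.append(
                FractionSummary(fraction, len(lengths), med / 1000.0,
                                q1 / 1000.0, q3 / 1000.0, int(sum(lengths)))
            )
        else:
            out.append(FractionSummary(fraction, 0, None, None, None, 0))
    return out


def estimate_replicons(
    genes: Iterable[GeneRecord],
    rep_pfams: frozenset[str] | set[str] = REPLICATION_PFAMS,
    fractions: Mapping[str, str] | None = None,
    one_rep_per_plasmid: bool = True,
) -> dict[str, int]:
    """Count putative plasmid replicons per fraction.

    A gene carrying one or more replication-initiator Pfam domains counts
    as one replicon (a gene with several rep domains is not double
    counted). With the assumption that the majority of plasmids carry a
    single replication gene (``one_rep_per_plasmid``), the count is a lower
    bound on the number of distinct plasmids. ``fractions`` maps gene_id to
    an exclusivity category; genes without an entry (or with no mapping
    given) fall under "all".
    """
    if not rep_pfams:
        raise ValueError("rep_pfams must be non-empty")
    if not one_rep_per_plasmid:
        raise NotImplementedError(
            "multi-replicon plasmid correction is deliberately unsupported: "
            "the single-rep assumption keeps the count an 'at least' estimate"
        )
    counts: dict[str, int] = {}
    for gene in genes:
        if not (gene.pfam_ids & set(rep_pfams)):
            continue
        fraction = fractions.get(gene.gene_id, "all") if fractions else "all"
        counts[fraction] = counts.get(fraction, 0) + 1
    return counts


def max_average_plasmid_size(
    total_contig_length_bp: float, replicon_count: int
) -> float | None:
    """Largest possible average plasmid size (kb) in a fraction.

    Total assembled length divided by the replicon count; because the
    replicon count is an "at least" estimate, the quotient is an upper
    bound on the average plasmid size. Returns None when no replicons were
    found (undefined, reported missing).
    """
    if total_contig_length_bp <= 0:
        raise ValueError("total contig length must be positive")
    if replicon_count < 0:
        raise ValueError("replicon count must be non-negative")
    if replicon_count == 0:
        return None
    return total_contig_length_bp / replicon_count / 1000.0


def detect_terminal_overlap(
    sequence: str, min_overlap: int = 14, max_overlap: int = 100
) -> int | None:
    """Longest exact terminal overlap of a contig, or None.

    Returns the largest k in [min_overlap, max_overlap] for which the first
    k bases equal the last k bases exactly (case-insensitive; ambiguity
    codes must match literally). Such an overlap suggests the contig is a
    closed circular sequence whose assembly ran past its own origin; the
    call is putative only — no read-pair or PCR confirmation is attempted.
    Degenerate sequences (e.g. homopolymers) force a hit at ``max_overlap``.
    """
    if min_overlap < 1 or max_overlap < min_overlap:
        raise ValueError("need 1 <= min_overlap <= max_overlap")
    seq = sequence.upper()
    if len(seq) < 2 * min_overlap:
        raise ValueError("sequence shorter than twice the minimum overlap")
    top = min(max_overlap, len(seq) // 2)
    for k in range(top, min_overlap - 1, -1):
        if seq[:k] == seq[-k:]:
            return k
    return None


def summary_table(summaries: Sequence[FractionSummary]) -> pd.DataFrame:
    """Tabulate fraction summaries (size quartiles in kb)."""
    return pd.DataFrame(
        [
            (s.fraction, s.n, s.median_kbp, s.q1_kbp, s.q3_kbp,
             s.total_contig_length_bp, s.replicon_count, s.max_avg_plasmid_size_kbp)
            for s in summaries
        ],
        columns=["fraction", "n", "median_kbp", "q1_kbp", "q3_kbp",
                 "total_length_bp", "replicon_count", "max_avg_plasmid_size_kbp"],
    )
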