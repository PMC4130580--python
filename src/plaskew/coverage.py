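"""Per-reference coverage breadth/depth and plasmid recovery classification.

Consumes read alignments (SAM, or the package's plain-TSV truth dialect) and
computes, per reference sequence, the breadth of coverage (fraction of
positions hit by ≥1 read), mean depth over covered positions, mean depth
over the whole reference, and depth normalised per 10 million library
reads. A reference is classified as partially recovered when, in at least
one library, ≥1,500 bases are covered, breadth is ≥10 %, and mean depth
over covered positions exceeds 1×; a qualifying reference with breadth
≥85 % counts as near-complete. These thresholds guard against references
that recruit reads only through shared repeat elements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "MappingRecord",
    "CoverageProfile",
    "COVERAGE_CLASSES",
    "read_mappings",
    "write_mappings_tsv",
    "split_circular_records",
    "compute_coverage",
    "classify_coverage",
    "coverage_table",
]

#: Ordered recovery classes; later entries imply the earlier criteria.
COVERAGE_CLASSES = ("none", "partial", "near_complete")

TRUTH_TSV_COLUMNS = ["read_id", "ref_id", "start0", "end0", "strand"]


@dataclass(frozen=True)
class MappingRecord:
    """One aligned segment on a reference, 0-based half-open.

    ``end0`` may exceed the reference length for reads that wrap the origin
    of a circular reference; :func:`split_circular_records` normalises such
    records into two segments.
    """

    read_id: str
    ref_id: str
    start0: int
    end0: int
    library_label: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start0 < 0:
            raise ValueError(f"negative start for read {self.read_id}")
        if self.end0 <= self.start0:
            raise ValueError(f"empty span for read {self.read_id}")

    @property
    def span(self) -> int:
        return self.end0 - self.start0


@dataclass(frozen=True)
class CoverageProfile:
    """Coverage summary for one reference in one library."""

    ref_id: str
    ref_length_bp: int
    covered_bases: int
    breadth: float
    mean_depth_covered: float
    mean_depth_all: float
    depth_per_10M: float
    library_label: str = ""


def read_mappings(
    path: str | Path,
    fmt: str | None = None,
    library_label: str = "",
    ref_lengths: Mapping[str, int] | None = None,
    include_secondary: bool = False,
) -> list[MappingRecord]:
    """Load alignments from SAM or the truth-TSV dialect.

    SAM files are parsed with pysam; unmapped reads are skipped and
    secondary/supplementary alignments are ignored unless
    ``include_secondary``. TSV files carry columns
    ``read_id ref_id start0 end0 [strand]``. When ``ref_lengths`` is given,
    records wrapping a circular origin (end0 > reference length) are split
    at the origin.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sam" if path.suffix.lower() == ".sam" else "tsv"
    if fmt == "sam":
        records = _read_sam(path, library_label, include_secondary)
    elif fmt == "tsv":
        records = _read_tsv(path, library_label)
    else:
        raise ValueError(f"unknown mapping format: {fmt!r}")
    if ref_lengths is not None:
        records = split_circular_records(records, ref_lengths)
    return records


def _read_sam(path: Path, library_label: str, include_secondary: bool) -> list[MappingRecord]:
    records: list[MappingRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        if not sam.header.get("SQ"):
            raise ValueError(f"{path}: SAM header lacks @SQ reference lengths")
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if not include_secondary and (aln.is_secondary or aln.is_supplementary):
                continue
            if aln.reference_end is None:
                continue
            records.append(
                MappingRecord(
                    read_id=aln.query_name or "",
                    ref_id=sam.get_reference_name(aln.reference_id),
                    start0=aln.reference_start,
                    end0=aln.reference_end,
                    library_label=library_label,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return records


def _read_tsv(path: Path, library_label: str) -> list[MappingRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "ref_id": str})
    missing = {"read_id", "ref_id", "start0", "end0"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "strand" not in df.columns:
        df["strand"] = "+"
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                MappingRecord(
                    read_id=row.read_id,
                    ref_id=row.ref_id,
                    start0=int(row.start0),
                    end0=int(row.end0),
                    library_label=library_label,
                    strand=str(row.strand),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{i}: malformed mapping row: {exc}") from exc
    return records


def write_mappings_tsv(records: Iterable[MappingRecord], path: str | Path) -> None:
    """Write records in the truth-TSV dialect (round-trips losslessly)."""
    df = pd.DataFrame(
        [(r.read_id, r.ref_id, r.start0, r.end0, r.strand) for r in records],
        columns=TRUTH_TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def split_circular_records(
    records: Iterable[MappingRecord], ref_lengths: Mapping[str, int]
) -> list[MappingRecord]:
    """Split origin-wrapping records (end0 > reference length) in two."""
    out: list[MappingRecord] = []
    for rec in records:
        length = ref_lengths.get(rec.ref_id)
        if length is None or rec.end0 <= length:
            out.append(rec)
            continue
        if rec.start0 >= length or rec.end0 > 2 * length:
            raise ValueError(
                f"read {rec.read_id}: span [{rec.start0},{rec.end0}) invalid for "
                f"circular reference of length {length}"
            )
        out.append(replace(rec, end0=length))
        out.append(replace(rec, start0=0, end0=rec.end0 - length))
    return out


def compute_coverage(
    mappings: Sequence[MappingRecord],
    ref_lengths: Mapping[str, int],
    total_reads_in_library: int,
    library_label: str | None = None,
) -> list[CoverageProfile]:
    """Coverage profiles for every reference in ``ref_lengths``.

    Depth is accumulated with a difference array, so runtime is linear in
    reads plus reference length. References recruiting no reads are reported
    with breadth 0. ``depth_per_10M`` normalises the whole-reference mean
    depth to a library of 10 million reads so libraries of different size
    are comparable.
    """
    if total_reads_in_library <= 0:
        raise ValueError("total_reads_in_library must be positive")
    for rec in mappings:
        if rec.ref_id not in ref_lengths:
            raise KeyError(f"mapping references unknown ref_id {rec.ref_id!r}")
    if library_label is None:
        labels = {r.library_label for r in mappings}
        library_label = labels.pop() if len(labels) == 1 else ""

    mappings = split_circular_records(mappings, ref_lengths)
    by_ref: dict[str, list[MappingRecord]] = {ref: [] for ref in ref_lengths}
    for rec in mappings:
        by_ref[rec.ref_id].append(rec)

    profiles = []
    for ref_id, length in ref_lengths.items():
        diff = np.zeros(length + 1, dtype=np.int64)
        for rec in by_ref[ref_id]:
            diff[rec.start0] += 1
            diff[min(rec.end0, length)] -= 1
        depth = np.cumsum(diff[:-1])
        covered = int(np.count_nonzero(depth))
        mean_all = float(depth.mean())
        mean_cov = float(depth[depth > 0].mean()) if covered else 0.0
        profiles.append(
            CoverageProfile(
                ref_id=ref_id,
                ref_length_bp=length,
                covered_bases=covered,
                breadth=covered / length,
                mean_depth_covered=mean_cov,
                mean_depth_all=mean_all,
                depth_per_10M=mean_all * 1e7 / total_reads_in_library,
                library_label=library_label,
            )
        )
    return profiles


def classify_coverage(
    profiles_across_libraries: Sequence[CoverageProfile],
    min_covered_bases: int = 1500,
    min_breadth: float = 0.10,
    min_mean_depth_covered: float = 1.0,
    near_complete_breadth: float = 0.85,
) -> str:
    """Classify recovery of one reference from its per-library profiles.

    ``partial`` requires a single library to meet all three criteria at
    once: covered bases ≥ ``min_covered_bases`` (inclusive), breadth ≥
    ``min_breadth`` (inclusive), and mean depth over covered positions
    strictly greater than ``min_mean_depth_covered``. ``near_complete``
    additionally requires a qualifying profile with breadth ≥
    ``near_complete_breadth``. Adding mappings can only promote the class.
    """
    if not profiles_across_libraries:
        raise ValueError("no coverage profiles given")
    best = "none"
    for p in profiles_across_libraries:
        qualifies = (
            p.covered_bases >= min_covered_bases
            and p.breadth >= min_breadth
            and p.mean_depth_covered > min_mean_depth_covered
        )
        if not qualifies:
            continue
        if p.breadth >= near_complete_breadth:
            return "near_complete"
        best = "partial"
    return best


def coverage_table(profiles: Sequence[CoverageProfile]) -> pd.DataFrame:
    """Tabulate profiles (one row per reference × library)."""
    return pd.DataFrame(
        [
            (p.library_label, p.ref_id, p.ref_length_bp, p.covered_bases,
             p.breadth, p.mean_depth_covered, p.mean_depth_all, p.depth_per_10M)
            for p in profiles
        ],
        columns=["library", "ref_id", "length", "covered_bases", "breadth",
                 "mean_depth_covered", "mean_depth_all", "depth_per_10M"],
    )
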