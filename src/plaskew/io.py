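"""Shared file I/O: FASTA, GFF-like gene tables, hmmscan domtblout, Pfam TSV.

Sequence formats go through Biopython; tabular formats through pandas. The
hmmscan ``--domtblout`` reader is a small column parser for that tool's
fixed whitespace-separated layout (22 columns plus a free-text
description), since no installed library exposes one.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "ref_lengths_from_fasta",
    "read_gff_like",
    "read_domtbl",
    "read_pfam_tsv",
]

_DOMTBL_MIN_COLUMNS = 22


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id → sequence dict (order-preserving)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq)
    if not records:
        logger.warning("empty FASTA: %s", path)
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    """Write an id → sequence mapping as wrapped FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def ref_lengths_from_fasta(path: str | Path) -> dict[str, int]:
    return {name: len(seq) for name, seq in read_fasta(path).items()}


def read_gff_like(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from GFF3 or a TSV.

    GFF3 (9 columns, 1-based inclusive coordinates) is converted to 0-based
    half-open; the gene id is taken from the ``ID=`` attribute, falling back
    to a positional name. TSV input must carry columns
    ``gene_id contig_id start0 end0`` (already 0-based half-open).
    Returns columns ``gene_id contig_id start0 end0``.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ValueError(f"{path}:{lineno}: expected 9 GFF columns, got {len(fields)}")
                contig, _source, _ftype, start1, end1, _score, _strand, _phase, attrs = fields
                gene_id = None
                for item in attrs.split(";"):
                    if item.strip().startswith("ID="):
                        gene_id = item.strip()[3:]
                        break
                if gene_id is None:
                    gene_id = f"{contig}_gene{lineno}"
                try:
                    start0, end0 = int(start1) - 1, int(end1)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
                rows.append((gene_id, contig, start0, end0))
        df = pd.DataFrame(rows, columns=["gene_id", "contig_id", "start0", "end0"])
    else:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig_id": str})
        missing = {"gene_id", "contig_id", "start0", "end0"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("no gene records in %s", path)
    return df


def read_domtbl(path: str | Path) -> pd.DataFrame:
    """Parse hmmscan ``--domtblout`` rows into (gene, Pfam domain) hits.

    Keeps the hits as given — when hmmscan was run with the gathering
    threshold cutoff the rows are already threshold-filtered. Returns
    columns ``gene_id pfam_id pfam_acc evalue``, where ``pfam_id`` is the
    target (domain) name and ``pfam_acc`` the versionless accession.
    """
    rows = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, _DOMTBL_MIN_COLUMNS)
            if len(fields) < _DOMTBL_MIN_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLUMNS} domtblout columns"
                )
            target_name, target_acc, _tlen, query_name = fields[0], fields[1], fields[2], fields[3]
            try:
                evalue = float(fields[11])  # per-domain conditional E-value
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed E-value field") from exc
            acc = target_acc.split(".")[0] if target_acc != "-" else target_acc
            rows.append((query_name, target_name, acc, evalue))
    if not rows:
        logger.warning("no domain hits in %s", path)
    return pd.DataFrame(rows, columns=["gene_id", "pfam_id", "pfam_acc", "evalue"])


def read_pfam_tsv(path: str | Path) -> pd.DataFrame:
    """Read a ``gene_id pfam_id [class]`` assignment table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_id", "pfam_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
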