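"""Readers and writers for the external formats the pipeline touches.

Conventions enforced throughout the package:

* all genomic intervals are 0-based half-open; BED is native, SAM ``POS``
  is converted from 1-based on load;
* sequences are held in the RNA alphabet (``U``, not ``T``), uppercase;
* expression matrices are complete — rows with missing values are dropped
  on load and the drop is counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_DNA_TO_RNA = str.maketrans("acgtuACGTU", "ACGUUACGUU")
_VALID_RNA = frozenset("ACGU")


def normalize_rna(sequence: str) -> str:
    """Uppercase and map T->U; raises on characters outside ACGTU."""
    seq = sequence.translate(_DNA_TO_RNA)
    bad = set(seq) - _VALID_RNA
    if bad:
        raise ValueError(f"non-ACGTU characters in sequence: {sorted(bad)}")
    return seq


def reverse_complement_rna(sequence: str) -> str:
    return sequence.translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class UtrRecord:
    """One 3'UTR sequence, optionally located on the genome.

    The genomic span may differ from the sequence length (spliced UTR
    models are permitted).
    """

    utr_id: str
    gene_id: str
    sequence: str
    interval: Optional[GenomicInterval] = None


@dataclass(frozen=True)
class Bed6Record:
    chrom: str
    start: int
    end: int
    name: str
    score: float
    strand: str


@dataclass(frozen=True)
class AlignedRead3p:
    """A 3'-end-sequencing read in mRNA-sense coordinates.

    ``genome_end3p`` is the 0-based position of the last genome-matched
    base on the mRNA 3' side; ``clip3p`` holds the soft-clipped bases
    beyond it, in mRNA-sense 5'->3' order, RNA alphabet.
    """

    read_id: str
    chrom: str
    strand: str
    genome_end3p: int
    mapq: int
    clip3p: str = ""


@dataclass
class ExpressionMatrix:
    """Genes/probe sets x samples numeric table with group labels."""

    data: pd.DataFrame  # rows = genes/probe sets, columns = samples
    groups: dict[str, str] = field(default_factory=dict)  # col_id -> label
    scale: str = "linear"  # "linear" or "log2"
    n_dropped_rows: int = 0

    def __post_init__(self):
        if self.data.index.has_duplicates:
            raise ValueError("duplicate row ids in expression matrix")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate column ids in expression matrix")
        if not np.all(np.isfinite(self.data.to_numpy(dtype=float))):
            raise ValueError("expression matrix contains non-finite values")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def columns_for(self, label: str) -> list[str]:
        return [c for c in self.data.columns if self.groups.get(c) == label]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[UtrRecord]:
    """Read 3'UTR records from FASTA.

    Headers are parsed as ``utr_id gene_id``; a missing gene_id defaults
    to the utr_id.  Sequences are normalized to the RNA alphabet.
    """
    path = Path(path)
    records: list[UtrRecord] = []
    with path.open() as handle:
        first = handle.read(1)
        if first and first != ">":
            raise ValueError(f"{path}: not FASTA — line 1 does not start with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        utr_id = parts[0]
        gene_id = parts[1] if len(parts) > 1 else utr_id
        try:
            seq = normalize_rna(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"record {utr_id!r}: {exc}") from exc
        records.append(UtrRecord(utr_id=utr_id, gene_id=gene_id, sequence=seq))
    return records


def write_fasta(records: Iterable[UtrRecord], path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            header = rec.utr_id if rec.gene_id == rec.utr_id else f"{rec.utr_id} {rec.gene_id}"
            fh.write(f">{header}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# BED6


def read_bed6(path) -> list[Bed6Record]:
    """Read a BED6 file of stranded 0-based half-open intervals.

    ``.`` strands are rejected: 3'UTR assignment is strand-aware.
    """
    out: list[Bed6Record] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: expected >=6 tab-separated fields, got {len(fields)}")
            chrom, start_s, end_s, name, score_s, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
                score = float(score_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            if start < 0 or start >= end:
                raise ValueError(f"line {lineno}: invalid interval {start}-{end}")
            if strand not in ("+", "-"):
                raise ValueError(f"line {lineno}: strand {strand!r} not usable for 3'UTRs")
            out.append(Bed6Record(chrom, start, end, name, score, strand))
    return out


def write_bed6(records: Iterable[Bed6Record], path) -> None:
    with Path(path).open("w") as fh:
        for r in records:
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{score}\t{r.strand}\n")


# ---------------------------------------------------------------------------
# SAM


def read_sam_3p(path) -> list[AlignedRead3p]:
    """Extract mRNA-sense 3'-end information from a SAM file.

    Unmapped reads are skipped.  For a forward-strand alignment the
    mRNA 3' end is the rightmost aligned base and the 3' soft-clip is the
    trailing ``S`` operation; for a reverse-strand alignment (FLAG 0x10)
    the 3' end is the leftmost aligned base and the 3' soft-clip is the
    leading ``S`` operation reverse-complemented into mRNA sense.
    """
    out: list[AlignedRead3p] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.cigartuples is None:
                raise ValueError(f"read {aln.query_name!r}: mapped read lacks CIGAR")
            seq = aln.query_sequence or ""
            cig = aln.cigartuples  # list of (op, length); op 4 = soft clip
            if aln.is_reverse:
                end3p = aln.reference_start  # 0-based leftmost aligned base
                clip_len = cig[0][1] if cig[0][0] == 4 else 0
                clip_dna = seq[:clip_len]
                clip3p = reverse_complement_rna(normalize_rna(clip_dna)) if clip_dna else ""
                strand = "-"
            else:
                end3p = aln.reference_end - 1  # 0-based rightmost aligned base
                clip_len = cig[-1][1] if cig[-1][0] == 4 else 0
                clip_dna = seq[len(seq) - clip_len :] if clip_len else ""
                clip3p = normalize_rna(clip_dna) if clip_dna else ""
                strand = "+"
            out.append(
                AlignedRead3p(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    strand=strand,
                    genome_end3p=end3p,
                    mapq=aln.mapping_quality,
                    clip3p=clip3p,
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV matrices


def read_matrix_tsv(path, groups: Optional[dict[str, str]] = None, scale: str = "linear") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column row ids, first row col ids).

    Rows containing any non-numeric or missing cell are dropped; the drop
    count is recorded on the returned matrix and logged.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids: {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_matrix_tsv: dropped %d rows with missing values", n_dropped)
    return ExpressionMatrix(
        data=numeric.loc[keep].astype(float),
        groups=dict(groups or {}),
        scale=scale,
        n_dropped_rows=n_dropped,
    )


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix TSV that round-trips bit-exactly through read_matrix_tsv."""
    # %.17g preserves every float64 bit across the text round-trip
    matrix.data.to_csv(path, sep="\t", index_label="id", float_format="%.17g")
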