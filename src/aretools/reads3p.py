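"""3'-end sequencing (3'READS-style) read quantification.

A read evidences a genuine poly(A) junction — a PASS read
(polyadenylation site-supporting) — when at least ``min_a`` consecutive
non-genomic A's immediately follow the genome-encoded part, i.e. the
mRNA-sense 3' soft-clip starts with >= min_a A's.  Later non-A bases in
the clip (sequencing error deep in the A-tail) do not disqualify a read;
a non-A directly at the junction does.

PASS reads falling inside annotated 3'UTRs give per-gene counts; RPM is
per million of *total* PASS reads, so reads outside annotated UTRs still
contribute to the denominator.  Between-condition changes are log2
ratios of RPM with a symmetric pseudocount.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .io_formats import AlignedRead3p, Bed6Record

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 10
DEFAULT_MIN_A = 2
DEFAULT_PSEUDO_RPM = 1.0


@dataclass(frozen=True)
class GeneQuant:
    gene_id: str
    pass_count: int
    rpm: float


@dataclass(frozen=True)
class ReadAccounting:
    """Per-run read conservation: every input read lands in exactly one bin."""

    n_input: int
    n_low_mapq: int
    n_non_pass: int
    n_pass_unassigned: int
    n_pass_assigned: int
    n_ambiguous: int  # subset of n_pass_assigned resolved by tie-break

    def conserved(self) -> bool:
        return self.n_input == (
            self.n_low_mapq + self.n_non_pass + self.n_pass_unassigned + self.n_pass_assigned
        )


def filter_mapq(reads: Iterable[AlignedRead3p], min_mapq: int = DEFAULT_MIN_MAPQ) -> list[AlignedRead3p]:
    """Keep reads with mapping quality >= min_mapq (inclusive), order preserved."""
    return [r for r in reads if r.mapq >= min_mapq]


def qualify_pass(read: AlignedRead3p, min_a: int = DEFAULT_MIN_A) -> bool:
    """True iff >= min_a consecutive A's open the mRNA-sense 3' soft-clip."""
    clip = read.clip3p
    lead = 0
    for base in clip:
        if base != "A":
            break
        lead += 1
        if lead >= min_a:
            return True
    return lead >= min_a


class Utr3pIndex:
    """Strand-aware interval index of 3'UTRs for read 3'-end assignment.

    When a 3' end falls in several overlapping UTRs the read goes to the
    gene whose annotated 3' terminus is nearest; exact ties break to the
    lexicographically smaller gene_id and are counted for auditing.
    """

    def __init__(self, utrs: Sequence[Bed6Record]):
        self._trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for utr in utrs:
            self._trees[(utr.chrom, utr.strand)][utr.start : utr.end] = utr
        self.n_ambiguous = 0

    def assign(self, read: AlignedRead3p) -> Optional[str]:
        tree = self._trees.get((read.chrom, read.strand))
        if tree is None:
            return None
        hits = tree[read.genome_end3p]
        if not hits:
            return None
        if len(hits) == 1:
            return next(iter(hits)).data.name
        candidates = []
        for iv in hits:
            utr: Bed6Record = iv.data
            terminus = utr.end - 1 if utr.strand == "+" else utr.start
            candidates.append((abs(read.genome_end3p - terminus), utr.name))
        candidates.sort()
        if candidates[0][0] == candidates[1][0]:
            self.n_ambiguous += 1
        return candidates[0][1]


def assign_to_utr(read: AlignedRead3p, utrs: Sequence[Bed6Record] | Utr3pIndex) -> Optional[str]:
    """Gene whose 3'UTR contains the read's 3' end (matching chrom/strand)."""
    index = utrs if isinstance(utrs, Utr3pIndex) else Utr3pIndex(utrs)
    return index.assign(read)


def quantify_rpm(assignments: Mapping[str, int], total_pass: int) -> list[GeneQuant]:
    """Reads-per-million of total PASS reads for each gene."""
    counted = sum(assignments.values())
    if total_pass <= 0:
        raise ValueError("total_pass must be positive")
    if total_pass < counted:
        raise ValueError(f"total_pass={total_pass} below the sum of per-gene counts ({counted})")
    return [
        GeneQuant(gene_id=g, pass_count=c, rpm=c / total_pass * 1e6)
        for g, c in sorted(assignments.items())
    ]


def log2_ratio(
    quant_a: Sequence[GeneQuant],
    quant_b: Sequence[GeneQuant],
    pseudo: float = DEFAULT_PSEUDO_RPM,
) -> dict[str, float]:
    """Per-gene log2((rpm_a + pseudo) / (rpm_b + pseudo)).

    Genes present in either condition are reported; a gene absent from
    one condition contributes rpm 0 there.  The symmetric pseudocount
    (default 1 RPM) keeps zero-expression genes finite and unbiased.
    """
    if pseudo <= 0:
        raise ValueError("pseudo must be positive")
    rpm_a = {q.gene_id: q.rpm for q in quant_a}
    rpm_b = {q.gene_id: q.rpm for q in quant_b}
    return {
        g: math.log2((rpm_a.get(g, 0.0) + pseudo) / (rpm_b.get(g, 0.0) + pseudo))
        for g in sorted(set(rpm_a) | set(rpm_b))
    }


def quantify_sample(
    reads: Sequence[AlignedRead3p],
    utrs: Sequence[Bed6Record],
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_a: int = DEFAULT_MIN_A,
) -> tuple[list[GeneQuant], ReadAccounting]:
    """Full per-sample pipeline: MAPQ filter -> PASS call -> UTR assignment -> RPM.

    Returns per-gene quantifications (RPM over total PASS reads,
    assigned or not) and the read-conservation accounting.
    """
    n_input = len(reads)
    kept = filter_mapq(reads, min_mapq)
    n_low = n_input - len(kept)
    pass_reads = [r for r in kept if qualify_pass(r, min_a)]
    n_non_pass = len(kept) - len(pass_reads)

    index = Utr3pIndex(utrs)
    counts: Counter[str] = Counter()
    n_unassigned = 0
    for read in pass_reads:
        gene = index.assign(read)
        if gene is None:
            n_unassigned += 1
        else:
            counts[gene] += 1
    accounting = ReadAccounting(
        n_input=n_input,
        n_low_mapq=n_low,
        n_non_pass=n_non_pass,
        n_pass_unassigned=n_unassigned,
        n_pass_assigned=len(pass_reads) - n_unassigned,
        n_ambiguous=index.n_ambiguous,
    )
    logger.info(
        "quantify_sample: %d reads -> %d low-MAPQ, %d non-PASS, %d unassigned, %d assigned (%d ambiguous)",
        n_input, n_low, n_non_pass, n_unassigned, accounting.n_pass_assigned, index.n_ambiguous,
    )
    quants = quantify_rpm(dict(counts), total_pass=len(pass_reads)) if pass_reads else []
    return quants, accounting
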