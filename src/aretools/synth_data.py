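"""Seeded synthetic data with the statistical structure the analyses assume.

Every generator is a pure function of a :class:`SimConfig`: the same
seed yields byte-identical output, and each dataset ships with its
ground truth so recovery can be asserted exactly.

What is emulated: 3'UTR sequences with exact planted AUUUA/UAUUUAU
counts in clustered (>=12-nt AU run) or isolated context; per-gene log2
expression changes whose location shifts with motif count; 3'-end
sequencing alignments with >=2-A soft-clips at planted poly(A) sites
plus non-PASS / low-MAPQ / intergenic decoys; an 81-tissue expression
atlas with a planted neural-enriched gene set; and replicate KO/WT
matrices with planted fold changes.  What is not: sequencing error
models, chip-specific probe effects, real covariance between genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    Bed6Record,
    ExpressionMatrix,
    UtrRecord,
    reverse_complement_rna,
)
from .are_annotation import (
    DEFAULT_GROUP_BOUNDARIES,
    annotate_ares,
    group_by_pentamer_count,
    group_labels,
)
from .tissue_rank import NEURAL, NON_NEURAL, TissueAtlas

_RNA = np.array(list("ACGU"))


@dataclass(frozen=True)
class MotifGroupPlan:
    n_genes: int
    target_pentamers: int
    clustered: bool = False


def default_motif_plan() -> dict[str, MotifGroupPlan]:
    # one plan per default pentamer-count bin (0, 1-2, 3-5, >=6)
    return {
        "0": MotifGroupPlan(150, 0),
        "1-2": MotifGroupPlan(150, 2),
        "3-5": MotifGroupPlan(150, 4),
        ">=6": MotifGroupPlan(150, 7, clustered=True),
    }


@dataclass(frozen=True)
class KoPlan:
    n_up: int = 50
    n_down: int = 50
    fold: float = 16.0
    n_reps_per_group: int = 4
    noise_sd: float = 0.25
    n_genes: int = 2000


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    utr_length_range: tuple[int, int] = (150, 300)
    gc_content: float = 0.5
    motif_plan: Mapping[str, MotifGroupPlan] = field(default_factory=default_motif_plan)
    group_boundaries: tuple[int, ...] = DEFAULT_GROUP_BOUNDARIES
    fc_effect: float = 1.0
    fc_noise_sd: float = 0.5
    reads_per_gene_range: tuple[int, int] = (50, 200)
    frac_non_pass: float = 0.10
    frac_low_mapq: float = 0.05
    frac_outside: float = 0.05
    n_tissues: int = 81
    n_neural: int = 12
    atlas_n_genes: int = 5000
    n_planted_neural: int = 80
    neural_shift_sd: float = 2.0
    ko_plan: KoPlan = field(default_factory=KoPlan)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent stream per generator so one dataset never perturbs another
    return np.random.default_rng([stream, cfg.seed % 2**31])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return "".join(rng.choice(_RNA, size=n, p=p))


def _clustered_block(c: int) -> str:
    """All-AU block carrying exactly c overlapping AUUUA/UAUUUAU motifs."""
    block = "U" + "AUUU" * c + "AU"
    while len(block) < 12:  # guarantee the >=12-nt run threshold
        block += "A"
    return block


# ---------------------------------------------------------------------------
# UTR sequences


def gen_utrs(cfg: SimConfig) -> tuple[list[UtrRecord], list[Bed6Record], pd.DataFrame]:
    """Generate UTRs whose annotated motif counts hit the plan exactly.

    Planted blocks are embedded in random-background flanks and the
    whole sequence is rejection-sampled until ``annotate_ares`` returns
    exactly the per-group target pentamer count (and, for clustered
    groups, all planted heptamers inside a >=12-nt AU run).  Also emits
    a BED6 track laying the UTRs head-to-tail on one chromosome with
    alternating strands, plus a per-gene truth table.
    """
    rng = _rng(cfg, 1)
    lo, hi = cfg.utr_length_range
    records: list[UtrRecord] = []
    beds: list[Bed6Record] = []
    truth_rows = []
    offset = 100
    gi = 0
    for label, plan in cfg.motif_plan.items():
        c = plan.target_pentamers
        min_len = len(_clustered_block(c)) if (plan.clustered and c) else 7 * c
        if min_len > hi:
            raise ValueError(f"group {label!r}: planted motifs do not fit in max UTR length {hi}")
        for _ in range(plan.n_genes):
            gi += 1
            gene = f"g{gi:04d}"
            length = int(rng.integers(max(lo, min_len), hi + 1))
            for _attempt in range(2000):
                seq = _build_planted_sequence(rng, length, c, plan.clustered, cfg.gc_content)
                ann = annotate_ares(UtrRecord(gene, gene, seq))
                if ann.n_pentamer != c:
                    continue
                if plan.clustered and c > 0 and ann.n_clustered < 1:
                    continue
                if not plan.clustered and ann.n_clustered > 0:
                    continue
                break
            else:  # pragma: no cover - astronomically unlikely with sane configs
                raise RuntimeError(f"could not plant {c} pentamers in {length} nt for {gene}")
            strand = "+" if gi % 2 else "-"
            records.append(UtrRecord(utr_id=gene, gene_id=gene, sequence=seq))
            beds.append(Bed6Record("chr1", offset, offset + len(seq), gene, 0, strand))
            truth_rows.append({"gene_id": gene, "group": label, "n_pentamer": c, "clustered": plan.clustered})
            offset += len(seq) + 200
    truth = pd.DataFrame(truth_rows)
    return records, beds, truth


def _build_planted_sequence(
    rng: np.random.Generator, length: int, c: int, clustered: bool, gc: float
) -> str:
    if c == 0:
        return _random_bases(rng, length, gc)
    if clustered:
        block = _clustered_block(c)
        flank = length - len(block)
        left = int(rng.integers(0, flank + 1))
        # G-caps terminate the AU run so the planted count stays exact
        return (
            _random_bases(rng, max(left - 1, 0), gc)
            + ("G" if left else "")
            + block
            + ("G" if flank - left else "")
            + _random_bases(rng, max(flank - left - 1, 0), gc)
        )
    block = "GAUUUAG"  # isolated: 5-nt AU run, far below the cluster threshold
    needed = c * len(block)
    if needed > length:
        raise ValueError(f"cannot fit {c} isolated motifs in {length} nt")
    spare = length - needed
    cuts = np.sort(rng.integers(0, spare + 1, size=c))
    parts = []
    prev = 0
    for cut in cuts:
        parts.append(_random_bases(rng, cut - prev, gc))
        parts.append(block)
        prev = cut
    parts.append(_random_bases(rng, spare - prev, gc))
    return "".join(parts)


# ---------------------------------------------------------------------------
# fold changes


def gen_fold_changes(cfg: SimConfig, annotations) -> dict[str, float]:
    """log2 fold changes whose location rises with pentamer-count bin.

    group_effect(bin i) = fc_effect * i / (n_bins - 1) (0 for the
    motif-less bin, fc_effect for the top bin), plus Normal(0,
    fc_noise_sd) gene-level noise.
    """
    rng = _rng(cfg, 2)
    labels = group_labels(cfg.group_boundaries)
    groups = group_by_pentamer_count(annotations, cfg.group_boundaries)
    out: dict[str, float] = {}
    denom = max(len(labels) - 1, 1)
    for i, label in enumerate(labels):
        effect = cfg.fc_effect * i / denom
        for gene in sorted(groups.get(label, ())):
            out[gene] = float(effect + rng.normal(0.0, cfg.fc_noise_sd))
    return out


# ---------------------------------------------------------------------------
# 3'-end sequencing alignments


@dataclass(frozen=True)
class SamTruth:
    pass_counts: dict[str, int]
    n_pass: int
    n_non_pass: int
    n_low_mapq: int
    n_outside: int

    @property
    def n_total(self) -> int:
        return self.n_pass + self.n_non_pass + self.n_low_mapq + self.n_outside


def gen_sam_3reads(
    cfg: SimConfig,
    utr_bed: Sequence[Bed6Record],
    path,
    truth: Optional[Mapping[str, int]] = None,
) -> SamTruth:
    """Write a SAM file of planted poly(A)-junction reads plus decoys.

    Each gene receives its planted number of PASS reads: 3' ends
    uniform inside the UTR, soft-clips opening with >=2 A's, MAPQ 30.
    Decoys, labelled in the read name, are: ``nonpass`` (0-1 leading
    A's), ``lowmapq`` (MAPQ < 10, removed exactly by the MAPQ filter)
    and ``outside`` (PASS-like but between UTRs).  Reverse-strand UTRs
    get FLAG-16 alignments with the clip reverse-complemented, so the
    reader must restore mRNA sense.
    """
    rng = _rng(cfg, 3)
    match_len = 20
    if truth is None:
        lo, hi = cfg.reads_per_gene_range
        truth = {b.name: int(rng.integers(lo, hi + 1)) for b in utr_bed}
    n_pass_total = sum(truth.values())
    n_non_pass = int(round(cfg.frac_non_pass * n_pass_total))
    n_low = int(round(cfg.frac_low_mapq * n_pass_total))
    n_outside = int(round(cfg.frac_outside * n_pass_total))

    chrom_len = max(b.end for b in utr_bed) + 10_000
    lines = ["@HD\tVN:1.6\tSO:unknown", f"@SQ\tSN:chr1\tLN:{chrom_len}"]
    bed_list = list(utr_bed)

    def emit(name: str, bed: Bed6Record, end3p: int, clip_sense: str, mapq: int) -> None:
        genome_rna = _random_bases(rng, match_len, 0.5)
        if bed.strand == "+":
            pos1 = end3p - match_len + 2  # 1-based leftmost
            cigar = f"{match_len}M{len(clip_sense)}S" if clip_sense else f"{match_len}M"
            seq_rna = genome_rna + clip_sense
            flag = 0
        else:
            pos1 = end3p + 1
            cigar = f"{len(clip_sense)}S{match_len}M" if clip_sense else f"{match_len}M"
            seq_rna = reverse_complement_rna(genome_rna + clip_sense)
            flag = 16
        seq_dna = seq_rna.replace("U", "T")
        lines.append(
            f"{name}\t{flag}\tchr1\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq_dna}\t*"
        )

    def pass_clip() -> str:
        return "A" * int(rng.integers(2, 7))

    def end_inside(bed: Bed6Record) -> int:
        # keep the full match inside the UTR so strand arithmetic stays simple
        if bed.strand == "+":
            return int(rng.integers(bed.start + match_len - 1, bed.end))
        return int(rng.integers(bed.start, bed.end - match_len + 1))

    idx = 0
    for bed in bed_list:
        for _ in range(truth.get(bed.name, 0)):
            idx += 1
            emit(f"{bed.name}:{idx}:pass", bed, end_inside(bed), pass_clip(), mapq=30)
    for _ in range(n_non_pass):
        idx += 1
        bed = bed_list[int(rng.integers(len(bed_list)))]
        clip = "A" if rng.random() < 0.5 else "G" + pass_clip()
        emit(f"decoy:{idx}:nonpass", bed, end_inside(bed), clip, mapq=30)
    for _ in range(n_low):
        idx += 1
        bed = bed_list[int(rng.integers(len(bed_list)))]
        emit(f"decoy:{idx}:lowmapq", bed, end_inside(bed), pass_clip(), mapq=int(rng.integers(0, 10)))
    for _ in range(n_outside):
        idx += 1
        end3p = int(rng.integers(chrom_len - 5_000 + match_len, chrom_len - 100))
        fake = Bed6Record("chr1", end3p - match_len, end3p + match_len, "none", 0, "+")
        emit(f"decoy:{idx}:outside", fake, end3p, pass_clip(), mapq=30)

    Path(path).write_text("\n".join(lines) + "\n")
    return SamTruth(
        pass_counts=dict(truth),
        n_pass=n_pass_total,
        n_non_pass=n_non_pass,
        n_low_mapq=n_low,
        n_outside=n_outside,
    )


# ---------------------------------------------------------------------------
# tissue atlas


def gen_atlas(cfg: SimConfig) -> tuple[TissueAtlas, set[str]]:
    """81-tissue-style atlas with a planted neural-enriched gene set.

    Background cells are i.i.d. Normal(8, 1) on a log2-like scale;
    planted rows gain ``neural_shift_sd`` (in SD units, SD = 1) in every
    neural tissue.  The first neural tissue is named ``cerebral_cortex``.
    """
    rng = _rng(cfg, 4)
    if cfg.n_neural < 1 or cfg.n_neural >= cfg.n_tissues:
        raise ValueError("need 1 <= n_neural < n_tissues")
    tissues = ["cerebral_cortex"] + [f"neural_{i:02d}" for i in range(2, cfg.n_neural + 1)]
    tissues += [f"tissue_{i:02d}" for i in range(cfg.n_neural + 1, cfg.n_tissues + 1)]
    labels = {t: (NEURAL if i < cfg.n_neural else NON_NEURAL) for i, t in enumerate(tissues)}

    n_rows = cfg.atlas_n_genes + cfg.n_planted_neural
    values = rng.normal(8.0, 1.0, size=(n_rows, cfg.n_tissues))
    planted = [f"planted_{i:03d}" for i in range(1, cfg.n_planted_neural + 1)]
    background = [f"a{i:05d}" for i in range(1, cfg.atlas_n_genes + 1)]
    values[: cfg.n_planted_neural, : cfg.n_neural] += cfg.neural_shift_sd
    df = pd.DataFrame(values, index=planted + background, columns=tissues)
    atlas = TissueAtlas(
        matrix=ExpressionMatrix(data=df, groups=dict(labels), scale="log2"),
        neural_labels=labels,
    )
    return atlas, set(planted)


# ---------------------------------------------------------------------------
# KO/WT replicate matrices


def gen_ko_matrix(cfg: SimConfig) -> tuple[ExpressionMatrix, set[str], set[str]]:
    """Replicate KO/WT log2 matrix with planted fold changes.

    Baselines per row ~ Normal(8, 2); within-group noise Normal(0,
    noise_sd); the first ``n_up`` rows gain +log2(fold) in every KO
    column and the next ``n_down`` rows lose the same amount.
    """
    rng = _rng(cfg, 5)
    plan = cfg.ko_plan
    if plan.n_reps_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    n = plan.n_genes
    if plan.n_up + plan.n_down > n:
        raise ValueError("planted rows exceed n_genes")
    wt_cols = [f"WT_{i}" for i in range(1, plan.n_reps_per_group + 1)]
    ko_cols = [f"KO_{i}" for i in range(1, plan.n_reps_per_group + 1)]
    baseline = rng.normal(8.0, 2.0, size=n)
    values = baseline[:, None] + rng.normal(0.0, plan.noise_sd, size=(n, 2 * plan.n_reps_per_group))
    shift = np.log2(plan.fold)
    values[: plan.n_up, plan.n_reps_per_group :] += shift
    values[plan.n_up : plan.n_up + plan.n_down, plan.n_reps_per_group :] -= shift
    rows = [f"p{i:05d}" for i in range(1, n + 1)]
    groups = {c: "WT" for c in wt_cols} | {c: "KO" for c in ko_cols}
    matrix = ExpressionMatrix(
        data=pd.DataFrame(values, index=rows, columns=wt_cols + ko_cols),
        groups=groups,
        scale="log2",
    )
    up = set(rows[: plan.n_up])
    down = set(rows[plan.n_up : plan.n_up + plan.n_down])
    return matrix, up, down
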