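"""Tissue-specificity rank statistics over a multi-tissue expression atlas.

Each gene's expression values across the T atlas tissues are sorted in
increasing order; a gene's rank for a focal tissue is the position of
that tissue in the sorted list (1 = expressed lower there than anywhere
else, T = higher than anywhere else).  Ties break by stable atlas column
order, keeping ranks integral in 1..T.

A gene set's shift towards high focal-tissue ranks (tissue-specific
expression) is measured by the one-sided KS statistic
D+ = sup(F_background - F_set) with p = exp(-2 D+^2 nm/(n+m)), and the
scan over all tissues is compared between neural and non-neural tissues
with a one-sided Wilcoxon rank-sum test on the per-tissue p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from . import stats_core

logger = logging.getLogger(__name__)

NEURAL = "neural"
NON_NEURAL = "non-neural"


@dataclass
class TissueAtlas:
    """Expression atlas (genes x tissues) with neural/non-neural labels."""

    matrix: ExpressionMatrix
    neural_labels: dict[str, str] = field(default_factory=dict)  # tissue -> label

    def __post_init__(self):
        if len(self.matrix.col_ids) < 2:
            raise ValueError("atlas needs at least 2 tissues")
        missing = set(self.matrix.col_ids) - set(self.neural_labels)
        if missing:
            raise ValueError(f"unlabelled tissues: {sorted(missing)[:5]}")
        bad = set(self.neural_labels.values()) - {NEURAL, NON_NEURAL}
        if bad:
            raise ValueError(f"labels must be {NEURAL!r}/{NON_NEURAL!r}, got {sorted(bad)}")

    @property
    def tissues(self) -> list[str]:
        return self.matrix.col_ids

    @property
    def n_tissues(self) -> int:
        return len(self.matrix.col_ids)

    def neural_tissues(self) -> list[str]:
        return [t for t in self.tissues if self.neural_labels[t] == NEURAL]


@dataclass(frozen=True)
class RankResult:
    focal_tissue: str
    ranks: dict[str, int]
    D_plus: float
    p_one_sided: float
    rank_median_set: float
    rank_median_background: float


def rank_tissue(expr_row: Sequence[float], focal_index: int) -> int:
    """Rank of the focal tissue in the ascending ordering of one gene's row.

    rank = 1 + #{tissues strictly below} + #{tied tissues earlier in
    column order}; equivalently the focal position after a stable
    ascending sort.  Ranks lie in 1..T.
    """
    row = np.asarray(expr_row, dtype=float)
    if not (0 <= focal_index < row.size):
        raise IndexError(f"focal index {focal_index} outside 0..{row.size - 1}")
    if not np.all(np.isfinite(row)):
        raise ValueError("expression row contains non-finite values")
    focal = row[focal_index]
    below = int(np.sum(row < focal))
    tied_earlier = int(np.sum(row[:focal_index] == focal))
    return 1 + below + tied_earlier


def rank_all_genes(atlas: TissueAtlas, focal: str) -> pd.Series:
    """Focal-tissue rank for every atlas gene (vectorised rank_tissue)."""
    if focal not in atlas.tissues:
        raise KeyError(f"tissue {focal!r} not in atlas")
    values = atlas.matrix.values
    fi = atlas.tissues.index(focal)
    focal_col = values[:, fi : fi + 1]
    below = (values < focal_col).sum(axis=1)
    tied_earlier = (values[:, :fi] == focal_col).sum(axis=1)
    ranks = 1 + below + tied_earlier
    return pd.Series(ranks.astype(int), index=atlas.matrix.data.index, name=focal)


def _retained(atlas: TissueAtlas, gene_set) -> tuple[list[str], int]:
    if gene_set == "all":
        return list(atlas.matrix.data.index), 0
    genes = sorted(set(gene_set))
    present = [g for g in genes if g in atlas.matrix.data.index]
    n_dropped = len(genes) - len(present)
    if n_dropped:
        logger.info("gene set: %d genes absent from atlas, dropped", n_dropped)
    return present, n_dropped


def rank_distribution(atlas: TissueAtlas, focal: str, gene_set="all") -> pd.Series:
    """Histogram of focal-tissue ranks (index 1..T) for a gene set."""
    present, _ = _retained(atlas, gene_set)
    if not present:
        raise ValueError("no genes from the set are present in the atlas")
    ranks = rank_all_genes(atlas, focal).loc[present]
    counts = ranks.value_counts().reindex(range(1, atlas.n_tissues + 1), fill_value=0)
    counts.index.name = "rank"
    return counts


def ks_right_skew(set_ranks, background_ranks) -> tuple[float, float]:
    """Right-shift of set ranks against background ranks (one-sided KS)."""
    return stats_core.ks_one_sided(set_ranks, background_ranks)


def rank_skew(
    atlas: TissueAtlas, focal: str, gene_set, background="all"
) -> RankResult:
    """One-sided KS right-skew of a gene set's focal-tissue ranks."""
    present, _ = _retained(atlas, gene_set)
    if len(present) < 2:
        raise ValueError("need at least 2 set genes present in the atlas")
    bg_genes, _ = _retained(atlas, background)
    all_ranks = rank_all_genes(atlas, focal)
    set_ranks = all_ranks.loc[present]
    bg_ranks = all_ranks.loc[bg_genes]
    d_plus, p = ks_right_skew(set_ranks.to_numpy(), bg_ranks.to_numpy())
    return RankResult(
        focal_tissue=focal,
        ranks=dict(set_ranks),
        D_plus=d_plus,
        p_one_sided=p,
        rank_median_set=float(set_ranks.median()),
        rank_median_background=float(bg_ranks.median()),
    )


def per_tissue_scan(atlas: TissueAtlas, gene_set, background="all") -> pd.DataFrame:
    """Right-skew KS of the gene set against background, per focal tissue.

    Returns one row per tissue: tissue, label, D_plus, p_one_sided,
    neg_log10_p, rank medians.
    """
    present, _ = _retained(atlas, gene_set)
    if len(present) < 2:
        raise ValueError("need at least 2 set genes present in the atlas")
    rows = []
    for tissue in atlas.tissues:
        res = rank_skew(atlas, tissue, present, background)
        rows.append(
            {
                "tissue": tissue,
                "label": atlas.neural_labels[tissue],
                "D_plus": res.D_plus,
                "p_one_sided": res.p_one_sided,
                "neg_log10_p": -np.log10(res.p_one_sided),
                "rank_median_set": res.rank_median_set,
                "rank_median_background": res.rank_median_background,
            }
        )
    return pd.DataFrame(rows)


def neural_vs_nonneural(
    scan_table: pd.DataFrame, labels: Optional[Mapping[str, str]] = None
) -> tuple[float, float, float]:
    """Are neural tissues' scan p-values smaller than non-neural ones?

    One-sided Wilcoxon rank-sum (alternative: neural p's smaller).
    Returns (wilcoxon_p, neural_median_p, nonneural_median_p).
    """
    table = scan_table.copy()
    if labels is not None:
        table["label"] = table["tissue"].map(dict(labels))
    neural_p = table.loc[table["label"] == NEURAL, "p_one_sided"].to_numpy()
    other_p = table.loc[table["label"] == NON_NEURAL, "p_one_sided"].to_numpy()
    if neural_p.size == 0 or other_p.size == 0:
        raise ValueError("both neural and non-neural tissue classes must be non-empty")
    _, p = stats_core.wilcoxon_rank_sum(neural_p, other_p, alternative="less")
    return p, float(np.median(neural_p)), float(np.median(other_p))


def expressed_genes(
    atlas: TissueAtlas, samples: ExpressionMatrix, quantile: float = 0.10
) -> set[str]:
    """Atlas genes detected in the compared samples.

    A gene counts as expressed when at least one sample column exceeds
    the atlas-wide expression quantile (default 10th percentile); used to
    build the scan background from the samples under comparison.
    """
    threshold = float(np.quantile(atlas.matrix.values, quantile))
    shared = [g for g in samples.row_ids if g in atlas.matrix.data.index]
    detected = samples.data.loc[shared].max(axis=1) > threshold
    return set(detected.index[detected])
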