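"""Differential-expression hit selection for two-group (e.g. KO vs WT) arrays.

Per-row Welch's t test on log2-scale expression, Benjamini–Hochberg
adjustment over all variance-passing rows, and a three-part hit filter:
|log2 fold change| above ``log2(fold_threshold)``, adjusted p below
``alpha``, and *consistency* — every treatment column deviates from the
control group mean in the same direction as the overall fold change.
Probe-level hits collapse to gene sets; genes with discordant probe
directions are set aside rather than assigned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix
from . import stats_core

logger = logging.getLogger(__name__)

DEFAULT_FOLD_THRESHOLD = 10.0
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DiffHit:
    probe_id: str
    gene_id: str
    log2fc: float  # group_a minus group_b means on log2 scale
    p_raw: float
    p_adj: float
    direction: str  # "up" | "down"
    consistent: bool


@dataclass(frozen=True)
class GeneCollapse:
    up_genes: frozenset[str]
    down_genes: frozenset[str]
    up_probes: int
    down_probes: int
    discordant_genes: frozenset[str]


def _group_arrays(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    for name, cols in (("group_a", group_a), ("group_b", group_b)):
        if len(cols) < 2:
            raise ValueError(f"{name} needs at least 2 columns, got {len(cols)}")
        missing = set(cols) - set(matrix.col_ids)
        if missing:
            raise KeyError(f"{name}: columns not in matrix: {sorted(missing)}")
    a = matrix.data[list(group_a)].to_numpy(dtype=float)
    b = matrix.data[list(group_b)].to_numpy(dtype=float)
    return a, b


def welch_t_rows(
    matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Row-wise Welch's t (unequal variances) between two column groups.

    Returns a table indexed by row id with columns ``t`` and ``p_raw``.
    Rows where both groups are constant with identical means get p = 1;
    both constant with different means gives a vanishing p (flagged in
    the log).
    """
    a, b = _group_arrays(matrix, group_a, group_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    same_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    degenerate_equal = zero_var & same_mean
    degenerate_sep = zero_var & ~same_mean
    t[degenerate_equal] = 0.0
    p[degenerate_equal] = 1.0
    if degenerate_sep.any():
        logger.warning("welch_t_rows: %d rows have zero variance but unequal means", int(degenerate_sep.sum()))
        p[degenerate_sep] = np.finfo(float).tiny
        t[degenerate_sep] = np.sign(a.mean(axis=1) - b.mean(axis=1))[degenerate_sep] * np.inf
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"t": t, "p_raw": p}, index=matrix.data.index)


def select_hits(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    probe2gene: Optional[Mapping[str, str]] = None,
) -> list[DiffHit]:
    """Strong, significant, consistent hits of group_a vs group_b.

    The matrix must be log2 scale.  The BH family is all rows with
    non-zero overall variance (a minimal expression filter); a hit needs
    |log2fc| > log2(fold_threshold), BH-adjusted p < alpha, and every
    group_a column on the same side of the group_b mean as the overall
    fold change.
    """
    if matrix.scale != "log2":
        raise ValueError("select_hits requires a log2-scale matrix")
    a, b = _group_arrays(matrix, group_a, group_b)
    var_ok = np.concatenate([a, b], axis=1).std(axis=1) > 0
    tested_ids = matrix.data.index[var_ok]
    if not len(tested_ids):
        return []
    sub = ExpressionMatrix(
        data=matrix.data.loc[tested_ids], groups=matrix.groups, scale=matrix.scale
    )
    tt = welch_t_rows(sub, group_a, group_b)
    p_adj = stats_core.bh_adjust(tt["p_raw"].to_numpy())

    a, b = a[var_ok], b[var_ok]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    dev = a - b.mean(axis=1, keepdims=True)
    consistent = np.where(
        log2fc > 0, (dev > 0).all(axis=1), np.where(log2fc < 0, (dev < 0).all(axis=1), False)
    )
    lfc_cut = math.log2(fold_threshold)

    hits: list[DiffHit] = []
    for i, probe in enumerate(tested_ids):
        if abs(log2fc[i]) <= lfc_cut or p_adj[i] >= alpha or not consistent[i]:
            continue
        hits.append(
            DiffHit(
                probe_id=str(probe),
                gene_id=str(probe2gene[probe]) if probe2gene else str(probe),
                log2fc=float(log2fc[i]),
                p_raw=float(tt["p_raw"].iloc[i]),
                p_adj=float(p_adj[i]),
                direction="up" if log2fc[i] > 0 else "down",
                consistent=True,
            )
        )
    return hits


def collapse_to_genes(hits: Sequence[DiffHit], probe2gene: Mapping[str, str]) -> GeneCollapse:
    """Collapse probe-level hits to gene sets.

    A gene is up iff at least one of its probes is an up hit (likewise
    down); genes with probes in both directions are excluded and counted
    as discordant.
    """
    up_p = [h for h in hits if h.direction == "up"]
    down_p = [h for h in hits if h.direction == "down"]
    for h in hits:
        if h.probe_id not in probe2gene:
            raise KeyError(f"probe {h.probe_id!r} missing from probe-to-gene map")
    up_genes = {probe2gene[h.probe_id] for h in up_p}
    down_genes = {probe2gene[h.probe_id] for h in down_p}
    discordant = up_genes & down_genes
    if discordant:
        logger.info("collapse_to_genes: %d discordant genes excluded", len(discordant))
    return GeneCollapse(
        up_genes=frozenset(up_genes - discordant),
        down_genes=frozenset(down_genes - discordant),
        up_probes=len(up_p),
        down_probes=len(down_p),
        discordant_genes=frozenset(discordant),
    )


def median_position_summary(
    matrix: ExpressionMatrix,
    gene_set: set[str],
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[float, float, float, float]:
    """Where a gene set sits relative to the transcriptome median.

    Per gene, expression is the mean over group columns; the summary is
    the median over the gene set and over all matrix rows, per group.
    Returns (median_a, median_b, transcriptome_median_a, transcriptome_median_b).
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    missing = gene_set - set(matrix.row_ids)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
    mean_a = matrix.data[list(group_a)].mean(axis=1)
    mean_b = matrix.data[list(group_b)].mean(axis=1)
    genes = sorted(gene_set)
    return (
        float(mean_a.loc[genes].median()),
        float(mean_b.loc[genes].median()),
        float(mean_a.median()),
        float(mean_b.median()),
    )


def hits_table(hits: Sequence[DiffHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe_id": h.probe_id,
                "gene_id": h.gene_id,
                "log2fc": h.log2fc,
                "p_raw": h.p_raw,
                "p_adj": h.p_adj,
                "direction": h.direction,
            }
            for h in hits
        ],
        columns=["probe_id", "gene_id", "log2fc", "p_raw", "p_adj", "direction"],
    )
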