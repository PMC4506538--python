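"""AU-rich element (ARE) annotation of 3'UTRs and k-mer enrichment.

An ARE core is the pentamer ``AUUUA``; the destabilizing heptamer bound
by tristetraprolin (TTP/Zfp36) is ``UAUUUAU``, which typically occurs
inside a longer run of consecutive A/U bases.  A heptamer is called
*clustered* when it lies entirely inside a maximal A/U run of at least
``min_run`` nucleotides (default 12), otherwise *isolated*.  Motif
occurrences are counted at every start position (overlapping), so dense
tandem arrays such as ``UAUUUAUUUAU`` contribute each heptamer copy.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import UtrRecord, normalize_rna
from . import stats_core

logger = logging.getLogger(__name__)

PENTAMER = "AUUUA"
HEPTAMER = "UAUUUAU"
DEFAULT_MIN_RUN = 12
DEFAULT_GROUP_BOUNDARIES = (1, 3, 6)

_AU_RUN_RE = re.compile(r"[AU]+")


@dataclass(frozen=True)
class AuRun:
    """Maximal run of consecutive A/U bases, half-open sequence coordinates."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AreAnnotation:
    utr_id: str
    n_pentamer: int
    n_heptamer: int
    runs: tuple[AuRun, ...]
    n_clustered: int
    n_isolated: int


def count_motif(sequence: str, motif: str) -> int:
    """Count all (overlapping) occurrence start positions of motif."""
    if not motif:
        raise ValueError("motif must be non-empty")
    count = 0
    pos = sequence.find(motif)
    while pos != -1:
        count += 1
        pos = sequence.find(motif, pos + 1)
    return count


def _motif_positions(sequence: str, motif: str) -> list[int]:
    positions = []
    pos = sequence.find(motif)
    while pos != -1:
        positions.append(pos)
        pos = sequence.find(motif, pos + 1)
    return positions


def find_au_runs(sequence: str) -> list[AuRun]:
    """Maximal runs of {A,U}, left to right."""
    return [AuRun(m.start(), m.end()) for m in _AU_RUN_RE.finditer(sequence)]


def annotate_ares(utr: UtrRecord, min_run: int = DEFAULT_MIN_RUN) -> AreAnnotation:
    """Annotate AUUUA/UAUUUAU content of one 3'UTR.

    A UAUUUAU heptamer is clustered iff its 7-nt span lies inside a
    maximal A/U run of length >= ``min_run``.
    """
    seq = normalize_rna(utr.sequence)
    runs = find_au_runs(seq)
    hept_positions = _motif_positions(seq, HEPTAMER)
    n_clustered = 0
    long_runs = [r for r in runs if r.length >= min_run]
    for pos in hept_positions:
        # a heptamer is inside exactly the run covering its first base
        if any(r.start <= pos and pos + len(HEPTAMER) <= r.end for r in long_runs):
            n_clustered += 1
    n_heptamer = len(hept_positions)
    return AreAnnotation(
        utr_id=utr.utr_id,
        n_pentamer=count_motif(seq, PENTAMER),
        n_heptamer=n_heptamer,
        runs=tuple(runs),
        n_clustered=n_clustered,
        n_isolated=n_heptamer - n_clustered,
    )


def group_labels(boundaries: Sequence[int]) -> list[str]:
    """Human-readable bin labels for pentamer-count boundaries."""
    bounds = list(boundaries)
    labels = ["0"]
    for lo, hi in zip(bounds, bounds[1:]):
        labels.append(str(lo) if hi == lo + 1 else f"{lo}-{hi - 1}")
    labels.append(f">={bounds[-1]}")
    return labels


def group_by_pentamer_count(
    annotations: Iterable[AreAnnotation],
    boundaries: Sequence[int] = DEFAULT_GROUP_BOUNDARIES,
    id_of=lambda ann: ann.utr_id,
) -> dict[str, set[str]]:
    """Partition UTRs into pentamer-count bins [0], [b1,b2), ..., [b_last, inf).

    Default boundaries (1, 3, 6) give bins 0, 1-2, 3-5, >=6.  Empty bins
    are omitted from the returned map.
    """
    bounds = list(boundaries)
    if bounds != sorted(set(bounds)) or bounds[0] != 1:
        raise ValueError(f"boundaries must be strictly increasing and start at 1, got {bounds}")
    labels = group_labels(bounds)
    edges = [0] + bounds  # bin i covers [edges[i], edges[i+1])
    out: dict[str, set[str]] = {}
    for ann in annotations:
        idx = int(np.searchsorted(edges, ann.n_pentamer, side="right")) - 1
        out.setdefault(labels[idx], set()).add(id_of(ann))
    return out


def compare_motif_groups(
    log2fc: Mapping[str, float], groups: Mapping[str, set[str]]
) -> pd.DataFrame:
    """Two-sided KS comparison of log2 fold-change distributions between bins.

    Every grouped gene must have a fold-change value.  Pairs involving a
    group with fewer than two values are skipped with a warning.
    Returns a table with columns group_a, group_b, n_a, n_b, D, p.
    """
    values: dict[str, np.ndarray] = {}
    for label, genes in groups.items():
        missing = [g for g in genes if g not in log2fc]
        if missing:
            raise KeyError(f"group {label!r}: no log2fc for {sorted(missing)[:5]}")
        values[label] = np.asarray([log2fc[g] for g in sorted(genes)], dtype=float)
    rows = []
    for la, lb in itertools.combinations(sorted(values), 2):
        if len(values[la]) < 2 or len(values[lb]) < 2:
            logger.warning("compare_motif_groups: skipping (%s, %s), group too small", la, lb)
            continue
        d, p = stats_core.ks_two_sided(values[la], values[lb])
        rows.append({"group_a": la, "group_b": lb, "n_a": len(values[la]), "n_b": len(values[lb]), "D": d, "p": p})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "D", "p"])


# ---------------------------------------------------------------------------
# k-mer enrichment


def _kmer_rate_matrix(records: Sequence[UtrRecord], k: int) -> tuple[np.ndarray, list[str]]:
    """Per-record k-mer occurrence rates: count / (len - k + 1).

    Records shorter than k are excluded by the caller.
    """
    alphabet = "ACGU"
    kmers = ["".join(t) for t in itertools.product(alphabet, repeat=k)]
    index = {km: i for i, km in enumerate(kmers)}
    rates = np.zeros((len(records), len(kmers)))
    for ri, rec in enumerate(records):
        seq = rec.sequence
        n_windows = len(seq) - k + 1
        for j in range(n_windows):
            idx = index.get(seq[j : j + k])
            if idx is not None:
                rates[ri, idx] += 1
        rates[ri] /= n_windows
    return rates, kmers


def pentamer_enrichment(
    foreground: Sequence[UtrRecord],
    background: Sequence[UtrRecord],
    k: int = 5,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Label-permutation k-mer enrichment of foreground vs background UTRs.

    For each k-mer the statistic is the difference of mean per-UTR
    occurrence rates (count / (len - k + 1)) between the two sets.  The
    null is built by shuffling set labels ``n_perm`` times; z-scores are
    against the permutation null and ``p_perm = (1 + #{null >= obs}) /
    (n_perm + 1)``.  The table is sorted by z descending.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    fg = [r for r in foreground if len(r.sequence) >= k]
    bg = [r for r in background if len(r.sequence) >= k]
    if not fg or not bg:
        raise ValueError(f"all UTRs shorter than k={k}")
    n_fg, n_bg = len(fg), len(bg)
    rates, kmers = _kmer_rate_matrix(list(fg) + list(bg), k)
    obs = rates[:n_fg].mean(axis=0) - rates[n_fg:].mean(axis=0)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(kmers)))
    for p in range(n_perm):
        perm = rng.permutation(n_fg + n_bg)
        null[p] = rates[perm[:n_fg]].mean(axis=0) - rates[perm[n_fg:]].mean(axis=0)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (obs - null_mean) / null_sd, 0.0)
    p_perm = (1 + (null >= obs).sum(axis=0)) / (n_perm + 1)

    table = pd.DataFrame(
        {
            "kmer": kmers,
            "fg_freq": rates[:n_fg].mean(axis=0),
            "bg_freq": rates[n_fg:].mean(axis=0),
            "z": z,
            "p_perm": p_perm,
        }
    )
    return table.sort_values("z", ascending=False, kind="mergesort").reset_index(drop=True)


def annotation_table(annotations: Iterable[AreAnnotation]) -> pd.DataFrame:
    """Flatten annotations into a per-UTR table (TSV-writable)."""
    rows = [
        {
            "utr_id": a.utr_id,
            "n_pentamer": a.n_pentamer,
            "n_heptamer": a.n_heptamer,
            "n_clustered": a.n_clustered,
            "n_isolated": a.n_isolated,
            "n_au_runs": len(a.runs),
            "longest_au_run": max((r.length for r in a.runs), default=0),
        }
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=["utr_id", "n_pentamer", "n_heptamer", "n_clustered", "n_isolated", "n_au_runs", "longest_au_run"])
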