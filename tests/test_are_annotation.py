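"""ARE annotation against brute-force enumeration, plus grouping and enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aretools import are_annotation as are
from aretools.io_formats import UtrRecord

# ---------------------------------------------------------------------------
# independent brute-force oracles


def brute_count(seq: str, motif: str) -> int:
    return sum(seq[i : i + len(motif)] == motif for i in range(len(seq) - len(motif) + 1))


def brute_runs(seq: str) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, base in enumerate(seq):
        if base in "AU":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def brute_annotate(seq: str, min_run: int = 12) -> tuple[int, int, int]:
    """(n_pentamer, n_heptamer, n_clustered) by full enumeration."""
    runs = brute_runs(seq)
    n_clustered = 0
    for i in range(len(seq) - 6):
        if seq[i : i + 7] == "UAUUUAU":
            if any(s <= i and i + 7 <= e and e - s >= min_run for s, e in runs):
                n_clustered += 1
    return brute_count(seq, "AUUUA"), brute_count(seq, "UAUUUAU"), n_clustered


rna_seq = st.text(alphabet="ACGU", max_size=100)
au_rich_seq = st.text(alphabet="AUAUUACG", max_size=100)  # AU-weighted so motifs occur


class TestCountMotif:
    @pytest.mark.parametrize(
        "seq,motif,expected",
        [("AUUUA", "AUUUA", 1), ("AUUUAUUUA", "AUUUA", 2), ("GCGCGC", "AUUUA", 0)],
    )
    def test_frozen_examples(self, seq, motif, expected):
        assert are.count_motif(seq, motif) == expected

    def test_empty_motif_rejected(self):
        with pytest.raises(ValueError):
            are.count_motif("ACGU", "")

    @given(au_rich_seq)
    def test_overlapping_count_matches_sliding_window(self, seq):
        for motif in ("AUUUA", "UAUUUAU"):
            assert are.count_motif(seq, motif) == brute_count(seq, motif)


class TestAuRuns:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGAUUUAUGG", [(2, 8)]), ("", []), ("AUAU", [(0, 4)])],
    )
    def test_frozen_examples(self, seq, expected):
        assert [(r.start, r.end) for r in are.find_au_runs(seq)] == expected

    @given(au_rich_seq)
    def test_runs_maximal_and_match_brute_force(self, seq):
        runs = are.find_au_runs(seq)
        assert [(r.start, r.end) for r in runs] == brute_runs(seq)
        for r in runs:  # maximality
            assert r.start == 0 or seq[r.start - 1] not in "AU"
            assert r.end == len(seq) or seq[r.end] not in "AU"


class TestAnnotateAres:
    @pytest.mark.parametrize(
        "seq,n_hept,n_clust,n_iso",
        [
            ("UAUUUAUAUUUAU", 2, 2, 0),  # 13-nt all-AU run
            ("GGUAUUUAUGG", 1, 0, 1),  # 7-nt run, below the 12-nt threshold
            ("", 0, 0, 0),
        ],
    )
    def test_frozen_examples(self, seq, n_hept, n_clust, n_iso):
        ann = are.annotate_ares(UtrRecord("u", "u", seq))
        assert (ann.n_heptamer, ann.n_clustered, ann.n_isolated) == (n_hept, n_clust, n_iso)

    def test_min_run_parameter(self):
        seq = "GGUAUUUAUGG"
        assert are.annotate_ares(UtrRecord("u", "u", seq), min_run=7).n_clustered == 1

    @settings(max_examples=1000)
    @given(au_rich_seq)
    def test_matches_brute_force_enumeration(self, seq):
        ann = are.annotate_ares(UtrRecord("u", "u", seq))
        assert (ann.n_pentamer, ann.n_heptamer, ann.n_clustered) == brute_annotate(seq)
        assert ann.n_clustered + ann.n_isolated == ann.n_heptamer
        assert ann.n_heptamer <= ann.n_pentamer

    @given(au_rich_seq)
    def test_invariant_to_tu_spelling(self, seq):
        dna = seq.replace("U", "t")
        ann_rna = are.annotate_ares(UtrRecord("u", "u", seq))
        ann_dna = are.annotate_ares(UtrRecord("u", "u", dna))
        assert ann_rna == ann_dna


class TestGrouping:
    def _ann(self, utr_id, n):
        return are.AreAnnotation(utr_id, n, 0, (), 0, 0)

    def test_default_bins(self):
        groups = are.group_by_pentamer_count([self._ann("g1", 0), self._ann("g2", 7)])
        assert groups == {"0": {"g1"}, ">=6": {"g2"}}

    def test_count_one_lands_in_middle_bin(self):
        groups = are.group_by_pentamer_count([self._ann("g", 1)])
        assert groups == {"1-2": {"g"}}

    def test_empty_input(self):
        assert are.group_by_pentamer_count([]) == {}

    def test_unsorted_boundaries_rejected(self):
        with pytest.raises(ValueError):
            are.group_by_pentamer_count([], boundaries=(3, 1, 6))

    def test_bins_partition_all_counts(self):
        anns = [self._ann(f"g{i}", i) for i in range(20)]
        groups = are.group_by_pentamer_count(anns)
        all_ids = set().union(*groups.values())
        assert all_ids == {f"g{i}" for i in range(20)}
        assert groups["3-5"] == {"g3", "g4", "g5"}


class TestCompareGroups:
    def test_identical_groups_null(self):
        fc = {f"g{i}": float(i) for i in range(8)}
        groups = {"a": {"g0", "g1", "g2", "g3"}, "b": {"g4", "g5", "g6", "g7"}}
        fc.update({g: fc[f"g{i}"] for i, g in enumerate(["g4", "g5", "g6", "g7"])})
        table = are.compare_motif_groups(fc, groups)
        assert table.loc[0, "D"] == pytest.approx(0.0)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        fc = {"a1": 0.0, "a2": 0.0, "b1": 1.0, "b2": 1.0}
        table = are.compare_motif_groups(fc, {"A": {"a1", "a2"}, "B": {"b1", "b2"}})
        assert table.loc[0, "D"] == pytest.approx(1.0)

    def test_frozen_half_overlap(self):
        fc = dict(zip("abcdwxyz", [1, 2, 3, 4, 3, 4, 5, 6]))
        table = are.compare_motif_groups(fc, {"lo": set("abcd"), "hi": set("wxyz")})
        assert table.loc[0, "D"] == pytest.approx(0.5)

    def test_small_group_skipped(self, caplog):
        fc = {"a1": 0.0, "a2": 1.0, "b1": 2.0}
        table = are.compare_motif_groups(fc, {"A": {"a1", "a2"}, "B": {"b1"}})
        assert table.empty

    def test_missing_fold_change_rejected(self):
        with pytest.raises(KeyError):
            are.compare_motif_groups({}, {"A": {"a1", "a2"}})


class TestPentamerEnrichment:
    def _records(self, seqs, prefix):
        return [UtrRecord(f"{prefix}{i}", f"{prefix}{i}", s) for i, s in enumerate(seqs)]

    def test_label_exchange_null(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=60)) for _ in range(20)]
        recs = self._records(seqs, "u")
        table = are.pentamer_enrichment(recs, recs, n_perm=199, seed=5)
        # observed fg-bg difference is exactly 0, so z only reflects
        # permutation-null sampling noise and no k-mer can be significant
        assert table["z"].abs().max() < 1.0
        assert table["p_perm"].min() >= 1 / 200
        assert (table["p_perm"] < 0.05).sum() == 0

    def test_planted_are_recovery(self, rng):
        fg = self._records(["GC" + "UAUUUAU" * 5 + "GC" + "".join(rng.choice(list("ACGU"), size=30)) for _ in range(30)], "f")
        bg = self._records(["".join(rng.choice(list("GCGA"), size=60)) for _ in range(30)], "b")
        table = are.pentamer_enrichment(fg, bg, n_perm=199, seed=5)
        top = set(table["kmer"].head(10))
        assert {"UAUUU", "UUUAU", "AUUUA"} <= top

    def test_single_base_kmers_structural(self):
        recs = self._records(["AACCGGUU", "ACGUACGU"], "u")
        table = are.pentamer_enrichment(recs, recs, k=1, n_perm=100, seed=1)
        assert len(table) == 4 and np.all(np.isfinite(table["z"]))

    def test_seeded_reproducibility(self, rng):
        fg = self._records(["".join(rng.choice(list("ACGU"), size=40)) for _ in range(10)], "f")
        bg = self._records(["".join(rng.choice(list("ACGU"), size=40)) for _ in range(10)], "b")
        t1 = are.pentamer_enrichment(fg, bg, n_perm=150, seed=9)
        t2 = are.pentamer_enrichment(fg, bg, n_perm=150, seed=9)
        assert t1.equals(t2)

    def test_all_short_rejected(self):
        with pytest.raises(ValueError):
            are.pentamer_enrichment(self._records(["AUG"], "f"), self._records(["AUG"], "b"), k=5, n_perm=100)
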