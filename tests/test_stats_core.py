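"""stats_core against closed forms, enumeration and scipy/statsmodels oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from aretools import stats_core as sc

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


class TestEcdf:
    def test_step_values(self):
        f = sc.ecdf([1, 2, 3])
        assert f(2) == pytest.approx(2 / 3)
        assert f(0.5) == 0.0
        assert f(3) == 1.0

    def test_single_point(self):
        f = sc.ecdf([5.0])
        assert f(4.9) == 0.0 and f(5.0) == 1.0

    def test_monotone_on_random_queries(self, rng):
        f = sc.ecdf(rng.normal(size=40))
        q = np.sort(rng.uniform(-4, 4, size=1000))
        vals = f(q)
        assert np.all(np.diff(vals) >= 0)
        assert vals.min() >= 0 and vals.max() <= 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.ecdf([])


class TestKsTwoSided:
    @pytest.mark.parametrize(
        "a,b,expected_d",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 0.0),
            ([0, 0, 0, 0], [1, 1, 1, 1], 1.0),
            ([1, 2, 3, 4], [3, 4, 5, 6], 0.5),
        ],
    )
    def test_frozen_d(self, a, b, expected_d):
        d, p = sc.ks_two_sided(a, b)
        assert d == pytest.approx(expected_d)
        if expected_d == 0.0:
            assert p == pytest.approx(1.0)

    def test_d_matches_scipy_on_random_pairs(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 40))
            b = rng.normal(1, 2, size=rng.integers(2, 40))
            d, _ = sc.ks_two_sided(a, b)
            assert d == pytest.approx(sps.ks_2samp(a, b).statistic)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=25)
        assert sc.ks_two_sided(a, b) == sc.ks_two_sided(b, a)

    def test_type_one_error_calibration(self, rng):
        """Same-distribution samples of size 50 reject at 5% in <=7% of trials."""
        hits = 0
        for _ in range(1000):
            a, b = rng.normal(size=50), rng.normal(size=50)
            _, p = sc.ks_two_sided(a, b)
            hits += p < 0.05
        assert hits / 1000 <= 0.07

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            sc.ks_two_sided([1], [1, 2])


class TestKsOneSided:
    def test_identical_inputs(self):
        assert sc.ks_one_sided([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_right_shifted_set_detected(self, rng):
        d, p = sc.ks_one_sided(rng.normal(3, 1, 100), rng.normal(0, 1, 100))
        assert d > 0.5 and p < 1e-6

    def test_left_shifted_set_gives_zero(self, rng):
        d, p = sc.ks_one_sided(rng.normal(-3, 1, 100), rng.normal(0, 1, 100))
        assert d == 0.0 and p == 1.0

    def test_d_plus_matches_brute_force_sweep(self, rng):
        for _ in range(500):
            a = rng.normal(size=rng.integers(2, 20))
            b = rng.normal(0.5, 1.5, size=rng.integers(2, 20))
            d, _ = sc.ks_one_sided(a, b)
            points = np.concatenate([a, b])
            brute = max(
                float(np.mean(b <= x) - np.mean(a <= x)) for x in points
            )
            assert d == pytest.approx(max(brute, 0.0))

    def test_exponential_bound_formula(self):
        a = np.arange(10) + 5.0
        b = np.arange(20, dtype=float)
        d, p = sc.ks_one_sided(a, b)
        en = 10 * 20 / 30
        assert p == pytest.approx(np.exp(-2 * d * d * en))


class TestWilcoxon:
    def test_exact_two_sided_tiny(self):
        u, p = sc.wilcoxon_rank_sum([1, 2], [3, 4])
        assert u == 0 and p == pytest.approx(2 / 6)

    def test_identical_samples_two_sided(self):
        _, p = sc.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.5, 2.5, 0.5])
        assert p > 0.5

    def test_exact_matches_scipy(self, rng):
        for alt in ("two-sided", "less", "greater"):
            for _ in range(30):
                x = rng.normal(size=int(rng.integers(2, 10)))
                y = rng.normal(size=int(rng.integers(2, 10)))
                u, p = sc.wilcoxon_rank_sum(x, y, alternative=alt)
                ref = sps.mannwhitneyu(x, y, alternative=alt, method="exact")
                assert u == pytest.approx(ref.statistic)
                assert p == pytest.approx(ref.pvalue)

    def test_exact_and_normal_branches_agree(self, rng):
        """Tie-free size-10+10 cases: exact vs normal approximation within 0.02."""
        for _ in range(200):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            _, p_exact = sc.wilcoxon_rank_sum(x, y)  # pooled size 20 -> exact branch
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert abs(p_exact - ref.pvalue) <= 0.02

    def test_pmf_total_mass(self):
        for n, m in [(3, 5), (7, 7), (10, 10)]:
            pmf = sc._mann_whitney_pmf(n, m)
            assert pmf.sum() == pytest.approx(1.0)
            assert len(pmf) == n * m + 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.wilcoxon_rank_sum([], [1.0])


class TestBhAdjust:
    def test_frozen_example(self):
        assert sc.bh_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_singleton_identity(self):
        assert sc.bh_adjust([0.5]) == pytest.approx([0.5])

    def test_matches_statsmodels(self, rng):
        p = rng.uniform(size=200)
        ours = sc.bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_output_dominates_input_and_capped(self, p):
        out = sc.bh_adjust(p)
        assert np.all(out >= np.asarray(p) - 1e-15)
        assert np.all(out <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sc.bh_adjust([0.5, 1.5])


class TestPearson:
    def test_perfect_linear(self):
        assert sc.pearson_r([1, 2, 3], [3, 5, 7]) == pytest.approx(1.0)
        assert sc.pearson_r([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_matches_two_pass_definition(self, rng):
        x, y = rng.normal(size=100), rng.normal(size=100)
        expected = float(np.corrcoef(x, y)[0, 1])
        assert sc.pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            sc.pearson_r([1, 1, 1], [1, 2, 3])
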