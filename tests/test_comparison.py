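"""Passing-Bablok regression, Cusum linearity, Spearman and outlier screens."""

import numpy as np
import pytest
from scipy import stats

from glycoval import (ComparisonSimConfig, PairedDataset, PassingBablok,
                      UnitSystem, cusum_linearity, generalized_esd,
                      grubbs_two_sided, normality_test, simulate_comparison,
                      spearman_with_ci, tukey_outliers)
from glycoval.comparison import _slope_intercept

from conftest import make_pairs


def brute_force_pb(x, y):
    """Literal transcription of the shifted-median procedure with loops."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                slopes.append(float("inf") if dy > 0 else float("-inf"))
            else:
                slopes.append(dy / dx)
    slopes = sorted(s for s in slopes if s != -1.0)
    k = sum(1 for s in slopes if s < -1.0)
    m = len(slopes)
    if m % 2 == 1:
        b = slopes[min((m - 1) // 2 + k, m - 1)]
    else:
        b = 0.5 * (slopes[min(m // 2 - 1 + k, m - 1)]
                   + slopes[min(m // 2 + k, m - 1)])
    a = float(np.median(np.asarray(y) - b * np.asarray(x)))
    return b, a


class TestPassingBablok:
    def test_identity_line(self):
        res = PassingBablok(make_pairs([1, 2, 3], [1, 2, 3])).fit()
        assert res.slope == 1.0
        assert res.intercept == 0.0

    def test_exact_line_slope2_intercept1(self):
        res = PassingBablok(make_pairs([1, 2, 3], [3, 5, 7])).fit()
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_noise_free_line_has_zero_width_ci(self):
        x = np.linspace(30, 73, 15)
        res = PassingBablok(make_pairs(x, 0.95 * x + 2)).fit()
        assert res.slope_ci == (pytest.approx(0.95), pytest.approx(0.95))
        assert res.intercept_ci[0] == pytest.approx(2.0)
        assert res.intercept_ci[1] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        x = rng.uniform(30, 73, n)
        y = 0.9 * x + 2 + rng.normal(0, 1.5, n)
        b_ref, a_ref = brute_force_pb(list(x), list(y))
        res = PassingBablok(make_pairs(x, y)).fit()
        assert res.slope == pytest.approx(b_ref, rel=1e-12)
        assert res.intercept == pytest.approx(a_ref, rel=1e-12)

    @pytest.mark.parametrize("scale", [0.09148, 3.7])
    def test_scale_equivariance(self, scale):
        ds = simulate_comparison(ComparisonSimConfig(n=40, seed=11))
        res = PassingBablok(ds).fit()
        scaled = make_pairs(scale * ds.x, scale * ds.y)
        res_s = PassingBablok(scaled).fit()
        assert res_s.slope == pytest.approx(res.slope, rel=1e-10)
        assert res_s.intercept == pytest.approx(scale * res.intercept, rel=1e-10)

    def test_swap_axes_inverts_slope(self):
        ds = simulate_comparison(ComparisonSimConfig(n=60, seed=5))
        res = PassingBablok(ds).fit()
        res_sw = PassingBablok(make_pairs(ds.y, ds.x)).fit()
        assert res_sw.slope == pytest.approx(1.0 / res.slope, rel=1e-9)
        assert res_sw.intercept == pytest.approx(
            -res.intercept / res.slope, rel=1e-6)

    def test_fast_point_estimate_equals_full_fit(self):
        ds = simulate_comparison(ComparisonSimConfig(n=97, seed=8))
        b, a = _slope_intercept(ds.x, ds.y)
        res = PassingBablok(ds).fit()
        assert (b, a) == (res.slope, res.intercept)

    def test_parameter_recovery_at_study_size(self):
        """Slope CI covers 1.00 and intercept CI covers -1.00 in >=90% of
        seeded study-sized datasets (n=178, 2% CV, true line y = x - 1)."""
        hits = 0
        n_seeds = 300
        for seed in range(n_seeds):
            ds = simulate_comparison(ComparisonSimConfig(seed=seed))
            res = PassingBablok(ds).fit()
            ok_slope = res.slope_ci[0] <= 1.0 <= res.slope_ci[1]
            ok_int = res.intercept_ci[0] <= -1.0 <= res.intercept_ci[1]
            hits += ok_slope and ok_int
        assert hits / n_seeds >= 0.90

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            PassingBablok(make_pairs([2, 2, 2], [1, 2, 3]))
        with pytest.raises(ValueError):
            PassingBablok(make_pairs([1, 2], [1, 2]))

    def test_predict_and_summary(self):
        res = PassingBablok(make_pairs([1, 2, 3], [3, 5, 7])).fit()
        assert res.predict(10.0) == pytest.approx(21.0)
        assert "slope" in res.summary()


class TestCusumLinearity:
    def test_perfectly_linear_data(self):
        res = PassingBablok(make_pairs([1, 2, 3, 4], [2, 4, 6, 8])).fit()
        assert res.cusum_statistic == 0.0
        assert res.cusum_p == 1.0

    def test_strong_curvature_rejected(self):
        x = np.arange(1, 51.0)
        res = PassingBablok(make_pairs(x, x ** 2)).fit()
        assert res.cusum_p < 0.05

    def test_asymptotic_p_matches_permutation_oracle(self):
        """The Kolmogorov-tail p-value agrees with a permutation oracle of
        the same cusum statistic on curved mid-size data."""
        x = np.arange(1, 21.0)
        y = x ** 2
        ds = make_pairs(x, y)
        b, a = _slope_intercept(ds.x, ds.y)
        stat, p_asym = cusum_linearity(ds, b, a)
        resid = y - a - b * x
        n_above, n_below = int((resid > 0).sum()), int((resid < 0).sum())
        scores = np.where(resid > 0, np.sqrt(n_below / n_above),
                          np.where(resid < 0, -np.sqrt(n_above / n_below), 0.0))
        rng = np.random.default_rng(0)
        perm = np.array([
            np.max(np.abs(np.cumsum(rng.permutation(scores))))
            / np.sqrt(n_above + n_below)
            for _ in range(4000)
        ])
        p_perm = float((perm >= stat - 1e-12).mean())
        assert p_asym == pytest.approx(p_perm, abs=0.04)

    def test_not_anticonservative_on_linear_noisy_data(self):
        """On truly linear data the test should reject at no more than the
        nominal rate (it is conservative because the line is fitted)."""
        rejections = 0
        n_seeds = 150
        for seed in range(n_seeds):
            ds = simulate_comparison(ComparisonSimConfig(n=100, seed=seed))
            if PassingBablok(ds).fit().cusum_p < 0.05:
                rejections += 1
        assert rejections / n_seeds <= 0.05


class TestSpearman:
    def test_monotone_pairs_give_unity(self):
        rho, lo, hi = spearman_with_ci(make_pairs([1, 2, 3, 4], [10, 20, 30, 41]))
        assert rho == 1.0

    def test_hand_ranked_example(self):
        # ranks x (1,2,3,4), y (2,1,4,3): sum d^2 = 4 -> rho = 1 - 24/60
        data = make_pairs([1, 2, 3, 4], [2, 1, 4, 3])
        rho, lo, hi = spearman_with_ci(data)
        assert rho == pytest.approx(0.6)
        assert rho == pytest.approx(stats.spearmanr(data.x, data.y).statistic)
        assert lo <= rho <= hi

    def test_study_sized_simulation_gives_strong_correlation(self):
        ds = simulate_comparison(ComparisonSimConfig(seed=3))
        rho, lo, hi = spearman_with_ci(ds)
        assert 0.97 <= rho <= 1.0
        assert hi - lo < 0.03

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            spearman_with_ci(make_pairs([1, 1, 1, 1], [1, 2, 3, 4]))


class TestOutlierScreens:
    def test_tukey_flags_gross_outlier(self):
        rep = tukey_outliers([1, 2, 3, 4, 100])
        assert rep.flagged_indices == (4,)

    def test_grubbs_flags_at_most_one(self):
        rng = np.random.default_rng(1)
        v = np.append(rng.normal(0, 1, 30), 8.0)
        rep = grubbs_two_sided(v)
        assert rep.flagged_indices == (30,)
        clean = grubbs_two_sided(rng.normal(0, 1, 30))
        assert len(clean.flagged_indices) <= 1

    @pytest.mark.parametrize("seed", range(6))
    def test_gesd_with_k1_agrees_with_grubbs(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 1, 25)
        if seed % 2:
            v[0] = 6.0
        assert (generalized_esd(v, max_k=1).flagged_indices
                == grubbs_two_sided(v).flagged_indices)

    def test_gesd_finds_exactly_the_planted_outliers(self):
        rng = np.random.default_rng(7)
        v = rng.normal(50, 1, 40)
        v[5] += 8.0
        v[17] -= 8.0
        rep = generalized_esd(v, max_k=3)
        assert rep.flagged_indices == (5, 17)

    def test_clean_normal_sample_rarely_flagged(self):
        rng = np.random.default_rng(2)
        none_flagged = 0
        for _ in range(50):
            v = rng.normal(0, 1, 178)
            if not generalized_esd(v, max_k=5).flagged_indices:
                none_flagged += 1
        assert none_flagged >= 40

    def test_normality_contract(self):
        w, p = normality_test(np.random.default_rng(0).normal(0, 1, 60))
        assert 0 <= w <= 1 and 0 <= p <= 1
        with pytest.raises(ValueError):
            normality_test([3.0, 3.0, 3.0, 3.0])
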