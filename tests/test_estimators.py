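"""The five causal estimators against independent oracles and invariants."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrmediate import (egger, ivw, mode_estimate, pval_from_estimate,
                       to_odds_ratio, wald_ratio, weighted_median)
from mrmediate.estimators import _kde_argmax, _mode_bandwidth, _weighted_median
from tests.conftest import make_harmonized, random_harmonized


class TestWaldRatio:
    @pytest.mark.parametrize("bx,by,sy,beta,se", [
        (0.5, 0.1, 0.05, 0.2, 0.1),
        (0.5, 0.0, 0.05, 0.0, 0.1),
        (-0.5, 0.1, 0.05, -0.2, 0.1),
    ])
    def test_definitional_arithmetic(self, bx, by, sy, beta, se):
        est = wald_ratio(bx, 0.01, by, sy)
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_zero_exposure_effect_fatal(self):
        with pytest.raises(ValueError):
            wald_ratio(0.0, 0.01, 0.1, 0.05)


class TestIvw:
    def test_equal_weights_give_mean_of_ratios(self):
        h = make_harmonized([1.0, 1.0], 0.01, [0.1, 0.3], 1.0)
        assert ivw(h, model="fixed").beta == pytest.approx(0.2)

    def test_matches_weighted_least_squares_oracle(self, rng):
        for _ in range(10):
            h = random_harmonized(rng, k=15, beta=rng.normal(0, 0.5), noise=1.0)
            d = h.data
            fit = sm.WLS(d["beta_y"], d[["beta_x"]], weights=d["se_y"] ** -2).fit()
            assert ivw(h, model="fixed").beta == pytest.approx(fit.params.iloc[0], rel=1e-10)

    def test_single_instance_parameter_recovery(self, rng):
        # 50 clean instruments around a true ratio of 0.30
        h = random_harmonized(rng, k=50, beta=0.30, noise=1.0)
        est = ivw(h)
        assert abs(est.beta - 0.30) < 3 * est.se

    def test_k_below_two_directs_to_wald_ratio(self):
        h = make_harmonized([0.5], 0.01, [0.1], 0.05)
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(h)


class TestEgger:
    def test_matches_weighted_regression_oracle(self, rng):
        for _ in range(10):
            h = random_harmonized(rng, k=15, beta=0.3, noise=1.0)
            est, intercept, _, _ = egger(h)
            d = h.data
            sign = np.where(d["beta_x"] < 0, -1.0, 1.0)
            bx, by = d["beta_x"] * sign, d["beta_y"] * sign
            fit = sm.WLS(by, sm.add_constant(bx), weights=d["se_y"] ** -2).fit()
            assert intercept == pytest.approx(fit.params.iloc[0], rel=1e-10, abs=1e-12)
            assert est.beta == pytest.approx(fit.params.iloc[1], rel=1e-10)

    def test_recovers_injected_directional_pleiotropy(self, rng):
        # alpha = 0.02 added to every outcome effect, true causal effect 0
        k, alpha = 100, 0.02
        bx = rng.uniform(0.05, 0.3, k)
        sy = np.full(k, 0.01)
        by = alpha + rng.normal(0, sy)
        est, intercept, intercept_se, _ = egger(make_harmonized(bx, 0.001, by, sy))
        assert abs(intercept - alpha) < 3 * intercept_se
        assert abs(est.beta) < 3 * est.se

    def test_intercept_pvalue_calibrated_without_pleiotropy(self):
        rng = np.random.default_rng(7)
        k, reps, rejections = 30, 2000, 0
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.3, k)
            sy = rng.uniform(0.01, 0.05, k)
            by = 0.2 * bx + rng.normal(0, sy)
            _, _, _, p = egger(make_harmonized(bx, 0.001, by, sy))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_k_below_three_errors_naming_minimum(self):
        h = make_harmonized([0.1, 0.2], 0.01, [0.0, 0.0], 0.05)
        with pytest.raises(ValueError, match="3"):
            egger(h)


class TestWeightedMedian:
    def test_equal_weight_median_is_outlier_immune(self):
        h = make_harmonized([1.0, 1.0, 1.0], 0.01, [0.1, 0.2, 0.9], 1.0)
        assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.2)

    def test_matches_cumulative_weight_scan_oracle(self, rng):
        def scan(r, w):
            order = np.argsort(r)
            r, w = np.asarray(r)[order], np.asarray(w)[order]
            w = w / w.sum()
            s = np.cumsum(w) - 0.5 * w
            below = max(i for i in range(len(s)) if s[i] < 0.5)
            return r[below] + (r[below + 1] - r[below]) * (0.5 - s[below]) / (s[below + 1] - s[below])

        for _ in range(20):
            h = random_harmonized(rng, k=11, beta=0.3, noise=2.0)
            d = h.data
            r = (d["beta_y"] / d["beta_x"]).to_numpy()
            w = (d["beta_x"] / d["se_y"]).to_numpy() ** 2
            est = weighted_median(h, n_boot=10, seed=1)
            assert est.beta == pytest.approx(scan(r, w), rel=1e-10)

    def test_breakdown_robustness_under_49pct_pleiotropy(self, rng):
        # 25 of 51 equally-weighted instruments shifted (49% of the weight
        # invalid): the median stays near truth while IVW is dragged away
        k = 51
        bx = np.full(k, 0.2)
        sy = np.full(k, 0.002)
        by = 0.3 * bx + rng.normal(0, sy)
        by[:25] += 0.5 * bx[:25]
        h = make_harmonized(bx, 0.001, by, sy)
        est = weighted_median(h, n_boot=200, seed=3)
        assert abs(est.beta - 0.3) < 3 * max(est.se, 0.002 / 0.2)
        assert abs(est.beta - 0.3) < abs(ivw(h).beta - 0.3)


class TestModes:
    def test_identical_ratios_return_common_ratio(self):
        h = make_harmonized([0.2, 0.4, 0.8], 0.01, [0.05, 0.1, 0.2], 0.02)
        with pytest.warns(UserWarning, match="identical"):
            est = mode_estimate(h, weighted=False, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.25)
        assert est.se == 0.0

    def test_mode_not_pulled_by_gross_outlier(self):
        h = make_harmonized([1.0] * 4, 0.01, [0.2, 0.21, 0.19, 5.0], 0.05)
        est = mode_estimate(h, weighted=False, n_boot=10, seed=0)
        assert abs(est.beta - 0.2) < 0.05

    def test_argmax_matches_exhaustive_grid_oracle(self, rng):
        for _ in range(20):
            h = random_harmonized(rng, k=9, beta=0.3, noise=2.0)
            d = h.data
            r = (d["beta_y"] / d["beta_x"]).to_numpy()
            w = (d["beta_x"] / d["se_y"]).to_numpy() ** 2
            bw = _mode_bandwidth(r, 1.0)
            # independent dense evaluation, explicit loops
            grid = np.linspace(r.mean() - 5 * r.std(ddof=1),
                               r.mean() + 5 * r.std(ddof=1), 10_000)
            dens = np.zeros_like(grid)
            for j in range(len(r)):
                dens += (w[j] / w.sum()) * np.exp(-0.5 * ((grid - r[j]) / bw) ** 2)
            expected = grid[np.argmax(dens)]
            est = mode_estimate(h, weighted=True, n_boot=10, seed=0)
            assert est.beta == pytest.approx(expected, rel=1e-10)


class TestScaleConversions:
    def test_null_effect_gives_centered_unit_or(self):
        o, lo, hi = to_odds_ratio(0.0, 0.1)
        assert o == 1.0 and lo < 1.0 < hi
        assert lo * hi == pytest.approx(1.0)

    def test_reproduces_published_style_interval(self):
        # OR 1.901 with se back-computed from a 95% CI of [1.215, 2.972]
        o, lo, hi = to_odds_ratio(np.log(1.901), 0.22819, 0.95)
        assert o == pytest.approx(1.901, abs=5e-4)
        assert lo == pytest.approx(1.215, abs=2e-3)
        assert hi == pytest.approx(2.973, abs=2e-3)

    def test_pval_identities(self):
        assert pval_from_estimate(0.0, 1.0) == pytest.approx(1.0)
        assert pval_from_estimate(1.959964, 1.0) == pytest.approx(0.05, abs=1e-6)


class TestEstimatorInvariants:
    def _all_betas(self, h, seed=0):
        return {
            "ivw": ivw(h).beta,
            "egger": egger(h)[0].beta,
            "wmed": weighted_median(h, n_boot=10, seed=seed).beta,
            "wmode": mode_estimate(h, True, n_boot=10, seed=seed).beta,
            "smode": mode_estimate(h, False, n_boot=10, seed=seed).beta,
        }

    def test_scale_equivariance_in_exposure(self, rng):
        h = random_harmonized(rng, k=12, beta=0.3, noise=1.0)
        c = 2.5
        hs = make_harmonized(h.data["beta_x"] * c, h.data["se_x"] * c,
                             h.data["beta_y"], h.data["se_y"])
        a, b = self._all_betas(h), self._all_betas(hs)
        for key in a:
            assert b[key] == pytest.approx(a[key] / c, rel=1e-9), key

    def test_sign_equivariance_in_outcome(self, rng):
        h = random_harmonized(rng, k=12, beta=0.3, noise=1.0)
        hn = make_harmonized(h.data["beta_x"], h.data["se_x"],
                             -h.data["beta_y"], h.data["se_y"])
        a, b = self._all_betas(h), self._all_betas(hn)
        for key in a:
            assert b[key] == pytest.approx(-a[key], rel=1e-9, abs=1e-12), key

    def test_noise_free_single_ratio_recovered_exactly(self, rng):
        bx = rng.uniform(0.1, 0.4, 10)
        h = make_harmonized(bx, 0.01, 0.37 * bx, 0.02)
        with pytest.warns(UserWarning):
            modes = [mode_estimate(h, w, n_boot=5, seed=0).beta for w in (True, False)]
        vals = [ivw(h).beta, egger(h)[0].beta,
                weighted_median(h, n_boot=5, seed=0).beta, *modes]
        np.testing.assert_allclose(vals, 0.37, rtol=1e-9)
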