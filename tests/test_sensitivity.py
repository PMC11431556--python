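"""Heterogeneity, pleiotropy, leave-one-out and MR-PRESSO diagnostics."""

import numpy as np
import pytest

from mrmediate import (cochran_q, egger, egger_intercept_test, ivw,
                       leave_one_out, mr_presso, sensitivity_report)
from tests.conftest import make_harmonized, random_harmonized


class TestCochranQ:
    def test_collinear_noise_free_data_gives_zero_q(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_harmonized(bx, 0.01, 0.5 * bx, 0.02)
        q, df, p = cochran_q(h, "ivw")
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 3
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("method,dof_offset", [("ivw", 1), ("egger", 2)])
    def test_matches_explicit_residual_loop(self, rng, method, dof_offset):
        for _ in range(10):
            h = random_harmonized(rng, k=12, beta=0.3, noise=2.0)
            q, df, _ = cochran_q(h, method)
            assert df == h.k - dof_offset
            d = h.data
            bx, by = d["beta_x"].to_numpy(), d["beta_y"].to_numpy()
            w = d["se_y"].to_numpy() ** -2.0
            if method == "ivw":
                beta = np.sum(bx * by * w) / np.sum(bx * bx * w)
                resid = by - beta * bx
            else:
                est, intercept, _, _ = egger(h)
                sign = np.where(bx < 0, -1.0, 1.0)
                resid = by * sign - intercept - est.beta * bx * sign
            expected = sum(w[j] * resid[j] ** 2 for j in range(h.k))
            assert q == pytest.approx(expected, rel=1e-10)

    def test_rejection_rate_calibrated_under_homogeneity(self):
        rng = np.random.default_rng(11)
        reps, rej = 2000, 0
        for _ in range(reps):
            bx = rng.uniform(0.05, 0.3, 25)
            sy = rng.uniform(0.01, 0.05, 25)
            by = 0.25 * bx + rng.normal(0, sy)
            rej += cochran_q(make_harmonized(bx, 0.001, by, sy), "ivw")[2] < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_row_order_invariance(self, rng):
        h = random_harmonized(rng, k=10, beta=0.3, noise=2.0)
        hp = h.subset(list(rng.permutation(10)))
        assert cochran_q(h, "ivw")[0] == pytest.approx(cochran_q(hp, "ivw")[0], rel=1e-12)


class TestEggerIntercept:
    def test_balanced_pleiotropy_centres_on_zero(self, rng):
        k = 100
        bx = rng.uniform(0.05, 0.3, k)
        sy = np.full(k, 0.01)
        alpha = rng.choice([-0.05, 0.05], k)  # balanced: mean zero
        by = 0.2 * bx + alpha + rng.normal(0, sy)
        intercept, se, _ = egger_intercept_test(make_harmonized(bx, 0.001, by, sy))
        assert abs(intercept) < 3 * se

    def test_directional_pleiotropy_recovered(self, rng):
        k = 100
        bx = rng.uniform(0.05, 0.3, k)
        sy = np.full(k, 0.01)
        by = 0.2 * bx + 0.05 + rng.normal(0, sy)
        intercept, se, p = egger_intercept_test(make_harmonized(bx, 0.001, by, sy))
        assert abs(intercept - 0.05) < 3 * se
        assert p < 0.001


class TestLeaveOneOut:
    def test_k_entries_and_stability_on_homogeneous_data(self, rng):
        h = random_harmonized(rng, k=15, beta=0.3, noise=0.5)
        loo = leave_one_out(h)
        assert len(loo) == h.k
        assert not any(flag for _, _, flag in loo)

    def test_gross_outlier_omission_flagged_with_largest_shift(self, rng):
        bx = rng.uniform(0.1, 0.3, 12)
        sy = np.full(12, 0.01)
        by = 0.3 * bx + rng.normal(0, sy)
        by[4] += 1.0  # gross pleiotropic outlier
        h = make_harmonized(bx, 0.001, by, sy)
        # fixed-effect fit: the outlier inflates the random-effects CI so much
        # that the stability check would never fire
        full = ivw(h, model="fixed").beta
        loo = leave_one_out(h, ivw_model="fixed")
        deltas = [abs(est.beta - full) for _, est, _ in loo]
        assert int(np.argmax(deltas)) == 4
        assert loo[4][2]  # flagged


class TestMrPresso:
    def test_injected_outlier_detected_and_correction_reduces_bias(self, rng):
        bx = rng.uniform(0.1, 0.3, 20)
        sy = np.full(20, 0.01)
        by = 0.3 * bx + rng.normal(0, sy)
        by[7] += 10 * sy[7] * 5  # far beyond the null residual scale
        h = make_harmonized(bx, 0.001, by, sy)
        g, outliers, corrected = mr_presso(h, n_sim=1000, seed=5)
        assert g < 0.05
        assert "rs8" in outliers
        naive = ivw(h).beta
        assert abs(corrected.beta - 0.3) < abs(naive - 0.3)

    def test_seeded_runs_are_bit_reproducible(self, rng):
        h = random_harmonized(rng, k=10, beta=0.3, noise=2.0)
        a = mr_presso(h, n_sim=300, seed=42)
        b = mr_presso(h, n_sim=300, seed=42)
        assert a[0] == b[0] and a[1] == b[1]

    def test_minimum_instrument_count_enforced(self, rng):
        h = random_harmonized(rng, k=3, beta=0.3)
        with pytest.raises(ValueError, match="4"):
            mr_presso(h, n_sim=100, seed=0)

    def test_small_n_sim_warns(self, rng):
        h = random_harmonized(rng, k=6, beta=0.3)
        with pytest.warns(UserWarning, match="n_sim"):
            mr_presso(h, n_sim=50, seed=0)


def test_sensitivity_report_assembles_full_battery(rng):
    h = random_harmonized(rng, k=10, beta=0.3, noise=1.0)
    rep = sensitivity_report(h, n_sim=200, seed=1)
    assert rep.q_ivw_df == 9 and rep.q_egger_df == 8
    assert rep.q_ivw >= 0
    assert len(rep.loo) == 10
    assert rep.presso_global_pval is not None
    assert rep.egger_intercept_pval is not None
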