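"""MR estimators against closed forms, generic WLS oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import mrchain as mc
from mrchain.estimators import Z95, _weighted_median_point, _mode_point

from conftest import make_harmonized


def wls_oracle(X, y, w):
    """Textbook weighted least squares: coefficients and unscaled covariance."""
    Xw = X * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    cov = np.linalg.inv(Xw.T @ Xw)
    resid = yw - Xw @ beta
    dof = X.shape[0] - X.shape[1]
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    return beta, np.sqrt(np.diag(cov)), s2


class TestWaldRatios:
    @pytest.mark.parametrize("bx,by,se_y,ratio,ratio_se", [
        (0.1, 0.05, 0.02, 0.5, 0.2),
        (-0.1, 0.05, 0.02, -0.5, 0.2),
        (0.1, 0.0, 0.02, 0.0, 0.2),
    ])
    def test_first_order_delta(self, bx, by, se_y, ratio, ratio_se):
        h = make_harmonized([bx, 0.2], [by, 0.1], [se_y, 0.05])
        r, s = mc.wald_ratios(h)
        assert r[0] == pytest.approx(ratio)
        assert s[0] == pytest.approx(ratio_se)

    def test_zero_exposure_effect_names_variant(self):
        h = make_harmonized([0.0, 0.2], [0.1, 0.1], [0.02, 0.02])
        with pytest.raises(mc.DegenerateInstrumentError, match="rs1"):
            mc.wald_ratios(h)


class TestIVW:
    def test_two_variant_closed_form(self):
        h = make_harmonized([0.2, 0.4], [0.1, 0.1], [0.1, 0.1])
        est, q = mc.ivw(h, mode="fixed")
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(1 / np.sqrt(20.0), abs=1e-10)

    def test_matches_wls_through_origin(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.4 * bx + rng.normal(0, 0.02, 8)
        se_y = rng.uniform(0.01, 0.05, 8)
        h = make_harmonized(bx, by, se_y)
        est, q = mc.ivw(h, mode="fixed")
        beta, base_se, s2 = wls_oracle(bx[:, None], by, 1 / se_y**2)
        assert est.beta == pytest.approx(beta[0], abs=1e-10)
        assert est.se == pytest.approx(base_se[0], abs=1e-10)
        # Q is the weighted RSS of that regression
        assert q.Q == pytest.approx(s2 * (len(bx) - 1), abs=1e-8)

    def test_single_variant_reduces_to_wald_ratio(self):
        h = make_harmonized([0.2], [0.1], [0.05])
        est, q = mc.ivw(h)
        assert est.beta == pytest.approx(0.5)
        assert (q.Q, q.df) == (0.0, 0)
        assert np.isnan(q.pval)

    def test_homogeneous_ratios_have_zero_q(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.05, 0.1, 0.2],
                            [0.05, 0.05, 0.05])
        est_r, q = mc.ivw(h, mode="random")
        est_f, _ = mc.ivw(h, mode="fixed")
        assert q.Q == pytest.approx(0.0, abs=1e-12)
        assert est_r.se == est_f.se

    def test_random_se_at_least_fixed_iff_q_exceeds_df(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            bx = rng.uniform(0.05, 0.3, 6)
            by = 0.3 * bx + rng.normal(0, 0.05, 6)
            h = make_harmonized(bx, by, rng.uniform(0.01, 0.05, 6))
            fixed, q = mc.ivw(h, mode="fixed")
            random_, _ = mc.ivw(h, mode="random")
            assert random_.se >= fixed.se
            assert (random_.se == fixed.se) == (q.Q <= q.df)

    def test_empty_set_rejected(self):
        h = make_harmonized([], [], [])
        with pytest.raises(mc.DataError):
            mc.ivw(h)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.01 + 0.3 * bx
        h = make_harmonized(bx, by, [0.05] * 4)
        slope, intercept = mc.mr_egger(h)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.intercept == pytest.approx(0.01, abs=1e-12)

    def test_matches_generic_wls_with_intercept(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = np.array([0.05, 0.07, 0.13])
        se_y = np.array([0.1, 0.1, 0.1])
        h = make_harmonized(bx, by, se_y)
        slope, intercept = mc.mr_egger(h)
        X = np.column_stack([np.ones(3), bx])
        beta, base_se, s2 = wls_oracle(X, by, 1 / se_y**2)
        assert slope.beta == pytest.approx(beta[1], abs=1e-10)
        assert intercept.intercept == pytest.approx(beta[0], abs=1e-10)
        scale = max(1.0, np.sqrt(s2))
        assert slope.se == pytest.approx(base_se[1] * scale, abs=1e-10)
        assert intercept.se == pytest.approx(base_se[0] * scale, abs=1e-10)

    def test_orientation_invariance(self):
        bx = np.array([0.1, -0.2, 0.4, 0.15])
        by = np.array([0.05, 0.07, 0.13, 0.02])
        se_y = np.array([0.1, 0.08, 0.1, 0.09])
        s1, i1 = mc.mr_egger(make_harmonized(bx, by, se_y))
        s2_, i2 = mc.mr_egger(make_harmonized(-bx, -by, se_y))
        assert s1.beta == pytest.approx(s2_.beta)
        assert i1.intercept == pytest.approx(i2.intercept)

    def test_requires_three_variants(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1], [0.05, 0.05])
        with pytest.raises(mc.InsufficientInstrumentsError):
            mc.mr_egger(h)


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        assert _weighted_median_point(
            np.array([0.2, 0.5, 0.8]), np.ones(3)) == pytest.approx(0.5)

    def test_hand_interpolated_example(self):
        # cumulative midpoints 0.3, 0.7, 0.9 -> interpolate 0.5 to 0.15
        est = _weighted_median_point(np.array([0.1, 0.2, 0.3]),
                                     np.array([0.6, 0.2, 0.2]))
        assert est == pytest.approx(0.15)

    def test_degenerate_identical_ratios(self):
        bx = np.array([0.2, 0.25, 0.3])
        by = 0.4 * bx
        h = make_harmonized(bx, by, [1e-6] * 3, se_x=[1e-8] * 3)
        est = mc.weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.4, abs=1e-6)
        assert est.se < 1e-4  # bootstrap se shrinks with the input SEs

    def test_estimate_within_ratio_range(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(3, 9))
            bx = rng.uniform(0.05, 0.4, k)
            by = rng.normal(0, 0.1, k)
            h = make_harmonized(bx, by, rng.uniform(0.01, 0.1, k))
            ratios, _ = mc.wald_ratios(h)
            est = mc.weighted_median(h, n_boot=2, seed=0)
            assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12


class TestWeightedMode:
    def test_identical_ratios_recovered(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, 0.7 * bx, [0.05] * 3)
        est = mc.weighted_mode(h, n_boot=50, seed=2)
        assert est.beta == pytest.approx(0.7, abs=1e-9)

    def test_majority_cluster_wins(self):
        ratios = np.array([0.5, 0.5, 0.5, 1.0])
        est = _mode_point(ratios, np.ones(4))
        assert est == pytest.approx(0.5, abs=0.05)

    def test_scale_equivariance(self):
        ratios = np.array([0.2, 0.3, 0.35, 0.9])
        w = np.array([1.0, 2.0, 1.5, 0.5])
        assert _mode_point(2 * ratios, w) == pytest.approx(
            2 * _mode_point(ratios, w), abs=1e-9)


class TestMVMR:
    def test_single_exposure_reduces_to_ivw_random(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.4 * bx + rng.normal(0, 0.03, 8)
        se_y = rng.uniform(0.01, 0.05, 8)
        h = make_harmonized(bx, by, se_y)
        uni, _ = mc.ivw(h, mode="random")
        multi = mc.mvmr_ivw(bx[:, None], np.full((8, 1), 0.01), by, se_y)[0]
        assert multi.beta == pytest.approx(uni.beta, abs=1e-12)
        assert multi.se == pytest.approx(uni.se, rel=1e-6)

    def test_orthogonal_design_recovers_coefficients(self):
        k = 10
        bx = np.zeros((k, 2))
        bx[:5, 0] = np.linspace(0.1, 0.3, 5)
        bx[5:, 1] = np.linspace(0.1, 0.3, 5)
        truth = np.array([0.2, -0.1])
        by = bx @ truth
        est = mc.mvmr_ivw(bx, np.full((k, 2), 0.001), by, np.full(k, 0.01))
        assert est[0].beta == pytest.approx(0.2, abs=1e-6)
        assert est[1].beta == pytest.approx(-0.1, abs=1e-6)

    def test_duplicated_column_is_collinear(self):
        bx = np.tile(np.linspace(0.1, 0.4, 6)[:, None], (1, 2))
        with pytest.raises(mc.CollinearityError):
            mc.mvmr_ivw(bx, np.full((6, 2), 0.01), np.zeros(6),
                        np.full(6, 0.01))


class TestBetaToOR:
    def test_null_effect(self):
        or_, lo, hi, p = mc.beta_to_or(0.0, 0.1)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_published_forest_row_reconstruction(self):
        # OR 1.134 with CI (1.042, 1.234) implies p rounding to 0.004
        beta = np.log(1.134)
        se = (np.log(1.234) - np.log(1.042)) / (2 * Z95)
        or_, lo, hi, p = mc.beta_to_or(beta, se)
        assert lo == pytest.approx(1.042, abs=5e-4)
        assert hi == pytest.approx(1.234, abs=5e-4)
        assert round(p, 3) == 0.004

    @settings(max_examples=100, deadline=None)
    @given(beta=st.floats(-2, 2), se=st.floats(1e-3, 1.0))
    def test_geometric_mean_of_ci_is_or(self, beta, se):
        or_, lo, hi, p = mc.beta_to_or(beta, se)
        assert np.sqrt(lo * hi) == pytest.approx(or_, rel=1e-9)
        assert lo < or_ < hi


class TestEstimatorInvariances:
    def _random_h(self, seed, k=8):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.05, 0.4, k)
        by = 0.3 * bx + rng.normal(0, 0.03, k)
        return bx, by, rng.uniform(0.01, 0.06, k)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_variant_order_and_orientation_invariance(self, seed):
        bx, by, se_y = self._random_h(seed)
        h = make_harmonized(bx, by, se_y)
        perm = np.random.default_rng(seed + 100).permutation(len(bx))
        sign = np.where(np.arange(len(bx)) % 2 == 0, 1.0, -1.0)[perm]
        h2 = make_harmonized(bx[perm] * sign, by[perm] * sign, se_y[perm])
        for fn in (lambda h: mc.ivw(h)[0].beta,
                   lambda h: mc.mr_egger(h)[0].beta,
                   lambda h: mc.weighted_median(h, n_boot=2, seed=0).beta):
            assert fn(h2) == pytest.approx(fn(h), abs=1e-10)

    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_outcome_scaling_scales_beta_not_p(self, c):
        bx, by, se_y = self._random_h(4)
        h1 = make_harmonized(bx, by, se_y)
        h2 = make_harmonized(bx, c * by, c * se_y)
        for fn in (lambda h: mc.ivw(h)[0], lambda h: mc.mr_egger(h)[0]):
            e1, e2 = fn(h1), fn(h2)
            assert e2.beta == pytest.approx(c * e1.beta, rel=1e-9)
            assert e2.pval == pytest.approx(e1.pval, rel=1e-9)

    def test_estimators_agree_without_pleiotropy(self, strong_config):
        """With strong, valid instruments all four estimators land on the
        same causal effect within 2 SEs."""
        X, _, Y = mc.simulate_triplet(strong_config)
        res = mc.run_mr_suite(X, Y, n_boot=200, seed=5)
        ivw_est = res.estimates["ivw_random"]
        for method in ("egger", "weighted_median", "weighted_mode"):
            other = res.estimates[method]
            gap = abs(other.beta - ivw_est.beta)
            assert gap < 2 * max(other.se, ivw_est.se)
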