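"""ANOVA decomposition, LOAM, CIs and ICC against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

import volagree as va
from volagree.agreement import DegenerateDataError, Z_95

grids = arrays(
    float,
    (4, 3),
    elements=st.floats(min_value=1.0, max_value=1e4, allow_nan=False),
)


class TestSubjectStats:
    def test_two_observer_hand_value(self):
        m = va.AnnotationMatrix.from_wide([[10.0, 12.0], [10.0, 12.0]])
        s = va.subject_stats(m)
        assert s["mean_volume"].iloc[0] == 11.0
        assert s["sd_volume"].iloc[0] == pytest.approx(math.sqrt(2), rel=1e-12)
        assert s["sd_rel_pct"].iloc[0] == pytest.approx(100 * math.sqrt(2) / 11, rel=1e-12)

    def test_identical_observers_zero_sd(self):
        m = va.AnnotationMatrix.from_wide(np.full((3, 5), 5.0))
        assert (va.subject_stats(m)["sd_rel_pct"] == 0).all()

    def test_scale_invariance_of_relative_sd(self, cohort100):
        matrix, _ = cohort100
        a = va.subject_stats(matrix)["sd_rel_pct"]
        b = va.subject_stats(matrix.scale(7.3))["sd_rel_pct"]
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestAnova:
    def test_hand_example(self, hand_grid):
        ms = va.anova_mean_squares(hand_grid)
        assert ms.ms_observer == pytest.approx(1.5, rel=1e-12)
        assert ms.ms_residual == pytest.approx(3.5, rel=1e-12)
        assert ms.ms_subject == pytest.approx(213.5, rel=1e-12)
        assert (ms.df_subject, ms.df_observer, ms.df_residual) == (2, 1, 2)

    def test_constant_grid_all_zero(self):
        ms = va.anova_mean_squares(np.full((4, 3), 7.0))
        assert ms.ms_subject == ms.ms_observer == ms.ms_residual == 0.0

    @given(grids)
    def test_matches_brute_force(self, Y):
        from conftest import brute_force_mean_squares

        ms = va.anova_mean_squares(Y)
        ms_s, ms_o, ms_r = brute_force_mean_squares(Y)
        scale = max(1.0, ms_s, ms_o, ms_r)
        assert abs(ms.ms_subject - ms_s) <= 1e-10 * scale
        assert abs(ms.ms_observer - ms_o) <= 1e-10 * scale
        assert abs(ms.ms_residual - ms_r) <= 1e-10 * scale

    @given(grids, st.floats(min_value=0.1, max_value=100.0))
    def test_quadratic_scaling(self, Y, c):
        a, b = va.anova_mean_squares(Y), va.anova_mean_squares(c * Y)
        assert b.ms_subject == pytest.approx(c**2 * a.ms_subject, rel=1e-9, abs=1e-9)
        assert b.ms_residual == pytest.approx(c**2 * a.ms_residual, rel=1e-9, abs=1e-9)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            va.anova_mean_squares(np.ones((1, 5)))


class TestVarianceComponents:
    def test_truncation_on_hand_example(self, hand_grid):
        vc = va.variance_components(va.anova_mean_squares(hand_grid))
        assert vc.sigma2_observer == 0.0
        assert vc.observer_truncated
        assert vc.sigma2_observer_raw == pytest.approx(-2 / 3, rel=1e-12)
        assert vc.sigma2_residual == pytest.approx(3.5, rel=1e-12)

    def test_exact_zero_not_flagged(self):
        ms = va.MeanSquares(10.0, 3.5, 3.5, 7, 3)
        vc = va.variance_components(ms)
        assert vc.sigma2_observer == 0.0 and not vc.observer_truncated

    def test_positive_component_arithmetic(self):
        ms = va.MeanSquares(50.0, 10.5, 3.5, 7, 3)
        assert va.variance_components(ms).sigma2_observer == pytest.approx(1.0, rel=1e-12)


class TestLoam:
    def test_hand_value(self):
        vc = va.VarianceComponents(0.0, 3.5, True, -2 / 3)
        assert va.loam_estimate(vc, 2, 1.959964) == pytest.approx(
            1.959964 * math.sqrt(0.5 * 3.5), rel=1e-9
        )

    def test_zero_variance_zero_loam(self):
        assert va.loam_estimate(va.VarianceComponents(0.0, 0.0, False, 0.0), 5) == 0.0

    def test_sqrt2_scaling_law(self):
        a = va.loam_estimate(va.VarianceComponents(1.0, 2.0, False, 1.0), 4)
        b = va.loam_estimate(va.VarianceComponents(2.0, 4.0, False, 2.0), 4)
        assert b == pytest.approx(math.sqrt(2) * a, rel=1e-12)

    def test_finite_observer_factor_is_deviation_variance(self):
        # Monte-Carlo oracle: Var(Y_ij - Ybar_i.) = (m-1)/m (sigma_O^2 + sigma_R^2)
        rng = np.random.default_rng(0)
        sO, sR, m = 2.0, 5.0, 5
        n = 200_000
        b = rng.normal(0, sO, (n, m))
        e = rng.normal(0, sR, (n, m))
        y = b + e
        dev = y - y.mean(axis=1, keepdims=True)
        expected = (m - 1) / m * (sO**2 + sR**2)
        assert dev.var() == pytest.approx(expected, rel=0.01)


class TestLoamCI:
    def test_degenerate_zero(self):
        ms = va.MeanSquares(0.0, 0.0, 0.0, 5, 3)
        assert va.loam_ci(ms) == (0.0, 0.0)

    def test_matches_independent_mls_evaluation(self, hand_grid):
        ms = va.anova_mean_squares(hand_grid)
        n, m = 3, 2
        psi = ms.ms_observer / n + (n - 1) / n * ms.ms_residual
        terms_c = np.array([ms.ms_observer / n, (n - 1) / n * ms.ms_residual])
        dfs = np.array([m - 1, (n - 1) * (m - 1)], dtype=float)
        H = dfs / stats.chi2.ppf(0.025, dfs) - 1
        G = 1 - dfs / stats.chi2.ppf(0.975, dfs)
        hi = psi + math.sqrt(((H * terms_c) ** 2).sum())
        lo = psi - math.sqrt(((G * terms_c) ** 2).sum())
        exp = (Z_95 * math.sqrt(0.5 * max(lo, 0.0)), Z_95 * math.sqrt(0.5 * hi))
        got = va.loam_ci(ms)
        assert got[0] == pytest.approx(exp[0], rel=1e-10)
        assert got[1] == pytest.approx(exp[1], rel=1e-10)

    def test_interval_envelops_point(self, cohort100):
        matrix, _ = cohort100
        est = va.LoamAgreement(n_boot=200, random_state=0).fit(matrix)
        lo, hi = est.loam_abs_ci_
        assert 0 <= lo <= est.loam_abs_ <= hi


class TestComponentCIs:
    def test_truncation_propagates_to_lower_bound(self, hand_grid):
        ms = va.anova_mean_squares(hand_grid)
        cis = va.component_sd_cis(ms, n_boot=500, random_state=1)
        assert cis["sigma_o_ci"][0] == 0.0

    def test_seeded_determinism(self):
        ms = va.MeanSquares(500.0, 40.0, 9.0, 26, 5)
        a = va.component_sd_cis(ms, n_boot=500, random_state=7)
        b = va.component_sd_cis(ms, n_boot=500, random_state=7)
        assert a == b

    def test_small_n_boot_rejected(self):
        with pytest.raises(ValueError):
            va.component_sd_cis(va.MeanSquares(1, 1, 1, 5, 3), n_boot=50)

    def test_sigma_r_ci_coverage(self):
        # MC oracle: percentile bootstrap CI covers the true residual SD
        rng = np.random.default_rng(99)
        sO, sR, n, m = 10.0, 25.0, 26, 5
        hit = 0
        reps = 500
        for _ in range(reps):
            Y = rng.normal(0, sO, m)[None, :] + rng.normal(0, sR, (n, m))
            cis = va.component_sd_cis(va.anova_mean_squares(Y), n_boot=2000, random_state=rng)
            lo, hi = cis["sigma_r_ci"]
            hit += lo <= sR <= hi
        assert 0.92 <= hit / reps <= 0.98


class TestICC:
    def test_hand_example_plugin_value(self, hand_grid):
        icc, _ = va.icc_absolute_single(va.anova_mean_squares(hand_grid))
        assert icc == pytest.approx(210 / (647 / 3), rel=1e-10)

    def test_identical_observers_perfect_agreement(self):
        Y = np.tile(np.array([[10.0], [20.0], [35.0]]), (1, 4))
        icc, ci = va.icc_absolute_single(va.anova_mean_squares(Y))
        assert icc == 1.0 and ci == (1.0, 1.0)

    def test_scale_invariance(self, cohort100):
        matrix, _ = cohort100
        a, _ = va.icc_absolute_single(va.anova_mean_squares(matrix.to_array()))
        b, _ = va.icc_absolute_single(va.anova_mean_squares(7.3 * matrix.to_array()))
        assert a == pytest.approx(b, rel=1e-12)

    def test_degenerate_signalled(self):
        with pytest.raises(DegenerateDataError):
            va.icc_absolute_single(va.MeanSquares(0.0, 0.0, 0.0, 5, 3))

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        Y = (
            rng.normal(0, 3, (12, 4))
            + rng.normal(0, 8, 12)[:, None]
            + rng.normal(0, 2, 4)[None, :]
            + 50
        )
        icc, ci = va.icc_absolute_single(va.anova_mean_squares(Y))
        long = pd.DataFrame(
            {"s": np.repeat(np.arange(12), 4), "r": np.tile(np.arange(4), 12),
             "y": Y.ravel()}
        )
        row = (
            pg.intraclass_corr(long, targets="s", raters="r", ratings="y")
            .set_index("Type")
            .loc["ICC(A,1)"]
        )
        assert icc == pytest.approx(row["ICC"], rel=1e-9)
        # pingouin reports the CI rounded to 2 decimals
        assert ci[0] == pytest.approx(row["CI95"][0], abs=0.005)
        assert ci[1] == pytest.approx(row["CI95"][1], abs=0.005)


class TestLoamAgreementEstimator:
    def test_sklearn_param_interface(self):
        est = va.LoamAgreement(alpha=0.1, n_boot=500)
        assert est.get_params()["alpha"] == 0.1
        est.set_params(alpha=0.05)
        assert est.alpha == 0.05

    def test_scaling_equivariance(self, cohort100):
        matrix, _ = cohort100
        c = 3.7
        a = va.LoamAgreement(n_boot=500, random_state=0).fit(matrix)
        b = va.LoamAgreement(n_boot=500, random_state=0).fit(matrix.scale(c))
        assert b.loam_abs_ == pytest.approx(c * a.loam_abs_, rel=1e-9)
        assert b.loam_abs_ci_[1] == pytest.approx(c * a.loam_abs_ci_[1], rel=1e-9)
        assert b.loam_pct_ == pytest.approx(a.loam_pct_, rel=1e-9)
        assert b.icc_ == pytest.approx(a.icc_, rel=1e-9)

    def test_permutation_invariance(self, cohort100):
        matrix, _ = cohort100
        rng = np.random.default_rng(3)
        vols = matrix.volumes
        perm = vols.iloc[rng.permutation(100), rng.permutation(5)]
        a = va.LoamAgreement(n_boot=500, random_state=0).fit(matrix)
        b = va.LoamAgreement(n_boot=500, random_state=0).fit(
            va.AnnotationMatrix(perm, matrix.metadata)
        )
        assert b.loam_abs_ == pytest.approx(a.loam_abs_, rel=1e-12)
        assert b.icc_ == pytest.approx(a.icc_, rel=1e-12)

    def test_parameter_recovery_unbiased(self):
        # 100×5 grids at known variances: moment estimates unbiased to 3 MC SEs
        rng = np.random.default_rng(11)
        sO, sR, reps = 10.0, 25.0, 1000
        est_o, est_r = [], []
        for _ in range(reps):
            Y = rng.normal(0, sO, 5)[None, :] + rng.normal(0, sR, (100, 5)) + 500
            vc = va.variance_components(va.anova_mean_squares(Y))
            est_o.append(vc.sigma2_observer_raw)
            est_r.append(vc.sigma2_residual)
        for est, truth in ((np.array(est_o), sO**2), (np.array(est_r), sR**2)):
            se = est.std(ddof=1) / math.sqrt(reps)
            assert abs(est.mean() - truth) <= 3 * se

    def test_degenerate_matrix_yields_nan_icc(self):
        est = va.LoamAgreement(n_boot=200, random_state=0).fit(np.full((4, 3), 9.0))
        assert math.isnan(est.icc_)
        assert est.loam_abs_ == 0.0
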