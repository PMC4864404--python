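import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import geopoverty.model as M
from geopoverty.model import (
    GrowthPovertySystem,
    IdentificationError,
    SingularityError,
    adjusted_growth,
    evaluation_points,
    fit_2sls,
    fit_ols,
    fit_system_3sls,
    impact_table,
    marginal_impact,
    test_restrictions as run_restriction_test,
)
from geopoverty.synthetic import PanelConfig, generate_panel


class TestAdjustedGrowth:
    def test_zero_share_leaves_growth_unchanged(self):
        assert adjusted_growth(0.0, 3.36, "dal") == 3.36
        assert adjusted_growth(0.0, 3.36, "ial") == 3.36

    def test_dal_scaling(self):
        assert adjusted_growth(27.1, 3.36, "dal") == pytest.approx(0.729 * 3.36)

    def test_ial_scaling(self):
        assert adjusted_growth(10.8, 3.36, "ial") == pytest.approx(1.108 * 3.36)

    def test_share_outside_percent_range_rejected(self):
        with pytest.raises(ValueError):
            adjusted_growth(101.0, 3.36, "dal")

    @given(st.floats(0.0, 100.0), st.floats(0.01, 10.0))
    def test_polarity_ordering(self, share, growth):
        # DAL blunts, IAL amplifies, symmetric around the raw growth rate
        lo = adjusted_growth(share, growth, "dal")
        hi = adjusted_growth(share, growth, "ial")
        assert lo <= growth <= hi
        assert lo + hi == pytest.approx(2 * growth)


class TestMarginalImpact:
    def test_dal_high_share_cell(self):
        # beta1 and delta1 at printed rounding; one-SD-above-mean DAL share
        assert marginal_impact(-2.15, 0.54, 48.2, "dal", 3.36) == pytest.approx(-2.02, abs=0.005)

    def test_ial_high_share_cell(self):
        assert marginal_impact(-2.36, 0.34, 52.9, "ial", 3.36) == pytest.approx(-4.12, abs=0.005)

    def test_full_dal_share_annihilates_the_channel(self):
        assert marginal_impact(-2.15, 0.54, 100.0, "dal", 3.36) == 0.0

    @given(st.floats(0.1, 99.9), st.floats(0.1, 99.9))
    def test_magnitude_monotone_in_share(self, s1, s2):
        lo, hi = sorted((s1, s2))
        dal_lo = abs(marginal_impact(-2.0, 0.5, lo, "dal", 3.0))
        dal_hi = abs(marginal_impact(-2.0, 0.5, hi, "dal", 3.0))
        ial_lo = abs(marginal_impact(-2.0, 0.5, lo, "ial", 3.0))
        ial_hi = abs(marginal_impact(-2.0, 0.5, hi, "ial", 3.0))
        assert dal_hi <= dal_lo + 1e-12
        assert ial_hi >= ial_lo - 1e-12


class TestEvaluationPoints:
    @pytest.mark.parametrize(
        "mean,sd,mult,expected",
        [
            (27.11, 21.04, 1.0, (6.1, 27.1, 48.2)),
            (5.02, 4.43, 1.0, (0.6, 5.0, 9.5)),
            (31.89, 21.05, 1.0, (10.8, 31.9, 52.9)),
            (13.45, 18.83, 0.5, (4.0, 13.5, 22.9)),
        ],
    )
    def test_sample_moment_row_labels(self, mean, sd, mult, expected):
        assert evaluation_points(mean, sd, mult) == expected

    def test_zero_sd_collapses_to_mean(self):
        assert evaluation_points(10.0, 0.0) == (10.0, 10.0, 10.0)

    def test_points_clipped_at_zero(self):
        lo, mid, hi = evaluation_points(1.0, 5.0)
        assert lo == 0.0


def _noiseless_panel(seed=4, **kw):
    cfg = PanelConfig(error_sd_P=0.0, error_sd_G=0.0, theta_direct=0.0, seed=seed, **kw)
    return generate_panel(cfg)


class TestOLS:
    def test_noiseless_exact_recovery(self):
        panel, truth = _noiseless_panel()
        fit = fit_ols(panel, share="d1", include_controls=True)
        assert fit.beta0 == pytest.approx(truth["beta0"], abs=1e-8)
        assert fit.beta1 == pytest.approx(truth["beta1"], abs=1e-8)
        assert fit.delta1 == pytest.approx(truth["delta1"], abs=1e-8)

    def test_matches_statsmodels_on_the_same_design(self):
        import statsmodels.api as sm

        panel, _ = generate_panel(PanelConfig(n_countries=60, seed=17))
        fit = fit_ols(panel, share="i1", include_controls=True)
        s = panel["i1"].to_numpy()
        X = np.column_stack(
            [np.ones(60), (1 + s / 100.0) * panel["g"], panel["Z1"], panel["Z2"]]
        )
        ref = sm.OLS(panel["gamma_H"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.params_P, ref.params, atol=1e-10)

    def test_duplicate_regressor_raises_singularity_error(self):
        panel, _ = generate_panel(PanelConfig(n_countries=50, seed=2))
        panel["Z2"] = panel["Z1"]
        with pytest.raises(SingularityError, match="Z"):
            fit_ols(panel, share="d1", include_controls=True)

    def test_beta1_within_two_se_of_truth_with_exogenous_noise(self):
        panel, truth = generate_panel(
            PanelConfig(n_countries=500, error_corr=0.0, seed=31)
        )
        fit = fit_ols(panel, share="d1", include_controls=True)
        assert abs(fit.beta1 - truth["beta1"]) < 2 * fit.beta1_se


class TestTwoStageLS:
    def test_degenerate_instruments_reduce_to_ols(self):
        # exogenous errors and an instrument list spanning the regressors
        panel, _ = _noiseless_panel(seed=9)
        panel["adj"] = (1 - panel["d1"] / 100.0) * panel["g"]
        ols = fit_ols(panel, share="d1", include_controls=True)
        iv = fit_2sls(panel, share="d1", include_controls=True, instruments=["adj"])
        np.testing.assert_allclose(iv.params_P, ols.params_P, atol=1e-8)

    def test_corrects_endogeneity_bias(self):
        panel, truth = generate_panel(
            PanelConfig(n_countries=500, error_corr=0.6, seed=13)
        )
        ols = fit_ols(panel, share="d1", include_controls=True)
        iv = fit_2sls(panel, share="d1", include_controls=True)
        assert abs(iv.beta1 - truth["beta1"]) < 2 * iv.beta1_se
        # OLS attenuated: its error exceeds the IV error by a wide margin
        assert abs(ols.beta1 - truth["beta1"]) > 4 * iv.beta1_se

    def test_underidentification_raises(self):
        panel, _ = generate_panel(PanelConfig(n_countries=50, seed=3))
        est = GrowthPovertySystem(share="d1", estimator="2sls", include_controls=True)
        yP, XP, nP, yG, XG, nG, Z, iN, n = est._design(panel)
        with pytest.raises(IdentificationError):
            # strip instruments below the regressor count
            est_small = GrowthPovertySystem(share="d1", estimator="2sls")
            est_small._design = lambda p: (yP, XP, nP, yG, XG, nG, Z[:, :1], iN[:1], n)
            est_small.fit(panel)


def _matrix_2sls(y, X, Z):
    PZ = Z @ np.linalg.solve(Z.T @ Z, Z.T)
    return np.linalg.solve(X.T @ PZ @ X, X.T @ PZ @ y)


class TestSystemEstimators:
    """Degenerate-limit identities against direct matrix-formula oracles."""

    def _design(self, n=40, seed=7, corr=0.0):
        panel, _ = generate_panel(PanelConfig(n_countries=n, error_corr=corr, seed=seed))
        est = GrowthPovertySystem(share="d1", estimator="3sls", include_controls=True)
        return panel, est._design(panel)

    def test_3sls_with_diagonal_sigma_equals_per_equation_2sls(self):
        panel, (yP, XP, nP, yG, XG, nG, Z, iN, n) = self._design()
        bP_oracle = _matrix_2sls(yP, XP, Z)
        bG_oracle = _matrix_2sls(yG, XG, Z)
        sigd = np.diag([4.0, 0.5])  # any diagonal weighting
        b, _ = M._system_gls([yP, yG], [XP, XG], sigd, Z)
        np.testing.assert_allclose(b[: XP.shape[1]], bP_oracle, atol=1e-9)
        np.testing.assert_allclose(b[XP.shape[1] :], bG_oracle, atol=1e-9)

    def test_sur_with_diagonal_sigma_and_exogenous_regressors_equals_ols(self):
        panel, (yP, XP, nP, yG, XG, nG, Z, iN, n) = self._design(seed=8)
        bP_oracle = np.linalg.solve(XP.T @ XP, XP.T @ yP)
        bG_oracle = np.linalg.solve(XG.T @ XG, XG.T @ yG)
        b, _ = M._system_gls([yP, yG], [XP, XG], np.diag([2.0, 3.0]), None)
        np.testing.assert_allclose(b[: XP.shape[1]], bP_oracle, atol=1e-9)
        np.testing.assert_allclose(b[XP.shape[1] :], bG_oracle, atol=1e-9)

    def test_full_3sls_agrees_with_direct_stacked_formula(self):
        panel, (yP, XP, nP, yG, XG, nG, Z, iN, n) = self._design(seed=9, corr=0.4)
        fit = fit_system_3sls(panel, share="d1", include_controls=True)
        # oracle: explicit kronecker-form GLS on the stacked system
        _, _, eP = M._iv_eq(yP, XP, Z)
        _, _, eG = M._iv_eq(yG, XG, Z)
        sigma = M._sigma(eP, eG)
        PZ = Z @ np.linalg.solve(Z.T @ Z, Z.T)
        Xbar = np.block(
            [[XP, np.zeros((n, XG.shape[1]))], [np.zeros((n, XP.shape[1])), XG]]
        )
        ybar = np.concatenate([yP, yG])
        Wmat = np.kron(np.linalg.inv(sigma), PZ)
        b_oracle = np.linalg.solve(Xbar.T @ Wmat @ Xbar, Xbar.T @ Wmat @ ybar)
        np.testing.assert_allclose(
            np.concatenate([fit.params_P, fit.params_G]), b_oracle, atol=1e-8
        )

    def test_3sls_recovers_truth_on_endogenous_panel(self):
        panel, truth = generate_panel(PanelConfig(n_countries=500, error_corr=0.5, seed=23))
        fit = fit_system_3sls(panel, share="d1", include_controls=True)
        assert abs(fit.beta1 - truth["beta1"]) < 2 * fit.beta1_se
        assert abs(fit.delta1 - truth["delta1"]) < 2 * fit.delta1_se

    def test_residual_covariance_is_symmetric_psd(self):
        panel, _ = generate_panel(PanelConfig(n_countries=80, error_corr=0.5, seed=19))
        fit = fit_system_3sls(panel, share="d1", include_controls=True)
        np.testing.assert_allclose(fit.sigma, fit.sigma.T)
        assert np.all(np.linalg.eigvalsh(fit.sigma) >= -1e-12)

    def test_reported_tstats_are_coef_over_se(self):
        panel, _ = generate_panel(PanelConfig(n_countries=80, seed=20))
        fit = fit_system_3sls(panel, share="d1", include_controls=True)
        assert fit.tstats()["P:adjusted_growth"] == pytest.approx(fit.beta1 / fit.beta1_se)


class TestRestrictionTests:
    def test_wald_p_matches_statsmodels_chi2_on_ols(self):
        import statsmodels.api as sm

        panel, _ = generate_panel(PanelConfig(n_countries=80, error_corr=0.0, seed=29))
        fit = fit_ols(panel, share="d1", include_controls=True, include_direct=True)
        stat, p = M.wald_test(fit, "P", ["share_direct"])
        s = panel["d1"].to_numpy()
        X = np.column_stack(
            [np.ones(80), (1 - s / 100.0) * panel["g"], s, panel["Z1"], panel["Z2"]]
        )
        ref = sm.OLS(panel["gamma_H"].to_numpy(), X).fit()
        # same point estimates; statsmodels uses the n-k variance, ours n
        np.testing.assert_allclose(fit.params_P, ref.params, atol=1e-10)
        t_ref = ref.tvalues[2] * np.sqrt(80 / (80 - X.shape[1]))
        assert stat == pytest.approx(t_ref**2, rel=1e-8)

    def test_direct_channel_detected_when_present(self):
        panel, _ = generate_panel(
            PanelConfig(n_countries=500, theta_direct=0.5, error_corr=0.5, seed=37)
        )
        fit = fit_system_3sls(panel, share="d1", include_controls=True, include_direct=True)
        rep = run_restriction_test(fit, panel)
        assert rep["p_direct"] < 0.05
        assert rep["supported_channel"] == "both"

    def test_indirect_only_supported_when_theta_is_zero(self):
        panel, _ = generate_panel(
            PanelConfig(n_countries=500, theta_direct=0.0, error_corr=0.5, seed=38)
        )
        fit = fit_system_3sls(panel, share="d1", include_controls=True, include_direct=True)
        rep = run_restriction_test(fit, panel)
        assert rep["p_indirect"] < 0.05

    def test_zero_variance_share_column_is_input_error(self):
        panel, _ = generate_panel(PanelConfig(n_countries=50, seed=39))
        panel["d1"] = 25.0
        fit_like = fit_ols(panel.assign(d1=np.linspace(1, 50, 50)),
                           share="d1", include_controls=True, include_direct=True)
        with pytest.raises(ValueError, match="zero variance"):
            run_restriction_test(fit_like, panel)

    def test_fit_without_direct_term_rejected(self):
        panel, _ = generate_panel(PanelConfig(n_countries=50, seed=40))
        fit = fit_ols(panel, share="d1", include_controls=True)
        with pytest.raises(ValueError, match="direct"):
            run_restriction_test(fit, panel)


class TestImpactTable:
    def test_closed_form_evaluation_with_known_parameters(self):
        fits = {"d1": {"a": (-2.0, 0.5)}}
        moments = {"d1": (30.0, 10.0)}
        tab = impact_table(fits, moments, growth=4.0).set_index("point")
        assert tab.loc["mean", "impact_a"] == pytest.approx(-2.0 * 0.5 * 0.70 * 4.0)
        assert tab.loc["low", "impact_a"] == pytest.approx(-2.0 * 0.5 * 0.80 * 4.0)

    def test_zero_growth_gives_zero_impacts(self):
        fits = {"i1": {"a": (-2.0, 0.5)}}
        tab = impact_table(fits, {"i1": (30.0, 10.0)}, growth=0.0)
        assert (tab["impact_a"].dropna() == 0.0).all()

    def test_missing_share_variable_is_absent_row_not_failure(self):
        tab = impact_table({}, {}, growth=3.36)
        assert not tab["present"].any()
        assert set(tab["share_variable"]) == {"d1", "d2", "i1", "i2"}
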