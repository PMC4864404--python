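import numpy as np
import pytest

from geopoverty.grids import GridLayer, validate_stack
from geopoverty.synthetic import (
    LandscapeConfig,
    PanelConfig,
    compute_travel_time,
    generate_field,
    generate_landscape,
    generate_panel,
)


def lag1_autocorr(field: np.ndarray) -> float:
    a, b = field[:, :-1].ravel(), field[:, 1:].ravel()
    return float(np.corrcoef(a, b)[0, 1])


class TestField:
    def test_deterministic_given_seed(self):
        f1 = generate_field((32, 32), 4.0, seed=9)
        f2 = generate_field((32, 32), 4.0, seed=9)
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_standardised(self):
        f = generate_field((64, 64), 4.0, seed=1)
        assert abs(f.values.mean()) < 1e-10
        assert abs(f.values.std() - 1.0) < 1e-10

    def test_autocorrelation_tracks_smoothing_scale(self):
        # near-zero smoothing: white noise; large scale: strong lag-1 correlation
        rho_small = lag1_autocorr(generate_field((64, 64), 1e-3, seed=2).values)
        rho_large = lag1_autocorr(generate_field((64, 64), 8.0, seed=2).values)
        assert abs(rho_small) < 0.1
        assert rho_large > 0.5

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            generate_field((8, 8), 0.0, seed=0)


class TestTravelTime:
    def test_uniform_cost_matches_chebyshev_closed_form(self):
        # with unit cell costs, the optimal 8-neighbour path costs
        # (max-min) rook steps plus min diagonal steps at sqrt(2)
        cost = GridLayer(np.ones((9, 9)), kind="travel_time")
        tt = compute_travel_time(cost, [(4, 4)]).values
        for r in range(9):
            for c in range(9):
                dr, dc = abs(r - 4), abs(c - 4)
                expected = (max(dr, dc) - min(dr, dc)) + min(dr, dc) * np.sqrt(2.0)
                assert tt[r, c] == pytest.approx(expected, abs=1e-12)

    def test_rook_path_four_steps_is_four_hours(self):
        cost = GridLayer(np.ones((1, 6)), kind="travel_time")
        tt = compute_travel_time(cost, [(0, 0)]).values
        assert tt[0, 4] == pytest.approx(4.0)

    def test_city_cell_is_zero(self):
        cost = GridLayer(np.full((5, 5), 0.7), kind="travel_time")
        assert compute_travel_time(cost, [(2, 3)]).values[2, 3] == 0.0

    def test_two_cities_is_elementwise_min(self):
        rng = np.random.default_rng(5)
        cost = GridLayer(rng.uniform(0.2, 2.0, size=(12, 12)), kind="travel_time")
        a = compute_travel_time(cost, [(1, 1)]).values
        b = compute_travel_time(cost, [(10, 8)]).values
        both = compute_travel_time(cost, [(1, 1), (10, 8)]).values
        np.testing.assert_allclose(both, np.minimum(a, b), atol=1e-12)

    def test_adding_a_city_never_increases_time(self):
        rng = np.random.default_rng(6)
        cost = GridLayer(rng.uniform(0.2, 2.0, size=(10, 10)), kind="travel_time")
        base = compute_travel_time(cost, [(0, 0)]).values
        more = compute_travel_time(cost, [(0, 0), (5, 5)]).values
        assert (more <= base + 1e-12).all()

    def test_nodata_barrier_gives_unreachable_inf(self):
        vals = np.ones((3, 3))
        vals[:, 1] = -9999.0  # wall of nodata separating the city from column 2
        cost = GridLayer(vals, kind="travel_time", nodata=-9999.0)
        tt = compute_travel_time(cost, [(1, 0)]).values
        assert np.isinf(tt[1, 2])

    def test_empty_city_list_rejected(self):
        with pytest.raises(ValueError):
            compute_travel_time(GridLayer(np.ones((3, 3)), kind="travel_time"), [])


class TestLandscape:
    def test_default_landscape_passes_validation(self, default_landscape):
        report = validate_stack(default_landscape)
        assert not report.fatal, report.summary()

    def test_country_zones_partition_grid(self, default_landscape):
        zones = default_landscape.country_zone.values
        assert set(np.unique(zones)) == set(range(1, 7))

    def test_population_sums_to_total(self, default_landscape):
        total = default_landscape.population_2000.values.sum()
        assert total == pytest.approx(1_000_000.0, rel=1e-9)

    def test_urban_share_of_population(self, default_landscape):
        urb = default_landscape.urban_mask.values == 1
        pop = default_landscape.population_2000.values
        assert pop[urb].sum() / pop.sum() == pytest.approx(0.3, abs=1e-9)

    def test_zero_degrading_fraction_means_no_negative_trend_on_agri(self):
        stack = generate_landscape(LandscapeConfig(degrading_fraction=0.0, seed=3))
        agri = stack.agri_mask.values == 1
        assert (stack.npp_trend.values[agri] >= 0).all()

    def test_degrading_fraction_is_hit_closely(self):
        cfg = LandscapeConfig(nrows=128, ncols=128, degrading_fraction=0.4, seed=11)
        stack = generate_landscape(cfg)
        agri = stack.agri_mask.values == 1
        frac = (stack.npp_trend.values[agri] < 0).mean()
        assert frac == pytest.approx(0.4, abs=0.02)

    def test_too_many_countries_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(LandscapeConfig(nrows=2, ncols=2, n_countries=5)).validate()


class TestPanel:
    def test_deterministic_given_seed(self):
        p1, t1 = generate_panel(PanelConfig(seed=8))
        p2, t2 = generate_panel(PanelConfig(seed=8))
        assert p1.equals(p2)
        assert t1 == t2

    def test_noiseless_panel_is_exactly_structural(self):
        cfg = PanelConfig(error_sd_P=0.0, error_sd_G=0.0, theta_direct=0.0, seed=4)
        panel, truth = generate_panel(cfg)
        s = panel["d1"].to_numpy()
        g = panel["g"].to_numpy()
        W = panel[["W1", "W2"]].to_numpy()
        Z = panel[["Z1", "Z2"]].to_numpy()
        g_expect = cfg.delta0 + cfg.delta1 * panel["gamma_mu"] + W @ np.array(cfg.lambda_coefs)
        np.testing.assert_allclose(g, g_expect, atol=1e-12)
        gh_expect = (
            cfg.beta0 + cfg.beta1 * (1 - s / 100.0) * g + Z @ np.array(cfg.gamma_coefs)
        )
        np.testing.assert_allclose(panel["gamma_H"], gh_expect, atol=1e-12)

    def test_noiseless_regression_recovers_coefficients(self):
        cfg = PanelConfig(error_sd_P=0.0, error_sd_G=0.0, seed=5)
        panel, truth = generate_panel(cfg)
        s = panel["d1"].to_numpy()
        X = np.column_stack(
            [
                np.ones(len(panel)),
                (1 - s / 100.0) * panel["g"],
                panel["Z1"],
                panel["Z2"],
            ]
        )
        coef, *_ = np.linalg.lstsq(X, panel["gamma_H"], rcond=None)
        np.testing.assert_allclose(
            coef, [cfg.beta0, cfg.beta1, *cfg.gamma_coefs], atol=1e-9
        )

    def test_spell_fields_round_trip_growth_rates(self):
        panel, _ = generate_panel(PanelConfig(seed=6))
        years = (panel["t1"] - panel["t0"]).to_numpy()
        gh = 100.0 * (np.log(panel["H1"]) - np.log(panel["H0"])) / years
        np.testing.assert_allclose(gh, panel["gamma_H"], atol=1e-9)
        gm = 100.0 * (np.log(panel["mu1"]) - np.log(panel["mu0"])) / years
        np.testing.assert_allclose(gm, panel["gamma_mu"], atol=1e-9)

    def test_share_moments_match_configuration_at_large_n(self):
        panel, _ = generate_panel(PanelConfig(n_countries=500, seed=7))
        d1 = panel["d1"].to_numpy()
        # truncation at 0 shifts moments slightly; allow ~2 standard errors
        se_mean = 21.04 / np.sqrt(500)
        assert abs(d1.mean() - 27.11) < 2 * se_mean + 0.8
        assert abs(d1.std(ddof=1) - 21.04) < 2.0
        assert d1.min() >= 0.0 and d1.max() <= 100.0

    def test_invalid_share_variable_rejected(self):
        with pytest.raises(ValueError, match="share_variable"):
            generate_panel(PanelConfig(share_variable="x9"))

    def test_error_corr_bounds_enforced(self):
        with pytest.raises(ValueError):
            generate_panel(PanelConfig(error_corr=1.0))
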