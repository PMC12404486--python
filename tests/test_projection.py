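"""Random-walk drift estimation, kappa extrapolation, rate projection."""

import numpy as np
import pandas as pd
import pytest

from mortgap.data_io import SchemaError
from mortgap.model import ModelSpec, build_design, PosteriorDraws
from mortgap.projection import (
    build_horizon_frame,
    drift_posterior,
    estimate_drift,
    expected_deaths,
    fitted_rates,
    project_rates,
    project_year_effects,
    ProjectionResult,
)


class TestEstimateDrift:
    def test_linear_path_exact(self):
        t = np.arange(18)
        kappa = np.tile(0.1 * t, (5, 1))
        delta, sigma = estimate_drift(kappa)
        assert delta == pytest.approx(np.full(5, 0.1), abs=1e-12)
        assert sigma == pytest.approx(np.zeros(5), abs=1e-12)

    def test_constant_path_zero_drift(self):
        delta, sigma = estimate_drift(np.ones((3, 10)))
        assert delta == pytest.approx(np.zeros(3), abs=1e-12)

    def test_short_path_rejected(self):
        with pytest.raises(SchemaError, match=">= 3"):
            estimate_drift(np.zeros((4, 2)))

    def test_simulated_walk_recovers_drift(self):
        rng = np.random.default_rng(0)
        n_draws, T, true_delta, true_sigma = 500, 18, -0.02, 0.01
        steps = true_delta + true_sigma * rng.standard_normal((n_draws,
                                                               T - 1))
        kappa = np.concatenate([np.zeros((n_draws, 1)),
                                np.cumsum(steps, axis=1)], axis=1)
        delta, _ = estimate_drift(kappa)
        se = true_sigma / np.sqrt(T - 1) / np.sqrt(n_draws)
        assert abs(delta.mean() - true_delta) < 2 * se

    def test_drift_posterior_keeps_deterministic_paths_exact(self):
        kappa = np.tile(0.1 * np.arange(18), (5, 1))
        post = drift_posterior(kappa, seed=1)
        assert post == pytest.approx(np.full(5, 0.1), abs=1e-12)


class TestProjectYearEffects:
    def test_zero_innovation_is_exactly_linear(self):
        delta = np.array([-0.02, 0.01])
        paths = project_year_effects(delta, np.zeros(2), range(2019, 2037),
                                     seed=0)
        h = np.arange(1, 19)
        assert paths[0] == pytest.approx(-0.02 * h, abs=1e-12)
        assert paths[1] == pytest.approx(0.01 * h, abs=1e-12)

    def test_variance_grows_linearly_with_horizon(self):
        n = 10_000
        sigma = 0.05
        paths = project_year_effects(np.zeros(n), np.full(n, sigma),
                                     range(2019, 2029), seed=3)
        for h in (1, 5, 10):
            var = paths[:, h - 1].var()
            assert var == pytest.approx(h * sigma ** 2, rel=0.10)

    def test_horizon_before_baseline_rejected(self):
        with pytest.raises(SchemaError, match="after the baseline"):
            project_year_effects(np.zeros(2), np.zeros(2), [2018], seed=0)

    def test_empty_horizon_returns_baseline_shape(self):
        paths = project_year_effects(np.zeros(4), np.zeros(4), [], seed=0)
        assert paths.shape == (4, 0)


@pytest.fixture(scope="module")
def flat_draws(tiny_bundle):
    """Hand-built posterior with known constant parameters (no MCMC)."""
    _, covariates, table = tiny_bundle
    spec = ModelSpec(cause="LC", sex="M", overdispersion=False)
    design = build_design(spec, table, covariates)
    n_draws = 400
    theta = np.zeros((n_draws, design.n_params))
    theta[:, 0] = -6.0  # intercept only
    return PosteriorDraws(
        design=design, theta=theta, sigma_eps=np.zeros(n_draws),
        epsilon=np.zeros((n_draws, len(design.deaths)), dtype=np.float32),
        chain_id=np.zeros(n_draws, dtype=int)), covariates


class TestProjectRates:
    def test_zero_effects_projects_intercept_rate(self, flat_draws):
        draws, covariates = flat_draws
        paths = np.zeros((draws.n_draws, 3))
        result = project_rates(draws, paths, covariates,
                               horizon_years=range(2019, 2022), seed=0)
        assert np.allclose(result.rate_draws, np.exp(-6.0))

    def test_interval_width_nondecreasing_in_horizon(self, flat_draws):
        draws, covariates = flat_draws
        delta = np.zeros(draws.n_draws)
        sigma = np.full(draws.n_draws, 0.05)
        paths = project_year_effects(delta, sigma, range(2019, 2031), seed=4)
        result = project_rates(draws, paths, covariates,
                               horizon_years=range(2019, 2031), seed=4)
        s = result.summaries()
        widths = (np.log(s["hi"]) - np.log(s["lo"])).groupby(
            s["year"]).mean()
        assert np.all(np.diff(widths.to_numpy()) > -1e-9)

    def test_lognormal_mean_closed_form(self, flat_draws):
        """With only kappa stochastic the rate mean is
        exp(b0 + h*delta + h*sigma^2/2)."""
        draws, covariates = flat_draws
        n = draws.n_draws
        delta, sigma = -0.02, 0.1
        rng_paths = project_year_effects(np.full(n, delta), np.full(n, sigma),
                                         range(2019, 2029), seed=9)
        result = project_rates(draws, rng_paths, covariates,
                               horizon_years=range(2019, 2029), seed=9)
        h = 10
        sel = result.frame.index[result.frame["year"] == 2018 + h].to_numpy()
        m = result.rate_draws[:, sel].mean()
        target = np.exp(-6.0 + h * delta + h * sigma ** 2 / 2)
        # MC s.e. of a lognormal mean over n kappa paths
        mc_se = np.exp(-6.0) * np.sqrt(
            (np.exp(2 * h * sigma ** 2) - np.exp(h * sigma ** 2)) / n)
        assert abs(m - target) < 3 * mc_se

    def test_draw_count_mismatch_rejected(self, flat_draws):
        draws, covariates = flat_draws
        with pytest.raises(SchemaError, match="draw counts"):
            project_rates(draws, np.zeros((10, 3)), covariates,
                          horizon_years=range(2019, 2022), seed=0)


class TestExpectedDeaths:
    def test_hand_arithmetic(self):
        frame = pd.DataFrame({
            "cause": ["LC"], "sex": ["M"], "age_group": ["70-74"],
            "year": [2020], "region": ["london"], "deprivation": [1],
            "exposure": [100_000.0]})
        result = ProjectionResult(frame=frame,
                                  rate_draws=np.full((7, 1), 0.001))
        deaths = expected_deaths(result)
        assert np.allclose(deaths, 100.0)

    def test_additive_over_strata_per_draw(self, flat_draws):
        draws, covariates = flat_draws
        result = fitted_rates(draws)
        deaths = expected_deaths(result)
        total = deaths.sum(axis=1)
        frame = result.frame
        by_region = [
            deaths[:, frame.index[frame["region"] == r].to_numpy()].sum(axis=1)
            for r in frame["region"].unique()]
        assert np.allclose(np.sum(by_region, axis=0), total)

    def test_matches_per_stratum_product_oracle(self, flat_draws):
        draws, _ = flat_draws
        result = fitted_rates(draws)
        deaths = expected_deaths(result)
        E = result.frame["exposure"].to_numpy()
        for d in (0, 57, 399):
            for j in (0, 5, 71):
                assert deaths[d, j] == pytest.approx(
                    result.rate_draws[d, j] * E[j], rel=1e-12)


class TestDeterministicLimit:
    def test_projection_continuous_with_fitted_baseline_rate(self, flat_draws):
        """sigma_kappa = sigma_eps = 0: the projected path continues the
        fitted baseline-year rate exactly (log-linearly in the drift)."""
        draws, covariates = flat_draws
        fitted = fitted_rates(draws)
        base_sel = fitted.frame["year"] == 2018
        base_rate = fitted.rate_draws[:, base_sel.to_numpy()][0, 0]
        delta = np.full(draws.n_draws, -0.02)
        paths = project_year_effects(delta, np.zeros(draws.n_draws),
                                     range(2019, 2022), seed=0)
        result = project_rates(draws, paths, covariates,
                               horizon_years=range(2019, 2022), seed=0)
        first = result.frame["year"] == 2019
        proj_rate = result.rate_draws[:, first.to_numpy()][0, 0]
        assert proj_rate == pytest.approx(base_rate * np.exp(-0.02),
                                          rel=1e-9)
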