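import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import mchbench as m
from mchbench.synthetic import (LogisticTrend, SurveySchedule, SurveySource,
                                simulate_coverage_observations,
                                simulate_true_coverage)
from mchbench.trends import (GPRConfig, PosteriorSurface, build_spline_basis,
                             draw_and_summarize, fit_gpr, fit_stage1,
                             matern_cov, matern_kernel_matrix, predict_stage1,
                             run_coverage_pipeline)


def second_derivative(f, t, h=1e-3):
    return (f(t + h) - 2 * f(t) + f(t - h)) / h**2


class TestSplineBasis:
    def test_linear_beyond_boundary_knots(self):
        basis = build_spline_basis(np.arange(1990, 2012))
        for col in (0, 1):
            def f(t, c=col):
                return basis.design([t])[0, c]
            for t in (1989.0, 1990.0 - 1e-2, 2012.5, 2020.0):
                assert abs(second_derivative(f, t)) < 1e-6

    def test_linear_functions_lie_in_the_span(self):
        years = np.arange(1990, 2012, dtype=float)
        basis = build_spline_basis(years)
        X = np.column_stack([np.ones(len(years)), basis.design(years)])
        y = 3.0 - 0.25 * years
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.max(np.abs(X @ beta - y)) < 1e-10

    def test_curvature_column_matches_constraint_solving_oracle(self):
        # independent construction: the unique (up to scale) combination of
        # truncated cubics (t-xi)+^3 whose cubic and quadratic tails vanish
        # beyond the last knot, found by solving the constraint equations
        years = np.arange(1990, 2012)
        basis = build_spline_basis(years)
        b0, b1 = basis.boundary_knots
        k = basis.interior_knot
        A = np.array([[1.0, 1.0, 1.0], [b0, k, b1]])
        _, _, vt = np.linalg.svd(A)
        c = vt[-1]  # null space: c1+c2+c3 = 0 and c.xi = 0

        def oracle(t):
            return sum(ci * max(t - xi, 0.0) ** 3 for ci, xi in zip(c, (b0, k, b1)))

        test_years = [1991.5, 1996.0, 2000.5, 2005.25, 2011.0]
        ours = np.array([basis.design([t])[0, 1] for t in test_years])
        theirs = np.array([oracle(t) for t in test_years])
        scale = ours[2] / theirs[2]
        assert np.allclose(ours, scale * theirs, rtol=1e-9, atol=1e-12)

    def test_interior_knot_outside_boundaries_rejected(self):
        with pytest.raises(ValueError, match="interior knot"):
            build_spline_basis(np.arange(1990, 2012), interior_knot=1980.0)


def _sim_obs(graph, years, seed, trends=None, n_eff=1000.0, indicator="x"):
    truth = simulate_true_coverage(graph, years, trends, seed=seed)
    sched = m.default_schedule(years, n_eff=n_eff, seed=seed)
    return truth, simulate_coverage_observations(truth, sched, seed=seed,
                                                 indicator=indicator)


class TestStage1:
    def test_single_region_equals_ols_spline_fit(self, years_grid):
        g = m.make_region_graph(2, "line")
        _, obs = _sim_obs(g, years_grid, seed=6)
        sub = obs[obs.region == "R0"]
        basis = build_spline_basis(years_grid)
        fit = fit_stage1(sub, basis)
        assert fit.method == "ols"
        X = np.column_stack([np.ones(len(sub)),
                             basis.design(sub["year"].to_numpy(float))])
        beta, *_ = np.linalg.lstsq(X, sub["transformed_value"].to_numpy(), rcond=None)
        pred = predict_stage1(fit, "R0", years_grid)
        Xg = np.column_stack([np.ones(len(years_grid)), basis.design(years_grid)])
        assert np.allclose(pred, Xg @ beta, atol=1e-10)

    def test_noiseless_model_data_recovered_at_observation_years(self, years_grid):
        # exact mixed-model data: region curves = fixed spline + region offsets
        basis = build_spline_basis(years_grid)
        rng = np.random.default_rng(3)
        fe = np.array([-0.5, 0.05, 0.001])
        regions = [f"R{i}" for i in range(8)]
        rows = []
        obs_years = np.array([1992, 1995, 1999, 2003, 2007, 2010])
        for r in regions:
            re = rng.normal(0, [0.3, 0.02, 0.002])
            X = np.column_stack([np.ones(len(obs_years)), basis.design(obs_years)])
            vals = X @ (fe + re)
            for y, v in zip(obs_years, vals):
                rows.append({"region": r, "year": y, "transformed_value": v,
                             "indicator": "x", "source": "s", "is_dhs": True,
                             "transformed_variance": 1e-6})
        obs = pd.DataFrame(rows)
        fit = fit_stage1(obs, basis)
        for r in regions:
            pred = predict_stage1(fit, r, obs_years)
            truth = obs[obs.region == r].sort_values("year")["transformed_value"].to_numpy()
            assert np.max(np.abs(pred - truth)) < 1e-6

    def test_recovers_region_trend_ordering(self, years_grid):
        # known region slopes: predicted trends correlate with truth
        g = m.make_region_graph(10, "ring")
        rng = np.random.default_rng(14)
        trends = [LogisticTrend(0.1 + 0.02 * i, 0.5 + 0.04 * i, 2000.0,
                                0.1 + 0.05 * i) for i in range(10)]
        truth, obs = _sim_obs(g, years_grid, seed=4, trends=trends)
        basis = build_spline_basis(years_grid)
        fit = fit_stage1(obs, basis)
        true_slope = logit(truth.values[:, -1]) - logit(truth.values[:, 0])
        pred_slope = np.array([
            (predict_stage1(fit, r, years_grid)[-1]
             - predict_stage1(fit, r, years_grid)[0]) for r in g.region_ids])
        r = np.corrcoef(true_slope, pred_slope)[0, 1]
        assert r > 0.9

    def test_predicted_random_intercepts_sum_near_zero(self, years_grid):
        g = m.make_region_graph(10, "ring")
        _, obs = _sim_obs(g, years_grid, seed=8)
        fit = fit_stage1(obs, build_spline_basis(years_grid))
        if fit.method == "ols":
            pytest.skip("mixed model unavailable on this fixture")
        intercepts = np.array([fit.random_effects[r][0] for r in g.region_ids])
        spread = np.std([fit.random_effects[r][0] for r in g.region_ids]) + 1e-12
        assert abs(intercepts.mean()) < 0.2 * spread + 1e-6


class TestMaternKernel:
    CFG = GPRConfig(amplitude=1.3, nonsampling_var=0.0)

    def test_distance_zero_is_squared_amplitude(self):
        assert matern_cov(2000.0, 2000.0, self.CFG) == pytest.approx(1.3**2)

    def test_nu_half_is_exponential(self):
        cfg = GPRConfig(nu=0.5, length_scale=7.0, amplitude=2.0, nonsampling_var=0.0)
        assert matern_cov(2000.0, 2003.5, cfg) == pytest.approx(4.0 * math.exp(-0.5))

    def test_nu_three_halves_closed_form_at_one_length_scale(self):
        cfg = GPRConfig(nu=1.5, length_scale=10.0, amplitude=1.0, nonsampling_var=0.0)
        expected = (1 + math.sqrt(3)) * math.exp(-math.sqrt(3))
        assert matern_cov(1990.0, 2000.0, cfg) == pytest.approx(expected, rel=1e-12)

    def test_kernel_matrix_symmetric_psd(self):
        grid = np.arange(1990, 2012, dtype=float)
        K = matern_kernel_matrix(grid, grid, self.CFG)
        assert np.allclose(K, K.T)
        assert np.min(np.linalg.eigvalsh(K)) > -1e-9


def mvn_conditioning_oracle(prior_mean, grid, obs_years, y, obs_var, cfg):
    """Brute-force joint multivariate-normal conditioning."""
    m_obs = np.interp(obs_years, grid, prior_mean)
    Kgg = matern_kernel_matrix(grid, grid, cfg)
    Koo = matern_kernel_matrix(obs_years, obs_years, cfg) + np.diag(obs_var + cfg.nonsampling_var)
    Kgo = matern_kernel_matrix(grid, obs_years, cfg)
    Kinv = np.linalg.inv(Koo)
    mean = prior_mean + Kgo @ Kinv @ (y - m_obs)
    cov = Kgg - Kgo @ Kinv @ Kgo.T
    return mean, cov


class TestGPR:
    def test_zero_observations_returns_prior(self, years_grid):
        cfg = GPRConfig(amplitude=1.0, nonsampling_var=0.01)
        prior = np.linspace(-1, 0, len(years_grid))
        surf = fit_gpr(prior, years_grid, pd.DataFrame(
            columns=["year", "transformed_value", "transformed_variance"]), cfg)
        assert np.array_equal(surf.mean, prior)
        assert np.allclose(surf.cov, matern_kernel_matrix(years_grid, years_grid, cfg))

    def test_near_noiseless_observation_is_interpolated(self, years_grid):
        cfg = GPRConfig(amplitude=1.0, nonsampling_var=0.0)
        prior = np.zeros(len(years_grid))
        obs = pd.DataFrame({"year": [2000], "transformed_value": [0.8],
                            "transformed_variance": [1e-12]})
        surf = fit_gpr(prior, years_grid, obs, cfg)
        t = 2000 - years_grid[0]
        assert abs(surf.mean[t] - 0.8) < 1e-8
        assert surf.cov[t, t] < 1e-8

    def test_matches_brute_force_conditioning_oracle(self, years_grid):
        rng = np.random.default_rng(42)
        cfg = GPRConfig(amplitude=0.8, nonsampling_var=0.02)
        prior = rng.standard_normal(len(years_grid)) * 0.3
        yrs = np.sort(rng.choice(years_grid, size=6, replace=False)).astype(float)
        y = rng.standard_normal(6) * 0.5
        var = rng.uniform(0.005, 0.05, size=6)
        obs = pd.DataFrame({"year": yrs, "transformed_value": y,
                            "transformed_variance": var})
        surf = fit_gpr(prior, years_grid, obs, cfg)
        mean, cov = mvn_conditioning_oracle(prior, np.asarray(years_grid, float),
                                            yrs, y, var, cfg)
        assert np.max(np.abs(surf.mean - mean)) < 1e-8
        assert np.max(np.abs(surf.cov - cov)) < 1e-8

    def test_adding_an_observation_never_increases_posterior_variance(self, years_grid):
        rng = np.random.default_rng(11)
        cfg = GPRConfig(amplitude=1.0, nonsampling_var=0.01)
        prior = np.zeros(len(years_grid))
        obs = pd.DataFrame({"year": [1995.0, 2003.0], "transformed_value": [0.2, -0.1],
                            "transformed_variance": [0.02, 0.03]})
        base = fit_gpr(prior, years_grid, obs, cfg)
        more = pd.concat([obs, pd.DataFrame({"year": [2008.0], "transformed_value": [0.3],
                                             "transformed_variance": [0.01]})])
        extended = fit_gpr(prior, years_grid, more, cfg)
        assert np.all(np.diag(extended.cov) <= np.diag(base.cov) + 1e-10)

    def test_reversion_to_prior_far_from_data(self):
        # single observation: the pull decays exactly like the kernel
        grid = np.arange(1990.0, 2060.0)
        cfg = GPRConfig(nu=1.5, length_scale=10.0, amplitude=1.0, nonsampling_var=0.0)
        prior = np.zeros(len(grid))
        obs = pd.DataFrame({"year": [1995.0], "transformed_value": [1.0],
                            "transformed_variance": [0.05]})
        surf = fit_gpr(prior, grid, obs, cfg)
        t0 = 5       # at the data year
        t_far = 35   # 3 length-scales away
        ratio = matern_cov(1995.0 + 30.0, 1995.0, cfg) / matern_cov(1995.0, 1995.0, cfg)
        assert abs(surf.mean[t_far] - ratio * surf.mean[t0]) < 1e-6


class TestDrawAndSummarize:
    def test_degenerate_posterior_collapses_interval(self, years_grid):
        surf = PosteriorSurface("R0", years_grid, np.full(len(years_grid), 0.4),
                                np.zeros((len(years_grid), len(years_grid))))
        s = draw_and_summarize(surf, "proportion", seed=1, n_draws=100)
        assert np.allclose(s["point"], expit(0.4))
        assert np.allclose(s["lower"], s["upper"])

    def test_logit_back_transform_bounds_draws(self, years_grid):
        cov = 4.0 * np.eye(len(years_grid))
        surf = PosteriorSurface("R0", years_grid, np.zeros(len(years_grid)), cov)
        _, draws = draw_and_summarize(surf, "proportion", seed=2, n_draws=500,
                                      return_draws=True)
        assert np.all((draws > 0) & (draws < 1))

    def test_median_commutes_with_monotone_transform(self, years_grid):
        cov = 0.04 * np.eye(len(years_grid))
        mean = np.linspace(-1, 1, len(years_grid))
        surf = PosteriorSurface("R0", years_grid, mean, cov)
        s = draw_and_summarize(surf, "proportion", seed=3, n_draws=100_000)
        assert np.max(np.abs(s["point"].to_numpy() - expit(mean))) < 1e-3


class TestPipeline:
    def test_row_order_and_rerun_invariance(self, years_grid):
        g = m.make_region_graph(4, "ring")
        _, obs = _sim_obs(g, years_grid, seed=10)
        est1 = run_coverage_pipeline(obs, years_grid, seed=5)
        est2 = run_coverage_pipeline(obs.sample(frac=1.0, random_state=7),
                                     years_grid, seed=5)
        pd.testing.assert_frame_equal(est1, est2)

    def test_sparse_indicator_excluded(self, years_grid):
        g = m.make_region_graph(4, "ring")
        _, obs = _sim_obs(g, years_grid, seed=10)
        lone = obs.iloc[[0]].assign(indicator="rare")
        est = run_coverage_pipeline(pd.concat([obs, lone]), years_grid, seed=5)
        assert "rare" not in set(est["indicator"])

    def test_intervals_bracket_points_and_respect_domain(self, years_grid):
        g = m.make_region_graph(4, "ring")
        _, obs = _sim_obs(g, years_grid, seed=10)
        est = run_coverage_pipeline(obs, years_grid, seed=5)
        assert (est["lower"] <= est["point"]).all()
        assert (est["point"] <= est["upper"]).all()
        assert (est["lower"] >= 0).all() and (est["upper"] <= 1).all()
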