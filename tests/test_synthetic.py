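import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import mchbench as m
from mchbench.synthetic import (DEFAULT_HAZARD_SHAPE, LogisticTrend,
                                MortalityModelParams, SurveySchedule, SurveySource,
                                TrueSurface, _segment_probs, sample_constrained_gmrf,
                                simulate_birth_histories,
                                simulate_coverage_observations,
                                simulate_from_mortality_model, simulate_microdata,
                                simulate_true_coverage)


class TestTrueCoverage:
    def test_zero_steepness_is_flat_at_midpoint_value(self, ring10, years_grid):
        tr = LogisticTrend(0.2, 0.6, 2000, 0.0)
        surf = simulate_true_coverage(ring10, years_grid, [tr] * 10)
        assert np.allclose(surf.values, 0.4)

    def test_logistic_limits_are_floor_and_ceiling(self):
        tr = LogisticTrend(0.1, 0.9, 2000, 0.5)
        assert tr([-1e6])[0] == pytest.approx(0.1, abs=1e-12)
        assert tr([1e6])[0] == pytest.approx(0.9, abs=1e-12)

    def test_monotone_in_year_for_positive_steepness(self, ring10, years_grid):
        surf = simulate_true_coverage(ring10, years_grid, seed=5)
        assert np.all(np.diff(surf.values, axis=1) > 0)
        assert surf.values.min() > 0 and surf.values.max() < 1

    def test_deterministic_for_fixed_seed(self, ring10, years_grid):
        a = simulate_true_coverage(ring10, years_grid, seed=11)
        b = simulate_true_coverage(ring10, years_grid, seed=11)
        assert np.array_equal(a.values, b.values)

    def test_ceiling_below_floor_rejected(self):
        with pytest.raises(ValueError, match="ceiling"):
            LogisticTrend(0.5, 0.4, 2000, 1.0)


class TestCoverageObservations:
    def test_infinite_n_and_zero_shift_reproduce_truth(self, ring10, years_grid):
        surf = simulate_true_coverage(ring10, years_grid, seed=2)
        sched = SurveySchedule((SurveySource("DHS0", True, (1995, 2005), 1e14),))
        obs = simulate_coverage_observations(surf, sched, seed=0)
        for _, r in obs.iterrows():
            assert r["estimate"] == pytest.approx(surf.value(r["region"], r["year"]),
                                                  abs=1e-6)

    def test_dhs_sources_get_no_shift(self, ring10, years_grid):
        surf = simulate_true_coverage(ring10, years_grid, seed=2)
        sched = SurveySchedule((SurveySource("DHS0", True, (2000,), 1e14, shift=5.0),))
        obs = simulate_coverage_observations(surf, sched, seed=0)
        # shift declared but is_dhs: transformed value equals logit(truth)
        for _, r in obs.iterrows():
            assert r["transformed_value"] == pytest.approx(
                logit(surf.value(r["region"], r["year"])), abs=1e-6)

    def test_replicate_mean_within_3_mc_se_of_shifted_truth(self, years_grid):
        # 1,000 replicate non-DHS observations of one region-year
        g = m.make_region_graph(2, "line")
        surf = simulate_true_coverage(g, years_grid,
                                      [LogisticTrend(0.3, 0.5, 2000, 0.0)] * 2)
        shift, n_eff = 0.4, 500.0
        srcs = [SurveySource("DHS0", True, (), n_eff)]
        srcs += [SurveySource(f"S{k}", False, (2001,), n_eff, shift) for k in range(1000)]
        obs = simulate_coverage_observations(surf, SurveySchedule(tuple(srcs)), seed=9)
        sub = obs[(obs.region == "R0") & ~obs.is_dhs]
        assert len(sub) == 1000
        p = surf.value("R0", 2001)
        target = logit(p) + shift
        sd = math.sqrt(1.0 / (n_eff * p * (1 - p)))
        mc_se = sd / math.sqrt(1000)
        assert abs(sub["transformed_value"].mean() - target) < 3 * mc_se


class TestMicrodata:
    def test_no_clustering_equal_weights_crude_mean_near_truth(self, years_grid):
        g = m.make_region_graph(2, "line")
        surf = simulate_true_coverage(g, years_grid,
                                      [LogisticTrend(0.35, 0.45, 2000, 0.0)] * 2)
        df = simulate_microdata(surf, 2000, clusters_per_region=50,
                                children_per_cluster=40, weight_dispersion=0.0,
                                cluster_sd=0.0, seed=4)
        sub = df[df.region == "R0"]
        p = surf.value("R0", 2000)
        n = len(sub)
        assert abs(sub["value"].mean() - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_fixed_seed_reproduces_fixture(self, years_grid):
        g = m.make_region_graph(2, "line")
        surf = simulate_true_coverage(g, years_grid, seed=1)
        a = simulate_microdata(surf, 1995, seed=7)
        b = simulate_microdata(surf, 1995, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_design_effect_exceeds_one_with_cluster_variance(self, years_grid):
        g = m.make_region_graph(2, "line")
        surf = simulate_true_coverage(g, years_grid,
                                      [LogisticTrend(0.35, 0.45, 2000, 0.0)] * 2)
        p = surf.value("R0", 2000)
        ests = []
        for rep in range(200):
            df = simulate_microdata(surf, 2000, clusters_per_region=10,
                                    children_per_cluster=15, weight_dispersion=0.0,
                                    cluster_sd=0.12, seed=1000 + rep)
            sub = df[df.region == "R0"]
            ests.append(sub["value"].mean())
        emp_var = np.var(ests, ddof=1)
        srs_var = p * (1 - p) / 150
        assert emp_var / srs_var > 1.0


class TestBirthHistories:
    @staticmethod
    def _flat_truth(graph, years, q5):
        vals = np.full((graph.n_regions, len(years)), q5)
        return TrueSurface(graph.region_ids, years, vals, "mortality")

    def test_zero_mortality_generates_no_deaths(self, years_grid):
        g = m.make_region_graph(2, "line")
        births = simulate_birth_histories(self._flat_truth(g, years_grid, 0.0),
                                          n_mothers=200, seed=3)
        assert births["age_at_death_months"].isna().all()

    def test_certain_immediate_death(self, years_grid):
        g = m.make_region_graph(2, "line")
        shape = (1.0, 0, 0, 0, 0, 0, 0)
        births = simulate_birth_histories(self._flat_truth(g, years_grid, 1.0),
                                          hazard_shape=shape, n_mothers=100, seed=3)
        dead = births["age_at_death_months"].dropna()
        # all uncensored children die at age 0 months
        assert len(dead) > 0
        assert np.allclose(dead, 0.0)

    def test_infeasible_hazard_shape_rejected(self):
        # 90% of deaths in one month-wide segment with q5=1 would need
        # q >= 1 in a later segment once survival is exhausted
        with pytest.raises(ValueError, match="sum to 1"):
            _segment_probs(0.5, (0.5, 0.1), ((0, 1), (1, 60)))

    def test_segment_probs_reproduce_target_q5(self):
        from mchbench.extraction import DEFAULT_AGE_SEGMENTS
        for q5 in (0.05, 0.15, 0.4):
            q = _segment_probs(q5, DEFAULT_HAZARD_SHAPE, DEFAULT_AGE_SEGMENTS)
            assert 1 - np.prod(1 - q) == pytest.approx(q5, abs=1e-12)

    def test_fixed_seed_reproducible(self, years_grid):
        g = m.make_region_graph(2, "line")
        t = self._flat_truth(g, years_grid, 0.1)
        a = simulate_birth_histories(t, n_mothers=50, seed=5)
        b = simulate_birth_histories(t, n_mothers=50, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestMortalityModelSimulator:
    def _schedule(self, years):
        ys = tuple(int(y) for y in years)
        return SurveySchedule((SurveySource("A", True, ys, 1000),
                               SurveySource("B", False, ys, 1000, 0.3)))

    def test_degenerate_variances_give_exact_fixed_effect_curve(self, ring10, years_grid):
        inf = float("inf")
        params = MortalityModelParams(beta0=-2.0, beta1=-0.03, beta2=0.0,
                                      tau_u=inf, tau_v=inf, tau_w=inf,
                                      tau_delta=inf, tau_gamma=inf, sigma2=0.0)
        obs, lat = simulate_from_mortality_model(ring10, years_grid, params,
                                                 self._schedule(years_grid), seed=0)
        tc = years_grid - years_grid.mean()
        expected = expit(-2.0 - 0.03 * tc)
        for _, r in obs.iterrows():
            t = int(r["year"]) - years_grid[0]
            assert r["q5"] == pytest.approx(expected[t], abs=1e-14)

    def test_drawn_effects_satisfy_sum_to_zero(self, ring10, years_grid):
        params = MortalityModelParams()
        _, lat = simulate_from_mortality_model(ring10, years_grid, params,
                                               self._schedule(years_grid), seed=4)
        assert abs(lat["u"].sum()) < 1e-10
        assert abs(lat["v"].sum()) < 1e-10
        assert abs(lat["w"].sum()) < 1e-10
        assert np.all(np.abs(lat["delta"].sum(axis=0)) < 1e-9)
        assert np.all(np.abs(lat["delta"].sum(axis=1)) < 1e-9)

    def test_car_sample_covariance_matches_pseudoinverse(self):
        # Monte-Carlo covariance of constrained ICAR draws vs the
        # linear-algebra oracle pinv(tau * K)
        g = m.make_region_graph(6, "ring")
        K = m.build_icar_precision(g)
        tau = 4.0
        rng = np.random.default_rng(12)
        draws = sample_constrained_gmrf(K, tau, rng, size=1000)
        emp = np.cov(draws.T)
        target = np.linalg.pinv(tau * K)
        # elementwise MC standard error of a covariance entry
        se = np.sqrt((np.outer(np.diag(target), np.diag(target)) + target**2) / 1000)
        assert np.all(np.abs(emp - target) < 4 * se + 1e-12)

    def test_simulator_bit_reproducible(self, ring10, years_grid):
        params = MortalityModelParams()
        o1, _ = simulate_from_mortality_model(ring10, years_grid, params,
                                              self._schedule(years_grid), seed=8)
        o2, _ = simulate_from_mortality_model(ring10, years_grid, params,
                                              self._schedule(years_grid), seed=8)
        pd.testing.assert_frame_equal(o1, o2)
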