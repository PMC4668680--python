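"""Synthetic worlds with the statistical structure the analysis assumes.

The generators here stand in for the restricted multi-survey microdata the
real analysis consumed: region-varying logistic coverage trends bounded in
(0,1), multi-source survey observations with design-based sampling error
and a systematic non-DHS shift on the transformed scale, clustered
weighted microdata, complete birth histories under piecewise-constant
age-specific hazards, and draws from the exact spatiotemporal mortality
model (CAR intercepts/slopes, RW1 year effect, CAR x RW1 interaction, iid
region-source effects) so that estimator recovery and calibration can be
tested against known truth.

All simulators are bit-reproducible for a fixed seed: each draws from a
named substream of the master seed (see :mod:`mchbench.rng`), so running
simulations in a different order never changes any one of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .extraction import DEFAULT_AGE_SEGMENTS, OBS_COLUMNS
from .graphs import RegionGraph
from .rng import stream_rng
from .structure import (build_icar_precision, build_interaction_precision,
                        build_rw1_precision)

__all__ = [
    "TrueSurface", "LogisticTrend", "SurveySource", "SurveySchedule",
    "simulate_true_coverage", "simulate_coverage_observations",
    "simulate_microdata", "simulate_birth_histories",
    "MortalityModelParams", "simulate_from_mortality_model",
    "sample_constrained_gmrf",
]


@dataclass
class TrueSurface:
    """Region x year grid of true values (the simulation ground truth)."""

    region_ids: tuple
    years: np.ndarray
    values: np.ndarray  # (n_regions, n_years)
    scale_tag: str = "proportion"  # proportion | positive | mortality

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), len(self.years)):
            raise ValueError("values must be (n_regions, n_years)")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must form a contiguous integer grid")
        if self.scale_tag == "proportion":
            if np.any(self.values <= 0) or np.any(self.values >= 1):
                raise ValueError("proportion truths must lie strictly in (0,1)")
        elif self.scale_tag == "mortality":
            # probabilities; the exact 0/1 endpoints are legal degenerate
            # truths for birth-history generation
            if np.any(self.values < 0) or np.any(self.values > 1):
                raise ValueError("mortality truths must lie in [0,1]")

    def value(self, region_id, year) -> float:
        i = self.region_ids.index(region_id)
        t = int(year) - int(self.years[0])
        return float(self.values[i, t])


@dataclass(frozen=True)
class LogisticTrend:
    """Logistic-in-time trend between a floor and a ceiling.

    value(t) = floor + (ceiling - floor) * expit(steepness * (t - midpoint))
    """

    floor: float
    ceiling: float
    midpoint: float
    steepness: float

    def __post_init__(self):
        if not (0.0 < self.floor < 1.0 and 0.0 < self.ceiling < 1.0):
            raise ValueError("floor and ceiling must lie in (0,1)")
        if self.ceiling <= self.floor:
            raise ValueError("ceiling must exceed floor")

    def __call__(self, years) -> np.ndarray:
        y = np.asarray(years, dtype=float)
        return self.floor + (self.ceiling - self.floor) * expit(self.steepness * (y - self.midpoint))


def simulate_true_coverage(graph: RegionGraph, years, trend_params=None,
                           seed: int = 0) -> TrueSurface:
    """True coverage surface from per-region logistic trends.

    ``trend_params`` maps region_id -> LogisticTrend (or a sequence in
    region order).  When omitted, plausible region-varying scale-up trends
    are drawn deterministically from the seed: floors 2-25%, ceilings
    45-95%, midpoints spread over the year range, decade-scale steepness.
    """
    years = np.asarray(years, dtype=int)
    if trend_params is None:
        rng = stream_rng(seed, "true-coverage", graph.n_regions)
        trend_params = [
            LogisticTrend(
                floor=rng.uniform(0.02, 0.25),
                ceiling=rng.uniform(0.45, 0.95),
                midpoint=rng.uniform(years[0] + 3, years[-1] - 3),
                steepness=rng.uniform(0.15, 0.6),
            )
            for _ in range(graph.n_regions)
        ]
    if isinstance(trend_params, dict):
        trends = [trend_params[r] for r in graph.region_ids]
    else:
        trends = list(trend_params)
    vals = np.vstack([tr(years) for tr in trends])
    return TrueSurface(graph.region_ids, years, vals, "proportion")


@dataclass(frozen=True)
class SurveySource:
    source_id: str
    is_dhs: bool
    years: tuple
    n_eff: float
    shift: float = 0.0  # additive on the transformed scale, non-DHS only

    def __post_init__(self):
        if self.n_eff <= 0:
            raise ValueError("effective sample size must be positive")


@dataclass
class SurveySchedule:
    """Multi-source survey calendar emulating the study's data landscape."""

    sources: tuple

    def __post_init__(self):
        self.sources = tuple(self.sources)
        if not any(s.is_dhs for s in self.sources):
            raise ValueError("schedule needs at least one DHS-flagged source")


def default_schedule(years, n_eff: float = 1000.0, shift: float = 0.3,
                     n_dhs: int = 4, n_other: int = 1,
                     years_per_survey: int = 6, seed: int = 0) -> SurveySchedule:
    """A schedule shaped like the study's: a handful of DHS-style surveys
    spread over the period plus a non-DHS source with a systematic shift."""
    years = np.asarray(years, dtype=int)
    rng = stream_rng(seed, "schedule")
    sources = []
    span = years[-1] - years[0]
    for k in range(n_dhs):
        anchor = years[0] + int(round((k + 1) * span / (n_dhs + 1)))
        ys = np.unique(np.clip(anchor + rng.integers(-2, 3, size=years_per_survey),
                               years[0], years[-1]))
        sources.append(SurveySource(f"DHS{k}", True, tuple(int(y) for y in ys), n_eff, 0.0))
    for k in range(n_other):
        ys = np.unique(rng.choice(years, size=years_per_survey, replace=False))
        sources.append(SurveySource(f"OTHER{k}", False, tuple(int(y) for y in ys),
                                    n_eff / 2, shift))
    return SurveySchedule(tuple(sources))


def _transform(vals, scale):
    return logit(vals) if scale in ("proportion", "mortality") else np.log(vals)


def simulate_coverage_observations(truth: TrueSurface, schedule: SurveySchedule,
                                   seed: int = 0, indicator: str = "indicator") -> pd.DataFrame:
    """Noisy multi-source observations around a true surface.

    Each observation is drawn on the transformed (logit or log) scale
    around transform(truth) + shift * (1 - is_dhs), with variance set by
    the source's effective sample size (delta-method binomial variance for
    proportions, 1/n_eff for positive quantities).  The transformed-scale
    variance used in generation is recorded alongside, so downstream
    smoothers see honest sampling uncertainty.
    """
    rows = []
    y0 = int(truth.years[0])
    for src in schedule.sources:
        rng = stream_rng(seed, "coverage-obs", indicator, src.source_id)
        for year in src.years:
            if not (truth.years[0] <= year <= truth.years[-1]):
                raise ValueError(f"survey year {year} outside the truth grid")
            t = int(year) - y0
            for i, region in enumerate(truth.region_ids):
                p = truth.values[i, t]
                if truth.scale_tag in ("proportion", "mortality"):
                    var = 1.0 / (src.n_eff * p * (1.0 - p))
                else:
                    var = 1.0 / src.n_eff
                mean = _transform(p, truth.scale_tag) + src.shift * (0.0 if src.is_dhs else 1.0)
                z = mean + math.sqrt(var) * rng.standard_normal()
                if truth.scale_tag in ("proportion", "mortality"):
                    est = float(expit(z))
                    se = math.sqrt(var) * est * (1 - est)
                else:
                    est = float(np.exp(z))
                    se = math.sqrt(var) * est
                rows.append({
                    "region": region, "year": int(year), "source": src.source_id,
                    "is_dhs": bool(src.is_dhs), "indicator": indicator,
                    "estimate": est, "se": se, "transformed_value": float(z),
                    "transformed_variance": float(var), "n_eff": float(src.n_eff),
                })
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def simulate_microdata(truth: TrueSurface, year: int, clusters_per_region: int = 30,
                       children_per_cluster: int = 20, weight_dispersion: float = 0.3,
                       cluster_sd: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Clustered, weighted child records for one survey year.

    Cluster-level coverage probabilities are Beta-distributed with mean
    equal to the regional truth and standard deviation ``cluster_sd`` (on
    the probability scale), which induces intra-cluster correlation while
    keeping the weighted population mean exactly at the truth.  Weights
    are lognormal with log-sd ``weight_dispersion``, independent of
    outcomes.  Ages are uniform over 0-59 months.
    """
    if clusters_per_region <= 0 or children_per_cluster <= 0:
        raise ValueError("design counts must be positive")
    rng = stream_rng(seed, "microdata", int(year))
    t = int(year) - int(truth.years[0])
    rows = []
    for i, region in enumerate(truth.region_ids):
        p = truth.values[i, t]
        max_sd = math.sqrt(p * (1 - p))
        sd = min(cluster_sd, 0.95 * max_sd)
        for c in range(clusters_per_region):
            if sd > 0:
                kappa = p * (1 - p) / sd**2 - 1.0
                pc = rng.beta(p * kappa, (1 - p) * kappa)
                pc = min(max(pc, 1e-9), 1 - 1e-9)
            else:
                pc = p
            m = children_per_cluster
            vals = rng.random(m) < pc
            w = np.exp(rng.normal(0.0, weight_dispersion, size=m)) if weight_dispersion > 0 \
                else np.ones(m)
            ages = rng.integers(0, 60, size=m)
            for k in range(m):
                rows.append({
                    "region": region, "cluster": f"{region}-c{c}",
                    "weight": float(w[k]), "value": int(vals[k]),
                    "age_months": int(ages[k]), "year": int(year),
                })
    return pd.DataFrame(rows)


def _segment_probs(q5: float, hazard_shape, segments) -> np.ndarray:
    """Conditional death probabilities q_a such that the unconditional
    probability of dying in segment a is hazard_shape[a] * q5."""
    shape = np.asarray(hazard_shape, dtype=float)
    if len(shape) != len(segments):
        raise ValueError("hazard_shape must have one entry per age segment")
    if abs(shape.sum() - 1.0) > 1e-9:
        raise ValueError("hazard_shape proportions must sum to 1")
    q = np.zeros(len(shape))
    surv = 1.0
    for a, frac in enumerate(shape):
        d = frac * q5
        if d > surv + 1e-12:
            raise ValueError("infeasible hazard_shape: segment death probability >= 1")
        qa = d / surv if surv > 0 else 1.0
        if qa > 1.0:
            raise ValueError("infeasible hazard_shape: segment death probability >= 1")
        q[a] = qa
        surv *= 1.0 - qa
    return q


#: Default distribution of under-5 deaths over the age segments: heavily
#: front-loaded, as in high-mortality settings (about 30% neonatal).
DEFAULT_HAZARD_SHAPE = (0.30, 0.18, 0.14, 0.16, 0.12, 0.06, 0.04)


def simulate_birth_histories(truth: TrueSurface, hazard_shape=DEFAULT_HAZARD_SHAPE,
                             n_mothers: int = 1000, births_per_mother: float = 3.0,
                             survey_year: Optional[float] = None, seed: int = 0,
                             age_segments=DEFAULT_AGE_SEGMENTS) -> pd.DataFrame:
    """Complete birth histories under piecewise-constant age hazards.

    For each child, the birth-cohort 5q0 is the truth at the calendar year
    of birth; segment hazards are solved so the implied 5q0 equals that
    truth exactly (see :func:`_segment_probs`).  Conditional on dying in a
    segment, the death time follows the truncated exponential of the
    segment's constant hazard.  Children are censored at the survey date;
    deaths that would occur after it are recorded as censored survivals.

    Returns one row per child: region, mother_id, birth_date (decimal
    years), age_at_death_months (NaN if alive at censoring),
    censor_age_months, censored, weight.
    """
    truth_q = truth.values
    if truth.scale_tag not in ("proportion", "mortality"):
        raise ValueError("birth-history truth must be a probability surface")
    years = truth.years
    if survey_year is None:
        survey_year = float(years[-1]) + 1.0
    rows = []
    segs = tuple(age_segments)
    widths = np.array([a1 - a0 for a0, a1 in segs], dtype=float)
    qseg_cache: dict = {}  # cohort q5 values repeat across children
    for i, region in enumerate(truth.region_ids):
        rng = stream_rng(seed, "births", region)
        mother_counter = 0
        for _ in range(n_mothers):
            mother_counter += 1
            mid = f"{region}-m{mother_counter}"
            nb = 1 + rng.poisson(max(births_per_mother - 1.0, 0.0))
            for _ in range(nb):
                bdate = rng.uniform(float(years[0]), survey_year)
                cohort = min(int(bdate), int(years[-1]))
                q5 = truth_q[i, cohort - int(years[0])]
                qseg = qseg_cache.get(q5)
                if qseg is None:
                    qseg = qseg_cache[q5] = _segment_probs(q5, hazard_shape, segs)
                censor_age = (survey_year - bdate) * 12.0
                death_age = np.nan
                age0 = 0.0
                u = rng.random()
                surv = 1.0
                for a, (a0, a1) in enumerate(segs):
                    d = surv * qseg[a]
                    if u < d:
                        # dies in this segment; truncated-exponential time
                        if qseg[a] >= 1.0:
                            death_age = float(a0)
                        else:
                            lam = -math.log(1.0 - qseg[a]) / widths[a]
                            v = rng.random()
                            death_age = a0 - math.log(1.0 - v * (1.0 - math.exp(-lam * widths[a]))) / lam
                        break
                    u -= d
                    surv *= 1.0 - qseg[a]
                if np.isfinite(death_age) and death_age >= censor_age:
                    death_age = np.nan  # death after the survey: censored alive
                rows.append({
                    "region": region, "mother_id": mid, "birth_date": float(bdate),
                    "age_at_death_months": float(death_age) if np.isfinite(death_age) else np.nan,
                    "censor_age_months": float(censor_age),
                    "censored": not np.isfinite(death_age),
                    "weight": 1.0,
                })
    return pd.DataFrame(rows)


def sample_constrained_gmrf(structure: np.ndarray, precision: float,
                            rng: np.random.Generator, size: int = 1,
                            tol: float = 1e-9) -> np.ndarray:
    """Sample from an intrinsic GMRF restricted to the row space of its
    structure matrix (i.e. with its null-space constraints imposed).

    Uses the eigendecomposition of the structure matrix: components along
    zero eigenvalues are dropped, the rest get variance 1/(precision *
    eigenvalue).  For ICAR this enforces sum-to-zero; for the Kronecker
    interaction it enforces all row and column sums to zero.
    """
    vals, vecs = np.linalg.eigh(structure)
    keep = vals > tol * vals.max()
    z = rng.standard_normal((size, int(keep.sum())))
    scale = 1.0 / np.sqrt(precision * vals[keep])
    out = (z * scale) @ vecs[:, keep].T
    return out[0] if size == 1 else out


@dataclass(frozen=True)
class MortalityModelParams:
    """Generating parameters of the spatiotemporal mortality model.

    Time enters centred at the grid midpoint; beta0 is logit 5q0 at the
    centre year for an average region.  Precisions are those of the
    scaled CAR/RW1/interaction/iid priors; sigma2 is the observation
    variance on the logit scale.
    """

    beta0: float = -2.0
    beta1: float = -0.035
    beta2: float = 0.3
    tau_u: float = 50.0
    tau_v: float = 5000.0
    tau_w: float = 400.0
    tau_delta: float = 500.0
    tau_gamma: float = 100.0
    sigma2: float = 0.01

    def __post_init__(self):
        for name in ("tau_u", "tau_v", "tau_w", "tau_delta", "tau_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


def simulate_from_mortality_model(graph: RegionGraph, years,
                                  params: MortalityModelParams,
                                  schedule: SurveySchedule, seed: int = 0):
    """Draw latent effects and observations from the exact mortality model.

    Returns ``(observations, latents)``: a DataFrame of logit-5q0
    observations per region/year/source, and the latent effects used
    (u, v, w, delta, theta grid) for recovery testing.  u, v are
    constrained ICAR draws; w is a constrained RW1 draw; delta is a
    constrained CAR x RW1 interaction draw; gamma_{i,s} are iid normal.
    All sum-to-zero constraints hold by construction of the sampler.
    """
    years = np.asarray(years, dtype=int)
    n, T = graph.n_regions, len(years)
    tc = years - years.mean()  # centred time covariate

    K = build_icar_precision(graph)
    R = build_rw1_precision(T)
    Q = build_interaction_precision(graph, T)

    rng_u = stream_rng(seed, "mort-u")
    rng_v = stream_rng(seed, "mort-v")
    rng_w = stream_rng(seed, "mort-w")
    rng_d = stream_rng(seed, "mort-delta")
    rng_g = stream_rng(seed, "mort-gamma")
    rng_e = stream_rng(seed, "mort-noise")

    u = sample_constrained_gmrf(K, params.tau_u, rng_u)
    v = sample_constrained_gmrf(K, params.tau_v, rng_v)
    w = sample_constrained_gmrf(R, params.tau_w, rng_w)
    delta_flat = sample_constrained_gmrf(Q, params.tau_delta, rng_d)
    delta = delta_flat.reshape(T, n).T  # (n, T); flat index was t*n + i

    theta_grid = (params.beta0 + params.beta1 * tc[None, :]
                  + u[:, None] + v[:, None] * tc[None, :]
                  + w[None, :] + delta)

    gamma = {}
    rows = []
    for src in schedule.sources:
        for i, region in enumerate(graph.region_ids):
            g = rng_g.normal(0.0, 1.0 / math.sqrt(params.tau_gamma))
            gamma[(region, src.source_id)] = g
            for year in src.years:
                t = int(year) - int(years[0])
                mean = theta_grid[i, t] + params.beta2 * (0.0 if src.is_dhs else 1.0) + g
                yobs = mean + math.sqrt(params.sigma2) * rng_e.standard_normal()
                rows.append({
                    "region": region, "year": int(year), "source": src.source_id,
                    "is_dhs": bool(src.is_dhs), "logit_q5": float(yobs),
                    "q5": float(expit(yobs)),
                })
    obs = pd.DataFrame(rows)
    latents = {"u": u, "v": v, "w": w, "delta": delta, "gamma": gamma,
               "theta": theta_grid, "years": years, "tc": tc,
               "region_ids": graph.region_ids, "params": params}
    return obs, latents
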