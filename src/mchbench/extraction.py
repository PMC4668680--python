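"""Turning individual-level survey records into model-ready estimates.

Three jobs live here:

* design-weighted indicator coverage with a design-based standard error
  (Taylor linearization of the ratio estimator, clusters as primary
  sampling units);
* the logit / log transform of an estimate together with its delta-method
  variance, which is the scale on which all smoothing happens;
* direct under-5 mortality (5q0) from complete birth histories by the
  synthetic-cohort life-table method: period-specific death probabilities
  per age segment chained into 1 - prod(1 - q_a), with a mother-level
  jackknife standard error.

Observation tables travel as pandas DataFrames with the documented header
``region, year, source, is_dhs, indicator, estimate, se, transformed_value,
transformed_variance, n_eff``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "OBS_COLUMNS",
    "IndicatorDefinition",
    "CoverageEstimate",
    "weighted_coverage",
    "transform_observation",
    "back_transform",
    "DEFAULT_AGE_SEGMENTS",
    "Direct5q0",
    "direct_5q0",
    "read_observations",
    "write_observations",
]

OBS_COLUMNS = [
    "region", "year", "source", "is_dhs", "indicator",
    "estimate", "se", "transformed_value", "transformed_variance", "n_eff",
]


@dataclass(frozen=True)
class IndicatorDefinition:
    """An indicator as a pair of pure predicates plus an age window.

    ``numerator`` and ``denominator`` map a record DataFrame to boolean
    Series; records outside ``age_window`` (months, half-open) are dropped
    before either predicate is evaluated.
    """

    indicator_id: str
    numerator: Callable[[pd.DataFrame], pd.Series] = None
    denominator: Callable[[pd.DataFrame], pd.Series] = None
    age_window: tuple = (0, 60)
    scale: str = "proportion"  # or "positive"

    def __post_init__(self):
        lo, hi = self.age_window
        if not lo < hi:
            raise ValueError("age window lower bound must be below upper bound")


@dataclass
class CoverageEstimate:
    estimate: float
    se: float
    n: int
    n_eff: Optional[float]
    missing: bool = False
    reason: str = ""


def weighted_coverage(microdata: pd.DataFrame, definition: IndicatorDefinition,
                      cluster_col: str = "cluster", weight_col: str = "weight",
                      value_col: str = "value", age_col: str = "age_months") -> CoverageEstimate:
    """Design-weighted coverage with a Taylor-linearized design-based SE.

    The estimator is the weighted ratio mean p = sum(w*y)/sum(w) over
    denominator records inside the age window.  Its variance treats
    clusters as with-replacement primary sampling units: with cluster
    totals z_c = sum_{k in c} w_k (y_k - p),

        var(p) = m/(m-1) * sum_c z_c^2 / (sum_k w_k)^2 ,

    the standard first-order linearization for a single-stage design.
    A single-cluster input falls back to the weighted SRS variance.
    An empty denominator yields a flagged missing estimate rather than an
    exception, so one empty survey cell cannot kill a pipeline run.
    """
    df = microdata
    lo, hi = definition.age_window
    if age_col in df.columns:
        df = df[(df[age_col] >= lo) & (df[age_col] < hi)]
    if definition.denominator is not None:
        df = df[definition.denominator(df).astype(bool)]
    if len(df) == 0:
        return CoverageEstimate(np.nan, np.nan, 0, None, missing=True,
                                reason="empty denominator after age window")
    if definition.numerator is not None:
        y = definition.numerator(df).astype(float).to_numpy()
    else:
        y = df[value_col].astype(float).to_numpy()
    w = df[weight_col].astype(float).to_numpy()
    W = w.sum()
    p = float(np.dot(w, y) / W)

    clusters = df[cluster_col].to_numpy()
    _, cidx = np.unique(clusters, return_inverse=True)
    m = cidx.max() + 1
    resid = w * (y - p)
    if m >= 2:
        z = np.bincount(cidx, weights=resid, minlength=m)
        var = m / (m - 1) * float(np.sum(z**2)) / W**2
    else:
        k = len(y)
        var = (k / (k - 1) * float(np.sum(resid**2)) / W**2) if k > 1 else 0.0
    se = math.sqrt(max(var, 0.0))
    if 0.0 < p < 1.0 and var > 0:
        n_eff = p * (1 - p) / var
    else:
        n_eff = float(len(y))
    return CoverageEstimate(p, se, int(len(y)), n_eff)


def _clamp_proportion(p: float, n_eff: Optional[float]) -> float:
    # Boundary handling before logit: keep estimates a quarter-count away
    # from 0/1 when the effective sample size is known.
    eps = 1.0 / (4.0 * n_eff) if (n_eff is not None and n_eff > 0) else 0.001
    eps = min(eps, 0.25)
    return min(max(p, eps), 1.0 - eps)


def transform_observation(estimate: float, se: float, scale: str = "proportion",
                          n_eff: Optional[float] = None):
    """Map a natural-scale estimate and SE to the modelling scale.

    Proportions go through the logit with delta-method variance
    var/(p(1-p))^2; positive quantities through the log with variance
    var/x^2.  A non-positive SE is only accepted when an effective sample
    size allows a binomial fallback.
    """
    if scale not in ("proportion", "positive"):
        raise ValueError(f"unknown scale tag {scale!r}")
    se = float(se) if se is not None and np.isfinite(se) else -1.0
    if se <= 0:
        if scale == "proportion" and n_eff and n_eff > 0:
            p0 = _clamp_proportion(float(estimate), n_eff)
            se = math.sqrt(p0 * (1 - p0) / n_eff)
        else:
            raise ValueError("non-positive SE and no effective-n fallback")
    if scale == "proportion":
        p = _clamp_proportion(float(estimate), n_eff)
        tv = float(logit(p))
        tvar = se**2 / (p * (1 - p)) ** 2
    else:
        x = float(estimate)
        if x <= 0:
            raise ValueError("positive-scale estimate must be > 0")
        tv = math.log(x)
        tvar = se**2 / x**2
    return tv, tvar


def back_transform(values, scale: str = "proportion"):
    """Inverse of the modelling-scale transform, elementwise."""
    arr = np.asarray(values, dtype=float)
    if scale == "proportion":
        return expit(arr)
    if scale == "positive":
        return np.exp(arr)
    raise ValueError(f"unknown scale tag {scale!r}")


#: Age segments (months, half-open) of the synthetic-cohort life table:
#: neonatal-ish first month, remainder of infancy split at 6 months, then
#: yearly bands to age five.
DEFAULT_AGE_SEGMENTS = ((0, 1), (1, 6), (6, 12), (12, 24), (24, 36), (36, 48), (48, 60))


@dataclass
class Direct5q0:
    q5: float
    se: float
    deaths: np.ndarray
    exposure: np.ndarray
    missing: bool = False
    reason: str = ""


def _segment_tallies(birth_months, end_months, died, weights, p0, p1, segments):
    """Weighted deaths and child-month exposures per age segment inside the
    calendar window [p0, p1), all in months."""
    nseg = len(segments)
    D = np.zeros(nseg)
    E = np.zeros(nseg)
    for s, (a0, a1) in enumerate(segments):
        start = np.maximum(birth_months + a0, p0)
        stop = np.minimum(np.minimum(birth_months + a1, end_months), p1)
        exp_m = np.clip(stop - start, 0.0, None)
        E[s] = float(np.dot(weights, exp_m))
        age_end = end_months - birth_months
        dies_here = died & (age_end >= a0) & (age_end < a1) \
            & (end_months >= p0) & (end_months < p1)
        D[s] = float(np.dot(weights, dies_here.astype(float)))
    return D, E


def direct_5q0(births: pd.DataFrame, region_id=None, period=None,
               age_segments: Sequence = DEFAULT_AGE_SEGMENTS,
               jackknife: bool = True) -> Direct5q0:
    """Direct under-5 mortality from complete birth histories.

    For each age segment a the weighted period death rate m_a =
    deaths_a / exposure_a (per child-month) is converted to a segment
    probability q_a = 1 - exp(-m_a * width_a), and the synthetic-cohort
    probability of dying before age five is 1 - prod_a (1 - q_a).  The
    standard error is a leave-one-mother-out jackknife, which respects the
    correlation of outcomes within a mother's birth history.

    ``births`` columns: region, mother_id, birth_date (decimal years),
    age_at_death_months (NaN if alive at censoring), censor_age_months,
    weight.  ``period`` is a (start_year, end_year) window, inclusive of
    start, exclusive of end+1 (calendar years of exposure).
    """
    df = births
    if region_id is not None:
        df = df[df["region"] == region_id]
    if len(df) == 0:
        return Direct5q0(np.nan, np.nan, np.zeros(len(age_segments)),
                         np.zeros(len(age_segments)), missing=True, reason="no births")
    birth_months = df["birth_date"].to_numpy(float) * 12.0
    death_age = df["age_at_death_months"].to_numpy(float)
    died = np.isfinite(death_age)
    censor_age = df["censor_age_months"].to_numpy(float)
    end_age = np.where(died, death_age, censor_age)
    end_months = birth_months + end_age
    weights = df["weight"].to_numpy(float)
    if period is None:
        p0, p1 = -np.inf, np.inf
    else:
        p0, p1 = period[0] * 12.0, (period[1] + 1) * 12.0

    segs = tuple(age_segments)
    D, E = _segment_tallies(birth_months, end_months, died, weights, p0, p1, segs)
    q5 = _q5_from_tallies(D, E, segs)
    if not np.isfinite(q5):
        bad = [segs[i] for i in np.where(E <= 0)[0]]
        return Direct5q0(np.nan, np.nan, D, E, missing=True,
                         reason=f"zero exposure in age segment(s) {bad}")

    se = np.nan
    if jackknife:
        mothers = df["mother_id"].to_numpy()
        uniq, midx = np.unique(mothers, return_inverse=True)
        M = len(uniq)
        if M >= 2:
            # per-mother tallies, then leave-one-out totals
            nseg = len(segs)
            Dm = np.zeros((M, nseg))
            Em = np.zeros((M, nseg))
            for s, (a0, a1) in enumerate(segs):
                start = np.maximum(birth_months + a0, p0)
                stop = np.minimum(np.minimum(birth_months + a1, end_months), p1)
                exp_m = np.clip(stop - start, 0.0, None)
                age_end = end_months - birth_months
                dies_here = died & (age_end >= a0) & (age_end < a1) \
                    & (end_months >= p0) & (end_months < p1)
                Em[:, s] = np.bincount(midx, weights=weights * exp_m, minlength=M)
                Dm[:, s] = np.bincount(midx, weights=weights * dies_here, minlength=M)
            stats = []
            for j in range(M):
                s_j = _q5_from_tallies(D - Dm[j], E - Em[j], segs)
                if np.isfinite(s_j):
                    stats.append(s_j)
            stats = np.asarray(stats)
            if len(stats) >= 2:
                mj = len(stats)
                se = math.sqrt((mj - 1) / mj * float(np.sum((stats - stats.mean()) ** 2)))
    return Direct5q0(q5, se, D, E)


def _q5_from_tallies(D, E, segments) -> float:
    """Chain segment probabilities; NaN marks a segment with zero exposure
    while the synthetic cohort still has survivors (a true data gap).
    Zero exposure with deaths means instantaneous mortality (q_a = 1)."""
    surv = 1.0
    for s, (a0, a1) in enumerate(segments):
        if surv <= 0.0:
            break
        if E[s] <= 0:
            if D[s] > 0:
                surv = 0.0
                break
            return float("nan")
        m = D[s] / E[s]
        q = 1.0 - math.exp(-m * (a1 - a0))
        surv *= 1.0 - q
    return 1.0 - surv


def read_observations(path) -> pd.DataFrame:
    """Read an observation table, skipping provenance comment lines."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation file {path} lacks columns {missing}")
    return df


def write_observations(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
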