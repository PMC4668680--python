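"""Two-stage smoother for regional indicator trends.

Stage 1 fits a linear mixed-effects model on the transformed scale with a
one-knot natural cubic spline in time (two basis columns) as fixed
effects and region-level random intercepts and slopes on the same
columns, so levels and trends can vary between regions.  The region's
predicted curve — fixed effects plus best linear unbiased predictions of
its random effects — is the mean prior for stage 2.

Stage 2 is Gaussian process regression with a Matern covariance: exact
Gaussian conditioning of the prior mean on the observed points, each
weighted by its own transformed-scale sampling variance plus a
non-sampling variance floor.  Uncertainty is propagated by drawing from
the posterior (1,000 draws by default), back-transforming each draw, and
summarising per year by the median and the 2.5th/97.5th percentiles.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .extraction import back_transform
from .rng import stream_rng

__all__ = [
    "SplineBasis", "build_spline_basis", "Stage1Fit", "fit_stage1",
    "predict_stage1", "GPRConfig", "matern_cov", "matern_kernel_matrix",
    "PosteriorSurface", "fit_gpr", "draw_and_summarize", "run_coverage_pipeline",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# stage 1: natural cubic spline basis + mixed model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineBasis:
    """One-interior-knot natural cubic spline basis with two columns.

    h1(t) is the (centred) linear term; h2(t) is the single curvature
    basis of the natural cubic spline with knots (b0, k, b1), built from
    truncated cubics so the function is linear beyond the boundary knots.
    """

    interior_knot: float
    boundary_knots: tuple

    def __post_init__(self):
        b0, b1 = self.boundary_knots
        if not b0 < self.interior_knot < b1:
            raise ValueError("interior knot must lie strictly inside the boundary knots")

    def design(self, years) -> np.ndarray:
        """Evaluate [h1, h2] at the given years; shape (len(years), 2).

        Both columns are scaled to O(1) over the knot interval (fitted
        values are invariant to this re-parameterization, but the mixed
        model's covariance estimation is far better conditioned).
        """
        t = np.asarray(years, dtype=float)
        b0, b1 = self.boundary_knots
        k = self.interior_knot
        h1 = (t - 0.5 * (b0 + b1)) / (0.5 * (b1 - b0))

        def d(xi):
            return (np.clip(t - xi, 0, None) ** 3 - np.clip(t - b1, 0, None) ** 3) / (b1 - xi)

        # value of the raw curvature basis at b1: its maximum on [b0, b1]
        norm = (b1 - b0) ** 2 - (b1 - k) ** 2
        h2 = (d(b0) - d(k)) / norm
        return np.column_stack([h1, h2])


def build_spline_basis(years, interior_knot: Optional[float] = None) -> SplineBasis:
    """Basis over a year grid; the interior knot defaults to the midpoint
    of the range (e.g. 2000.5 for 1990-2011), boundary knots to the range
    endpoints."""
    years = np.asarray(years, dtype=float)
    if len(np.unique(years)) < 3:
        raise ValueError("need at least 3 distinct years for a spline basis")
    b0, b1 = float(years.min()), float(years.max())
    if interior_knot is None:
        interior_knot = 0.5 * (b0 + b1)
    return SplineBasis(float(interior_knot), (b0, b1))


@dataclass
class Stage1Fit:
    """Fitted spline mixed model: the GPR mean prior factory."""

    basis: SplineBasis
    fixed_effects: np.ndarray            # (3,) intercept, h1, h2
    random_effects: Dict[object, np.ndarray]  # region -> (3,) BLUPs
    cov_re: np.ndarray
    resid_var: float
    converged: bool
    method: str                           # reml | ml | ols


def _ols_fit(basis: SplineBasis, years, values) -> tuple:
    X = np.column_stack([np.ones(len(years)), basis.design(years)])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    dof = max(len(values) - X.shape[1], 1)
    return beta, float(resid @ resid / dof)


def fit_stage1(observations: pd.DataFrame, basis: SplineBasis) -> Stage1Fit:
    """REML fit of the spline mixed model on transformed values.

    Falls back REML -> ML -> fixed-effects-only OLS when the mixed model
    cannot be fit (single region, too few observations, or
    non-convergence), logging the step taken.  Degenerate (zero)
    random-effect variances are legal and simply yield zero BLUPs.
    """
    obs = observations.sort_values(["region", "year"]).reset_index(drop=True)
    y = obs["transformed_value"].to_numpy(float)
    years = obs["year"].to_numpy(float)
    regions = obs["region"].to_numpy()
    n_regions = len(pd.unique(regions))

    if n_regions < 2 or len(obs) <= 4:
        beta, rv = _ols_fit(basis, years, y)
        return Stage1Fit(basis, beta, {}, np.zeros((3, 3)), rv, True, "ols")

    import statsmodels.api as sm

    H = basis.design(years)
    X = np.column_stack([np.ones(len(y)), H])
    for method in ("reml", "ml"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(y, X, groups=regions, exog_re=X)
                res = md.fit(reml=(method == "reml"), method="lbfgs", maxiter=200)
            if not np.all(np.isfinite(res.fe_params)):
                raise ValueError("non-finite fixed effects")
            fe = np.asarray(res.fe_params, float)
            re = {g: np.asarray(b)[:3].astype(float) for g, b in res.random_effects.items()}
            if res.scale < 1e-10 * max(float(np.var(y)), 1e-12):
                # noiseless limit: BLUPs converge to per-region least
                # squares; compute that limit exactly instead of relying
                # on the optimizer's final shrinkage factor
                for g in re:
                    mask = regions == g
                    if mask.sum() >= 3:
                        Xg = X[mask]
                        bg, *_ = np.linalg.lstsq(Xg, y[mask] - Xg @ fe, rcond=None)
                        re[g] = bg
            return Stage1Fit(basis, fe, re,
                             np.asarray(res.cov_re, float), float(res.scale),
                             bool(res.converged), method)
        except Exception as exc:  # noqa: BLE001 - any optimizer failure falls through
            log.warning("stage-1 %s fit failed (%s); falling back", method, exc)
    beta, rv = _ols_fit(basis, years, y)
    log.warning("stage-1 mixed model unavailable; using fixed-effects-only fit")
    return Stage1Fit(basis, beta, {}, np.zeros((3, 3)), rv, False, "ols")


def predict_stage1(fit: Stage1Fit, region_id, years) -> np.ndarray:
    """Prior mean on the transformed scale: fixed effects plus the
    region's predicted random effects (zero vector for unseen regions)."""
    X = np.column_stack([np.ones(len(years)), fit.basis.design(years)])
    coef = fit.fixed_effects + fit.random_effects.get(region_id, np.zeros(3))
    return X @ coef


# ---------------------------------------------------------------------------
# stage 2: Matern GPR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRConfig:
    """Gaussian-process settings for the stage-2 smoother.

    nu is the Matern smoothness (1/2, 3/2 or 5/2); length_scale is in
    years; amplitude is the prior standard deviation on the transformed
    scale; nonsampling_var is a variance floor added to every
    observation's sampling variance.  ``amplitude``/``nonsampling_var``
    default to None, meaning "derive from the stage-1 fit": the stage-1
    residual variance decomposes into the observations' mean sampling
    variance plus an excess (model / non-sampling) variance, and that
    excess serves as both amplitude^2 (how far the truth may wander from
    the prior mean) and the per-observation variance floor (source-level
    systematic error).  The excess is floored at 10% of the residual
    variance so the prior never collapses entirely.
    """

    nu: float = 1.5
    length_scale: float = 10.0
    amplitude: Optional[float] = None
    nonsampling_var: Optional[float] = None
    n_draws: int = 1000

    def __post_init__(self):
        if self.nu not in (0.5, 1.5, 2.5):
            raise ValueError("nu must be one of 1/2, 3/2, 5/2")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.n_draws < 2:
            raise ValueError("need at least 2 posterior draws")

    def resolved(self, stage1: Stage1Fit,
                 mean_sampling_var: float = 0.0) -> "GPRConfig":
        excess = max(stage1.resid_var - mean_sampling_var, 0.1 * stage1.resid_var)
        amp = self.amplitude if self.amplitude is not None else math.sqrt(excess)
        nsv = self.nonsampling_var if self.nonsampling_var is not None else excess
        return replace(self, amplitude=float(amp), nonsampling_var=float(nsv))


def matern_cov(t1: float, t2: float, config: GPRConfig) -> float:
    """Matern covariance between two years (closed forms for the three
    half-integer smoothness values)."""
    if config.amplitude is None:
        raise ValueError("config amplitude unresolved; call config.resolved(stage1)")
    d = abs(float(t1) - float(t2)) / config.length_scale
    a2 = config.amplitude**2
    if config.nu == 0.5:
        return a2 * math.exp(-d)
    if config.nu == 1.5:
        s = math.sqrt(3.0) * d
        return a2 * (1.0 + s) * math.exp(-s)
    s = math.sqrt(5.0) * d
    return a2 * (1.0 + s + s * s / 3.0) * math.exp(-s)


def matern_kernel_matrix(t_a, t_b, config: GPRConfig) -> np.ndarray:
    ta = np.asarray(t_a, float)[:, None]
    tb = np.asarray(t_b, float)[None, :]
    d = np.abs(ta - tb) / config.length_scale
    a2 = config.amplitude**2
    if config.nu == 0.5:
        return a2 * np.exp(-d)
    if config.nu == 1.5:
        s = math.sqrt(3.0) * d
        return a2 * (1.0 + s) * np.exp(-s)
    s = math.sqrt(5.0) * d
    return a2 * (1.0 + s + s**2 / 3.0) * np.exp(-s)


@dataclass
class PosteriorSurface:
    """Per-region GPR posterior on the year grid (transformed scale)."""

    region_id: object
    years: np.ndarray
    mean: np.ndarray
    cov: np.ndarray


def fit_gpr(prior_mean: np.ndarray, grid_years, observations: pd.DataFrame,
            config: GPRConfig, region_id=None) -> PosteriorSurface:
    """Exact Gaussian conditioning of the stage-1 prior on the data.

    posterior mean = m + K_*' (K + D)^-1 (y - m_obs), with D diagonal
    holding each observation's sampling variance plus the non-sampling
    floor; replicate observations in one year are retained as separate
    heteroskedastic conditioning points.  With zero observations the
    prior is returned untouched.  A singular (K + D) gets one shot of
    1e-8 jitter before the failure propagates.
    """
    grid = np.asarray(grid_years, float)
    m = np.asarray(prior_mean, float)
    if m.shape != grid.shape:
        raise ValueError("prior mean and year grid must align")
    Kgg = matern_kernel_matrix(grid, grid, config)
    if len(observations) == 0:
        return PosteriorSurface(region_id, grid.astype(int), m.copy(), Kgg)
    t_obs = observations["year"].to_numpy(float)
    if np.any(t_obs < grid.min()) or np.any(t_obs > grid.max()):
        raise ValueError("observation years fall outside the grid")
    y = observations["transformed_value"].to_numpy(float)
    svar = observations["transformed_variance"].to_numpy(float)
    if np.any(~np.isfinite(svar)):
        raise ValueError("every observation needs a transformed-scale variance")
    # prior mean at the observation years: interpolate the grid prior
    m_obs = np.interp(t_obs, grid, m)
    Koo = matern_kernel_matrix(t_obs, t_obs, config)
    Kgo = matern_kernel_matrix(grid, t_obs, config)
    D = np.diag(svar + config.nonsampling_var)
    A = Koo + D
    try:
        cf = cho_factor(A, lower=True)
    except np.linalg.LinAlgError:
        cf = cho_factor(A + 1e-8 * np.eye(len(A)), lower=True)
    alpha = cho_solve(cf, y - m_obs)
    mean = m + Kgo @ alpha
    cov = Kgg - Kgo @ cho_solve(cf, Kgo.T)
    cov = 0.5 * (cov + cov.T)
    return PosteriorSurface(region_id, grid.astype(int), mean, cov)


def draw_and_summarize(surface: PosteriorSurface, scale: str = "proportion",
                       seed: int = 0, n_draws: int = 1000,
                       indicator_id: Optional[str] = None,
                       return_draws: bool = False):
    """Posterior draws, back-transform, and median / 95% summaries.

    Draws come from the posterior Gaussian on the transformed scale via
    an eigenvalue square root (negative eigenvalues from roundoff are
    clipped to zero), are back-transformed elementwise, and summarised
    per year by the median and 2.5th/97.5th percentiles.
    """
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    rng = stream_rng(seed, "gpr-draws", indicator_id or "", surface.region_id)
    vals, vecs = np.linalg.eigh(surface.cov)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = rng.standard_normal((n_draws, len(surface.mean)))
    draws_t = surface.mean[None, :] + z @ root.T
    draws = back_transform(draws_t, scale)
    point = np.median(draws, axis=0)
    lower = np.percentile(draws, 2.5, axis=0)
    upper = np.percentile(draws, 97.5, axis=0)
    series = pd.DataFrame({
        "indicator": indicator_id, "region": surface.region_id,
        "year": surface.years, "point": point, "lower": lower, "upper": upper,
    })
    if return_draws:
        return series, draws
    return series


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

NATIONAL = "national"


def run_coverage_pipeline(observations: pd.DataFrame, years,
                          scales: Optional[Dict[str, str]] = None,
                          gpr_config: GPRConfig = GPRConfig(),
                          seed: int = 0, interior_knot: Optional[float] = None,
                          national: bool = True, return_draws: bool = False):
    """Stage 1 + stage 2 for every indicator in an observation table.

    For each indicator: fit the spline mixed model across regions, then
    condition each region's prior on its own observations with GPR and
    summarise 1,000 back-transformed draws.  A national series runs the
    same machinery on the nation-pooled observations.  Indicators with
    fewer than two observations are excluded with a logged reason.
    Observations are sorted internally, so input row order is irrelevant.

    Returns a tidy estimates DataFrame (indicator, region, year, point,
    lower, upper) and, when requested, a dict of natural-scale draw
    matrices keyed by (indicator, region).
    """
    years = np.asarray(years, dtype=int)
    scales = scales or {}
    obs = observations.sort_values(["indicator", "region", "year", "source"]).reset_index(drop=True)
    all_series = []
    all_draws = {}
    for ind, sub in obs.groupby("indicator", sort=True):
        if len(sub) < 2:
            log.warning("indicator %s has <2 observations; excluded", ind)
            continue
        scale = scales.get(ind, "proportion")
        basis = build_spline_basis(years, interior_knot)
        fit = fit_stage1(sub, basis)
        msv = float(sub["transformed_variance"].mean())
        cfg = gpr_config.resolved(fit, msv)
        region_list = list(pd.unique(sub["region"]))
        targets = [(r, sub[sub["region"] == r]) for r in region_list]
        if national:
            targets.append((NATIONAL, sub))
        for region, robs in targets:
            if region == NATIONAL:
                nat_basis = build_spline_basis(years, interior_knot)
                nat_fit = fit_stage1(robs.assign(region=NATIONAL), nat_basis)
                prior = predict_stage1(nat_fit, NATIONAL, years)
                cfg_r = gpr_config.resolved(nat_fit, msv)
            else:
                prior = predict_stage1(fit, region, years)
                cfg_r = cfg
            surface = fit_gpr(prior, years, robs, cfg_r, region_id=region)
            series, draws = draw_and_summarize(
                surface, scale=scale, seed=seed, n_draws=cfg_r.n_draws,
                indicator_id=ind, return_draws=True)
            all_series.append(series)
            all_draws[(ind, region)] = draws
    if not all_series:
        empty = pd.DataFrame(columns=["indicator", "region", "year", "point", "lower", "upper"])
        return (empty, all_draws) if return_draws else empty
    est = pd.concat(all_series, ignore_index=True)
    return (est, all_draws) if return_draws else est
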