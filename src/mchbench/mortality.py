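"""Bayesian hierarchical spatiotemporal model for under-5 mortality.

Observed logit(5q0) values by region, year and source follow

    logit(5q0)_{its} ~ Normal(theta_{its}, sigma^2)
    theta_{its} = b0 + b1*t + b2*1[s not DHS] + u_i + v_i*t + w_t
                  + delta_{it} + gamma_{is}

with intrinsic CAR priors on the region intercepts u and slopes v, an RW1
prior on the year effect w, a CAR x RW1 interaction prior on delta, iid
normal region-source effects gamma, weakly informative normal priors on
the fixed effects and gamma priors on all precisions.  Inference is by
Gibbs sampling: every block has a Gaussian full conditional given the
precisions, and every precision a gamma full conditional.  Sum-to-zero
constraints (u, v, w, and both margins of delta) are enforced after each
block update by re-centring, with the removed means transferred into the
matching fixed effect so the likelihood is untouched.

Predictions drop the non-DHS adjustment and the source effects: the
posterior of theta_{it} is summarised by its median and 2.5th/97.5th
percentiles, inverse-logit transformed to the 5q0 scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .graphs import RegionGraph
from .rng import stream_rng
from .structure import (build_icar_precision, build_interaction_precision,
                        build_rw1_precision)

__all__ = [
    "build_icar_precision", "build_rw1_precision", "build_interaction_precision",
    "MortalityPriors", "MCMCSettings", "MortalityPosterior",
    "fit_mortality_model", "predict_5q0",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MortalityPriors:
    """Weakly informative defaults: Normal(0, 31.6^2) on fixed effects,
    Gamma(shape 1, rate 0.01) on every precision (random effects and the
    observation noise)."""

    beta_sd: float = 31.6
    gamma_shape: float = 1.0
    gamma_rate: float = 0.01


@dataclass(frozen=True)
class MCMCSettings:
    iterations: int = 5000
    burnin: Optional[int] = None      # default: iterations // 2
    chains: int = 2
    seed: int = 0

    @property
    def n_burn(self) -> int:
        return self.iterations // 2 if self.burnin is None else self.burnin


@dataclass
class MortalityPosterior:
    """Posterior samples and summaries from the Gibbs sampler.

    theta_samples holds the prediction-scale linear predictor (non-DHS
    shift and source effects set to zero) with shape
    (n_samples, n_regions, n_years), chains concatenated.
    """

    region_ids: tuple
    years: np.ndarray
    theta_samples: np.ndarray
    beta_samples: np.ndarray        # (S, 3)
    tau_samples: pd.DataFrame       # columns tau_u .. tau_gamma, sigma2
    rhat: Dict[str, float]
    u_samples: np.ndarray
    v_samples: np.ndarray
    w_samples: np.ndarray

    def summaries(self) -> pd.DataFrame:
        """Region-year 5q0 medians and 95% intervals."""
        qs = np.percentile(self.theta_samples, [50.0, 2.5, 97.5], axis=0)
        rows = []
        for i, region in enumerate(self.region_ids):
            for t, year in enumerate(self.years):
                med, lo, hi = expit(qs[0, i, t]), expit(qs[1, i, t]), expit(qs[2, i, t])
                rows.append({"region": region, "year": int(year),
                             "median": med, "lower": lo, "upper": hi})
        return pd.DataFrame(rows)

    def max_rhat(self) -> float:
        return max(self.rhat.values())


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of a (n_chains, n_iter) array of one scalar summary."""
    n_chains, n_iter = chains.shape
    half = n_iter // 2
    if half < 2:
        return np.nan
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = segs.shape
    means = segs.mean(axis=1)
    W = segs.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def _sample_gaussian(prec: np.ndarray, b: np.ndarray, rng) -> np.ndarray:
    """Draw from N(prec^{-1} b, prec^{-1}) via one Cholesky factorization:
    x = L^{-T}(L^{-1} b + z) with prec = L L^T and z standard normal."""
    from scipy.linalg import solve_triangular

    L = np.linalg.cholesky(prec)
    tmp = solve_triangular(L, b, lower=True, check_finite=False)
    z = rng.standard_normal(len(b))
    return solve_triangular(L.T, tmp + z, lower=False, check_finite=False)


def fit_mortality_model(observations: pd.DataFrame, graph: RegionGraph, years,
                        mcmc: MCMCSettings = MCMCSettings(),
                        priors: MortalityPriors = MortalityPriors()) -> MortalityPosterior:
    """Gibbs sampler for the spatiotemporal mortality model.

    ``observations`` needs columns region, year, source, is_dhs and
    either logit_q5 or q5.  Every observed region must be in the graph
    and every year on the grid.  Split-R-hat is reported for the fixed
    effects, log precisions and log sigma^2; values above 1.1 trigger a
    warning advising longer chains.
    """
    years = np.asarray(years, dtype=int)
    n, T = graph.n_regions, len(years)
    obs = observations.reset_index(drop=True)
    if "logit_q5" in obs.columns:
        yv = obs["logit_q5"].to_numpy(float)
    elif "q5" in obs.columns:
        q = obs["q5"].to_numpy(float)
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("q5 observations must lie strictly in (0,1)")
        yv = logit(q)
    else:
        raise ValueError("observations need a logit_q5 or q5 column")
    if not np.all(np.isfinite(yv)):
        raise ValueError("non-finite observation values")

    ridx = {r: i for i, r in enumerate(graph.region_ids)}
    try:
        iidx = np.array([ridx[r] for r in obs["region"]], dtype=int)
    except KeyError as exc:
        raise ValueError(f"observed region {exc} not in graph") from None
    yr = obs["year"].to_numpy(int)
    if np.any(yr < years[0]) or np.any(yr > years[-1]):
        raise ValueError("observed years fall outside the year grid")
    tidx = yr - int(years[0])
    nd = (~obs["is_dhs"].astype(bool)).to_numpy().astype(float)
    tc_grid = years - years.mean()
    tc = tc_grid[tidx]

    pairs = list(zip(obs["region"], obs["source"]))
    cmap: Dict[tuple, int] = {}
    for c in pairs:
        cmap.setdefault(c, len(cmap))
    gidx = np.array([cmap[c] for c in pairs], dtype=int)
    n_g = len(cmap)

    K = build_icar_precision(graph)
    R = build_rw1_precision(T)
    Q = build_interaction_precision(graph, T)
    rank_K, rank_R, rank_Q = n - 1, T - 1, (n - 1) * (T - 1)

    # Sum-to-zero contrast bases (Helmert): u = Bn @ u~, w = BT @ w~ and
    # delta = kron(BT, Bn) @ d~, so every constraint holds identically and
    # the intrinsic priors become proper on the reduced coordinates.
    from scipy.linalg import helmert

    Bn = helmert(n).T            # (n, n-1), columns orthonormal, _|_ 1
    BT = helmert(T).T            # (T, T-1)
    Ktil = Bn.T @ K @ Bn
    Rtil = BT.T @ R @ BT
    Qtil = np.kron(Rtil, Ktil)   # prior structure of d~, nonsingular
    BKron = np.kron(BT, Bn)      # maps d~ back to the (T*n) grid

    N = len(yv)
    # one design matrix for the whole Gaussian mean structure:
    # [1, t, nonDHS | u~ | v~ (xt) | w~ | d~ | gamma]
    A_beta = np.column_stack([np.ones(N), tc, nd])
    A_u = Bn[iidx, :]
    A_v = Bn[iidx, :] * tc[:, None]
    A_w = BT[tidx, :]
    A_d = (BT[tidx, :, None] * Bn[iidx, None, :]).reshape(N, (T - 1) * (n - 1))
    A_g = np.zeros((N, n_g))
    A_g[np.arange(N), gidx] = 1.0
    A = np.concatenate([A_beta, A_u, A_v, A_w, A_d, A_g], axis=1)
    p = A.shape[1]
    AtA = A.T @ A
    Aty = A.T @ yv
    # slices into the coefficient vector
    s_beta = slice(0, 3)
    s_u = slice(3, 3 + (n - 1))
    s_v = slice(s_u.stop, s_u.stop + (n - 1))
    s_w = slice(s_v.stop, s_v.stop + (T - 1))
    s_d = slice(s_w.stop, s_w.stop + (T - 1) * (n - 1))
    s_g = slice(s_d.stop, s_d.stop + n_g)

    a0, b0 = priors.gamma_shape, priors.gamma_rate
    beta_prec = 1.0 / priors.beta_sd**2

    n_keep = mcmc.iterations - mcmc.n_burn
    if n_keep < 2:
        raise ValueError("iterations must exceed burn-in by at least 2")

    theta_keep = np.empty((mcmc.chains, n_keep, n, T))
    beta_keep = np.empty((mcmc.chains, n_keep, 3))
    u_keep = np.empty((mcmc.chains, n_keep, n))
    v_keep = np.empty((mcmc.chains, n_keep, n))
    w_keep = np.empty((mcmc.chains, n_keep, T))
    monitored = {k: np.empty((mcmc.chains, n_keep))
                 for k in ("beta0", "beta1", "beta2", "log_tau_u", "log_tau_v",
                           "log_tau_w", "log_tau_delta", "log_tau_gamma", "log_sigma2")}
    tau_rows = []

    for chain in range(mcmc.chains):
        rng = stream_rng(mcmc.seed, "mortality-gibbs", chain)
        x = np.zeros(p)
        x[0] = float(np.mean(yv))
        tau_u = tau_v = tau_w = tau_d = tau_g = 1.0
        sigma2 = max(float(np.var(yv)) * 0.1, 1e-4)

        for it in range(mcmc.iterations):
            inv_s2 = 1.0 / sigma2

            # joint Gaussian update of all mean components: exact full
            # conditional given the precisions, so the near-confounded
            # directions (e.g. beta1 vs the RW1 trend) mix perfectly
            prec = AtA * inv_s2
            prec[s_beta, s_beta] += np.eye(3) * beta_prec
            prec[s_u, s_u] += tau_u * Ktil
            prec[s_v, s_v] += tau_v * Ktil
            prec[s_w, s_w] += tau_w * Rtil
            prec[s_d, s_d] += tau_d * Qtil
            prec[s_g, s_g] += tau_g * np.eye(n_g)
            x = _sample_gaussian(prec, Aty * inv_s2, rng)

            beta = x[s_beta]
            u = Bn @ x[s_u]
            v = Bn @ x[s_v]
            w = BT @ x[s_w]
            D = (BKron @ x[s_d]).reshape(T, n)
            gam = x[s_g]

            # conjugate precision updates
            tau_u = rng.gamma(a0 + 0.5 * rank_K, 1.0 / (b0 + 0.5 * u @ K @ u))
            tau_v = rng.gamma(a0 + 0.5 * rank_K, 1.0 / (b0 + 0.5 * v @ K @ v))
            tau_w = rng.gamma(a0 + 0.5 * rank_R, 1.0 / (b0 + 0.5 * w @ R @ w))
            dflat = D.reshape(-1)
            tau_d = rng.gamma(a0 + 0.5 * rank_Q, 1.0 / (b0 + 0.5 * dflat @ (Q @ dflat)))
            tau_g = rng.gamma(a0 + 0.5 * n_g, 1.0 / (b0 + 0.5 * gam @ gam))
            resid = yv - A @ x
            sigma2 = 1.0 / rng.gamma(a0 + 0.5 * N, 1.0 / (b0 + 0.5 * resid @ resid))

            if it >= mcmc.n_burn:
                k = it - mcmc.n_burn
                theta_keep[chain, k] = (beta[0] + beta[1] * tc_grid[None, :]
                                        + u[:, None] + v[:, None] * tc_grid[None, :]
                                        + w[None, :] + D.T)
                beta_keep[chain, k] = beta
                u_keep[chain, k] = u; v_keep[chain, k] = v; w_keep[chain, k] = w
                monitored["beta0"][chain, k] = beta[0]
                monitored["beta1"][chain, k] = beta[1]
                monitored["beta2"][chain, k] = beta[2]
                monitored["log_tau_u"][chain, k] = math.log(tau_u)
                monitored["log_tau_v"][chain, k] = math.log(tau_v)
                monitored["log_tau_w"][chain, k] = math.log(tau_w)
                monitored["log_tau_delta"][chain, k] = math.log(tau_d)
                monitored["log_tau_gamma"][chain, k] = math.log(tau_g)
                monitored["log_sigma2"][chain, k] = math.log(sigma2)
                tau_rows.append((chain, tau_u, tau_v, tau_w, tau_d, tau_g, sigma2))

    rhat = {k: _split_rhat(v) for k, v in monitored.items()}
    bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > 1.1}
    if bad:
        log.warning("split-R-hat above 1.1 for %s; consider longer chains", bad)

    S = mcmc.chains * n_keep
    tau_df = pd.DataFrame(tau_rows, columns=["chain", "tau_u", "tau_v", "tau_w",
                                             "tau_delta", "tau_gamma", "sigma2"])
    return MortalityPosterior(
        region_ids=graph.region_ids, years=years,
        theta_samples=theta_keep.reshape(S, n, T),
        beta_samples=beta_keep.reshape(S, 3),
        tau_samples=tau_df, rhat=rhat,
        u_samples=u_keep.reshape(S, n),
        v_samples=v_keep.reshape(S, n),
        w_samples=w_keep.reshape(S, T),
    )


def predict_5q0(posterior: MortalityPosterior, region_id, year) -> dict:
    """Median and 95% interval of 5q0 for one region-year.

    The prediction-scale theta excludes the non-DHS adjustment and the
    source effects; quantiles are taken on the logit scale and
    inverse-logit transformed (valid because the transform is monotone).
    """
    i = posterior.region_ids.index(region_id)
    t = int(year) - int(posterior.years[0])
    if not 0 <= t < len(posterior.years):
        raise ValueError(f"year {year} not in the fitted grid")
    s = posterior.theta_samples[:, i, t]
    lo, med, hi = np.percentile(s, [2.5, 50.0, 97.5])
    return {"median": float(expit(med)), "lower": float(expit(lo)),
            "upper": float(expit(hi))}
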