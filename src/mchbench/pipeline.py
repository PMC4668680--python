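"""Configuration, input validation, and the end-to-end driver.

``run_all`` reproduces the whole benchmarking analysis on either
user-supplied observation tables or the packaged synthetic world: it fits
regional coverage trends for every indicator, fits the spatiotemporal
mortality model, assembles the overall coverage index with uncertainty,
ranks regions, computes benchmarking correlations, and writes everything
as CSV with a provenance header (config hash + master seed).  Outputs are
deterministic: the same config and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import benchmark as bm
from .extraction import OBS_COLUMNS, read_observations, write_observations
from .graphs import RegionGraph, uganda_region_graph
from .mortality import MCMCSettings, MortalityPriors, fit_mortality_model
from .rng import stream_rng
from .synthetic import (LogisticTrend, SurveySchedule, SurveySource, TrueSurface,
                        default_schedule, simulate_coverage_observations,
                        simulate_true_coverage)
from .trends import GPRConfig, run_coverage_pipeline

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_inputs", "read_region_graph", "build_demo_world",
           "run_all"]


@dataclass
class RunConfig:
    """Everything a full run needs; YAML-serializable."""

    out_dir: str = "mchbench_out"
    seed: int = 0
    year_start: int = 1990
    year_end: int = 2011
    coverage_obs: Optional[str] = None     # CSV path; None -> packaged demo world
    mortality_obs: Optional[str] = None
    adjacency: Optional[str] = None        # None -> default 10-region graph
    indicators: Dict[str, str] = field(default_factory=lambda: {
        **{c: "proportion" for c in bm.INDEX_COMPONENTS}, "edu_years": "positive"})
    index_components: tuple = bm.INDEX_COMPONENTS
    interior_knot: Optional[float] = None
    gpr_nu: float = 1.5
    gpr_length_scale: float = 10.0
    gpr_draws: int = 1000
    mcmc_iterations: int = 3000
    mcmc_chains: int = 2
    write_draws: bool = False

    def __post_init__(self):
        if len(self.index_components) != 11:
            raise ValueError("exactly 11 indicators must be flagged as index components")
        missing = [c for c in self.index_components if c not in self.indicators]
        if missing:
            raise ValueError(f"index components not in the indicator registry: {missing}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "index_components" in data:
            data["index_components"] = tuple(data["index_components"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["index_components"] = list(self.index_components)
        return d

    def config_hash(self) -> str:
        # out_dir is a destination, not analysis content: two runs of the
        # same analysis into different directories hash identically
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_region_graph(path) -> RegionGraph:
    """Adjacency from a JSON file ({regions, edges by id}) or an edge-list
    CSV with columns region_a, region_b."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        regions = tuple(data["regions"])
        idx = {r: i for i, r in enumerate(regions)}
        edges = tuple((idx[a], idx[b]) for a, b in data["edges"])
        return RegionGraph(region_ids=regions, edges=edges)
    df = pd.read_csv(path, comment="#")
    regions = tuple(pd.unique(pd.concat([df["region_a"], df["region_b"]])))
    idx = {r: i for i, r in enumerate(regions)}
    edges = tuple((idx[a], idx[b]) for a, b in zip(df["region_a"], df["region_b"]))
    return RegionGraph(region_ids=regions, edges=edges)


def validate_inputs(obs_file, adjacency_file=None, scales: Optional[Dict[str, str]] = None) -> list:
    """Non-mutating validation report: a list of human-readable problems
    (empty when the inputs are clean).

    ``scales`` maps indicator id -> {proportion | positive}; the [0,1]
    range check only applies to proportion indicators.  Defaults to the
    standard registry (index components plus ``edu_years``); indicators
    absent from the registry are treated as proportions.
    """
    if scales is None:
        scales = {**{c: "proportion" for c in bm.INDEX_COMPONENTS},
                  "edu_years": "positive"}
    problems = []
    try:
        obs = read_observations(obs_file)
    except (OSError, ValueError) as exc:
        return [f"cannot read observation file {obs_file}: {exc}"]
    graph = None
    if adjacency_file is not None:
        try:
            graph = read_region_graph(adjacency_file)
        except (OSError, ValueError, KeyError) as exc:
            problems.append(f"cannot read adjacency file {adjacency_file}: {exc}")
    if graph is not None:
        unknown = sorted(set(obs["region"]) - set(graph.region_ids))
        for r in unknown:
            problems.append(f"region {r!r} in observations but not in adjacency")
    bad_year = obs[(obs["year"] < 1900) | (obs["year"] > 2100)]
    for _, row in bad_year.iterrows():
        problems.append(f"implausible year {row['year']} ({row['region']}, {row['indicator']})")
    bad_var = obs[obs["transformed_variance"] <= 0]
    for _, row in bad_var.iterrows():
        problems.append(
            f"non-positive transformed variance for {row['region']} "
            f"{row['year']} {row['indicator']}")
    is_prop = obs["indicator"].map(lambda i: scales.get(i, "proportion") == "proportion")
    prop = obs[is_prop & ((obs["estimate"] < 0) | (obs["estimate"] > 1))]
    for _, row in prop.iterrows():
        problems.append(
            f"estimate {row['estimate']} outside [0,1] for {row['region']} "
            f"{row['year']} {row['indicator']}")
    return problems


# ---------------------------------------------------------------------------
# packaged synthetic demo world
# ---------------------------------------------------------------------------

# Base logistic-trend parameters per indicator (floor, ceiling, midpoint
# year, steepness); regions jitter deterministically around these.  The
# shapes mirror the broad historical patterns the analysis targets: rapid
# post-2004 malaria scale-up, early high BCG, flat ANC4/OPV3, declining
# underweight (negative steepness).
_DEMO_TRENDS = {
    "itn_irs":     (0.02, 0.60, 2006.0, 0.80),
    "iptp2":       (0.01, 0.30, 2004.0, 0.50),
    "act":         (0.01, 0.50, 2007.0, 0.90),
    "ebf":         (0.50, 0.63, 2000.0, 0.15),
    "bcg":         (0.72, 0.94, 1996.0, 0.30),
    "measles":     (0.58, 0.85, 2000.0, 0.25),
    "opv3":        (0.62, 0.77, 1997.0, 0.20),
    "pentavalent": (0.02, 0.78, 2005.0, 0.90),
    "anc4":        (0.44, 0.50, 2000.0, 0.10),
    "sba":         (0.30, 0.70, 2003.0, 0.25),
    "underweight": (0.12, 0.23, 2000.0, -0.20),
}


def _demo_trend_params(graph: RegionGraph, seed: int) -> Dict[str, list]:
    out = {}
    for ind, (flo, cei, mid, steep) in _DEMO_TRENDS.items():
        rng = stream_rng(seed, "demo-trend", ind)
        params = []
        for _ in range(graph.n_regions):
            f = float(np.clip(flo * rng.uniform(0.7, 1.3), 0.005, 0.97))
            c = float(np.clip(cei * rng.uniform(0.85, 1.15), f + 0.02, 0.99))
            params.append(LogisticTrend(f, c, mid + rng.uniform(-2, 2),
                                        steep * rng.uniform(0.7, 1.3)))
        out[ind] = params
    return out


def build_demo_world(seed: int = 0, years=None, graph: Optional[RegionGraph] = None,
                     n_eff: float = 1000.0, non_dhs_shift: float = 0.3,
                     mortality_sd: float = 0.08) -> dict:
    """The packaged synthetic world: truths and observations for the 11
    index indicators plus a positive-scale education series, and a
    mortality truth generated as a decreasing function of the true
    overall coverage index plus noise (so the benchmarking correlation
    has a known sign).

    Returns a dict with the graph, year grid, per-indicator truths,
    coverage/mortality observation tables and the true index surface.
    """
    graph = graph or uganda_region_graph()
    years = np.arange(1990, 2012) if years is None else np.asarray(years, int)
    trend_params = _demo_trend_params(graph, seed)
    truths: Dict[str, TrueSurface] = {}
    obs_frames = []
    for ind in _DEMO_TRENDS:
        truth = simulate_true_coverage(graph, years, trend_params[ind], seed=seed)
        truths[ind] = truth
        schedule = default_schedule(years, n_eff=n_eff, shift=non_dhs_shift,
                                    seed=int(stream_rng(seed, "sched", ind).integers(2**31)))
        obs_frames.append(simulate_coverage_observations(truth, schedule,
                                                         seed=seed, indicator=ind))

    # positive-scale series: mean years of maternal education, rising
    rng_e = stream_rng(seed, "demo-edu")
    base = rng_e.uniform(1.5, 3.5, size=graph.n_regions)
    slope = rng_e.uniform(0.08, 0.16, size=graph.n_regions)
    edu_vals = base[:, None] + slope[:, None] * (years - years[0])[None, :]
    edu_truth = TrueSurface(graph.region_ids, years, edu_vals, "positive")
    truths["edu_years"] = edu_truth
    edu_sched = default_schedule(years, n_eff=4 * n_eff, shift=0.0, n_other=0, seed=seed)
    obs_frames.append(simulate_coverage_observations(edu_truth, edu_sched,
                                                     seed=seed, indicator="edu_years"))
    coverage_obs = pd.concat(obs_frames, ignore_index=True)

    # true overall index, then mortality as a noisy decreasing function of it
    comp_stack = np.mean(
        [1.0 - truths[c].values if c in bm.COMPLEMENTED_COMPONENTS else truths[c].values
         for c in bm.INDEX_COMPONENTS], axis=0)
    rng_m = stream_rng(seed, "demo-mortality")
    logit_q5 = -0.85 - 2.5 * comp_stack + rng_m.normal(0.0, 0.05, size=comp_stack.shape)
    q5_truth = TrueSurface(graph.region_ids, years, expit(logit_q5), "mortality")

    # three birth-history sources: two DHS-style, one shifted non-DHS
    rng_o = stream_rng(seed, "demo-mort-obs")
    sources = [("DHS_A", True, years[:len(years) * 3 // 4]),
               ("DHS_B", True, years[len(years) // 4:]),
               ("SURV_C", False, years[len(years) // 3: len(years) * 5 // 6])]
    rows = []
    for sid, is_dhs, ys in sources:
        for i, region in enumerate(graph.region_ids):
            for y in ys:
                t = int(y) - int(years[0])
                mu = logit(q5_truth.values[i, t]) + (0.0 if is_dhs else non_dhs_shift)
                z = mu + mortality_sd * rng_o.standard_normal()
                rows.append({"region": region, "year": int(y), "source": sid,
                             "is_dhs": is_dhs, "logit_q5": float(z),
                             "q5": float(expit(z))})
    mortality_obs = pd.DataFrame(rows)
    return {"graph": graph, "years": years, "truths": truths,
            "coverage_obs": coverage_obs, "mortality_obs": mortality_obs,
            "q5_truth": q5_truth, "true_index": comp_stack}


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, header_lines) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def run_all(config: RunConfig) -> Path:
    """Run the whole analysis and write the output directory.

    Outputs: coverage_estimates.csv, mortality_estimates.csv,
    league_table.csv, correlations.csv, run_log.txt (plus draws.csv when
    requested).  A stage failure leaves earlier outputs in place and is
    summarised in the run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]
    log_lines = [f"config_hash={config.config_hash()}", f"seed={config.seed}",
                 f"year grid: {config.year_start}-{config.year_end}",
                 f"spline interior knot: "
                 f"{config.interior_knot if config.interior_knot is not None else 'midpoint of range'}",
                 f"GPR: Matern nu={config.gpr_nu}, length_scale={config.gpr_length_scale} y, "
                 f"amplitude^2 = noise floor = stage-1 excess (non-sampling) variance, "
                 f"draws={config.gpr_draws}",
                 "priors: Normal(0, 31.6^2) fixed effects; Gamma(1, 0.01) precisions",
                 "logit clamp: [1/(4 n_eff), 1 - 1/(4 n_eff)], fallback [0.001, 0.999]"]
    years = config.years

    if config.adjacency:
        graph = read_region_graph(config.adjacency)
    else:
        graph = uganda_region_graph()
        log_lines.append("adjacency: packaged approximate 10-region default")

    if config.coverage_obs:
        coverage_obs = read_observations(config.coverage_obs)
        problems = validate_inputs(config.coverage_obs, config.adjacency,
                                   scales=config.indicators)
        for p in problems:
            log_lines.append(f"validation: {p}")
        mortality_obs = pd.read_csv(config.mortality_obs, comment="#") \
            if config.mortality_obs else None
        world = None
    else:
        world = build_demo_world(seed=config.seed, years=years, graph=graph)
        coverage_obs = world["coverage_obs"]
        mortality_obs = world["mortality_obs"]
        log_lines.append("inputs: packaged synthetic demo world")

    def fail(stage, exc):
        log_lines.append(f"STAGE FAILURE in {stage}: {exc!r}")
        log.error("stage %s failed: %r", stage, exc)

    estimates = pd.DataFrame()
    draws = {}
    try:
        known = coverage_obs["indicator"].isin(config.indicators)
        dropped = sorted(set(coverage_obs.loc[~known, "indicator"]))
        if dropped:
            log_lines.append(f"dropped undeclared indicators: {dropped}")
        gpr = GPRConfig(nu=config.gpr_nu, length_scale=config.gpr_length_scale,
                        n_draws=config.gpr_draws)
        estimates, draws = run_coverage_pipeline(
            coverage_obs[known], years, scales=config.indicators, gpr_config=gpr,
            seed=config.seed, interior_knot=config.interior_knot, return_draws=True)
        _write_csv(estimates, out / "coverage_estimates.csv", header)
        log_lines.append(f"coverage: {estimates['indicator'].nunique()} indicators, "
                         f"{len(estimates)} region-year estimates")
    except Exception as exc:  # noqa: BLE001 - stage isolation by design
        fail("coverage_trends", exc)

    mort_summ = pd.DataFrame()
    if mortality_obs is not None and len(mortality_obs):
        try:
            mcmc = MCMCSettings(iterations=config.mcmc_iterations,
                                chains=config.mcmc_chains, seed=config.seed)
            posterior = fit_mortality_model(mortality_obs, graph, years, mcmc)
            mort_summ = posterior.summaries()
            _write_csv(mort_summ, out / "mortality_estimates.csv", header)
            log_lines.append(f"mortality: max split-R-hat {posterior.max_rhat():.3f}")
        except Exception as exc:  # noqa: BLE001
            fail("mortality_model", exc)
    else:
        log_lines.append("mortality: no observations supplied; stage skipped")

    try:
        avail = set(estimates["indicator"].unique()) if len(estimates) else set()
        if set(config.index_components) <= avail:
            idx_rows = []
            regions_only = [r for r in pd.unique(estimates["region"]) if r != "national"]
            for region in regions_only:
                comp_draws = {}
                complete = True
                for c in config.index_components:
                    key = (c, region)
                    if key not in draws:
                        complete = False
                        break
                    comp_draws[c] = draws[key]
                if not complete:
                    log_lines.append(f"index not computed for region {region}: "
                                     "missing component draws")
                    continue
                idx_rows.append(bm.index_uncertainty(comp_draws, region_id=region,
                                                     years=years,
                                                     component_ids=config.index_components))
            index_df = pd.concat(idx_rows, ignore_index=True)
            table = bm.league_table(index_df)
            _write_csv(table, out / "league_table.csv", header)
        else:
            missing = sorted(set(config.index_components) - avail)
            log_lines.append(f"index not computed: missing components {missing}")
            table = pd.DataFrame()
            _write_csv(pd.DataFrame(columns=["region", "year", "index", "lower",
                                             "upper", "rank"]),
                       out / "league_table.csv", header)
    except Exception as exc:  # noqa: BLE001
        fail("benchmarking/index", exc)
        table = pd.DataFrame()

    try:
        corr_rows = []
        if len(table) and len(mort_summ):
            merged = table.merge(mort_summ, on=["region", "year"])
            merged = merged[merged["region"] != "national"]
            corr_rows.append({
                "pair": "overall_coverage~under5_mortality",
                "rho": bm.pearson_correlation(merged["index"], merged["median"]),
                "n": len(merged)})
        if len(table) and len(estimates):
            edu = estimates[(estimates["indicator"] == "edu_years")
                            & (estimates["region"] != "national")]
            if len(edu):
                m2 = table.merge(edu, on=["region", "year"])
                corr_rows.append({
                    "pair": "overall_coverage~edu_years",
                    "rho": bm.pearson_correlation(m2["index"], m2["point"]),
                    "n": len(m2)})
                if len(mort_summ):
                    m3 = edu.merge(mort_summ, on=["region", "year"])
                    corr_rows.append({
                        "pair": "under5_mortality~edu_years",
                        "rho": bm.pearson_correlation(m3["median"], m3["point"]),
                        "n": len(m3)})
        _write_csv(pd.DataFrame(corr_rows, columns=["pair", "rho", "n"]),
                   out / "correlations.csv", header)
    except Exception as exc:  # noqa: BLE001
        fail("benchmarking/correlations", exc)

    if config.write_draws and draws:
        frames = []
        for (ind, region), mat in sorted(draws.items()):
            nd, ny = mat.shape
            frames.append(pd.DataFrame({
                "indicator": ind, "region": region,
                "year": np.tile(years, nd), "draw": np.repeat(np.arange(nd), ny),
                "value": mat.reshape(-1)}))
        _write_csv(pd.concat(frames, ignore_index=True), out / "draws.csv", header)

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
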