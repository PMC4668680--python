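"""Overall intervention coverage index and benchmarking correlations.

The overall index is the equal-weight arithmetic mean of 11 intervention
coverages spanning the continuum of care — malaria vector control
(ITN ownership or IRS), IPTp2, ACT receipt after fever, exclusive
breastfeeding, BCG / measles / OPV3 / pentavalent immunization, ANC4,
skilled birth attendance, and child nutrition entering as the proportion
of children *not* underweight.  Uncertainty is propagated by averaging
matched posterior draws of the components.  Benchmarking comparisons use
Pearson correlations over pooled region-year pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "INDEX_COMPONENTS", "COMPLEMENTED_COMPONENTS", "CoverageIndex",
    "overall_coverage", "index_series", "index_uncertainty",
    "pearson_correlation", "league_table",
]

#: The 11 component indicators of the overall coverage index.
INDEX_COMPONENTS = (
    "itn_irs", "iptp2", "act", "ebf", "bcg", "measles", "opv3",
    "pentavalent", "anc4", "sba", "underweight",
)

#: Components stored as an adverse prevalence: enter the index as 1 - value.
COMPLEMENTED_COMPONENTS = frozenset({"underweight"})


@dataclass
class CoverageIndex:
    region_id: object
    year: int
    components: Dict[str, float]   # already complement-adjusted, each in [0,1]
    value: float


def _oriented(components: Dict[str, float],
              component_ids: Sequence[str] = INDEX_COMPONENTS) -> Dict[str, float]:
    missing = [c for c in component_ids if c not in components]
    if missing:
        raise KeyError(f"missing index components: {missing}")
    out = {}
    for c in component_ids:
        v = float(components[c])
        out[c] = 1.0 - v if c in COMPLEMENTED_COMPONENTS else v
    return out


def overall_coverage(components: Dict[str, float], region_id=None, year=None,
                     component_ids: Sequence[str] = INDEX_COMPONENTS) -> CoverageIndex:
    """Equal-weight mean of the 11 components for one region-year.

    ``components`` maps indicator id -> natural-scale estimate;
    underweight is complemented before averaging.  All components must be
    present — a missing one means the index is not computed for that
    region-year (callers log and skip).
    """
    oriented = _oriented(components, component_ids)
    vals = np.array([oriented[c] for c in component_ids], dtype=float)
    return CoverageIndex(region_id, year, oriented, float(vals.mean()))


def index_series(estimates: pd.DataFrame,
                 component_ids: Sequence[str] = INDEX_COMPONENTS) -> pd.DataFrame:
    """Overall index per region-year from a tidy estimates table
    (indicator, region, year, point).  Region-years lacking any component
    are skipped with a log message."""
    rows = []
    wide = estimates.pivot_table(index=["region", "year"], columns="indicator",
                                 values="point", aggfunc="first")
    for (region, year), row in wide.iterrows():
        comp = {c: row[c] for c in component_ids if c in row and np.isfinite(row[c])}
        try:
            idx = overall_coverage(comp, region, year, component_ids)
        except KeyError as exc:
            log.info("index skipped for %s %s: %s", region, year, exc)
            continue
        rows.append({"region": region, "year": int(year), "index": idx.value})
    return pd.DataFrame(rows)


def index_uncertainty(component_draws: Dict[str, np.ndarray], region_id=None,
                      years=None,
                      component_ids: Sequence[str] = INDEX_COMPONENTS) -> pd.DataFrame:
    """Index series with a 95% interval from matched posterior draws.

    ``component_draws`` maps indicator id -> (n_draws, n_years) natural-
    scale draw matrix; draw d of the index is the equal-weight mean of
    the components' draw d (complemented where required), so component
    correlations within a draw are preserved.
    """
    missing = [c for c in component_ids if c not in component_draws]
    if missing:
        raise KeyError(f"missing index components: {missing}")
    shapes = {component_draws[c].shape for c in component_ids}
    if len(shapes) != 1:
        raise ValueError(f"mismatched draw-matrix shapes: {sorted(shapes)}")
    stack = []
    for c in component_ids:
        d = np.asarray(component_draws[c], dtype=float)
        stack.append(1.0 - d if c in COMPLEMENTED_COMPONENTS else d)
    draws = np.mean(stack, axis=0)  # (n_draws, n_years)
    point = np.median(draws, axis=0)
    lower = np.percentile(draws, 2.5, axis=0)
    upper = np.percentile(draws, 97.5, axis=0)
    n_years = draws.shape[1]
    years = np.arange(n_years) if years is None else np.asarray(years)
    return pd.DataFrame({"region": region_id, "year": years,
                         "index": point, "lower": lower, "upper": upper})


def pearson_correlation(series_a, series_b) -> float:
    """Product-moment correlation over paired values.

    Requires at least 3 pairs and non-zero variance in both series; a
    degenerate series raises rather than silently returning NaN.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    return float(stats.pearsonr(a, b).statistic)


def league_table(index_df: pd.DataFrame) -> pd.DataFrame:
    """Rank regions within each year by the overall index (1 = highest)."""
    df = index_df.copy()
    df["rank"] = df.groupby("year")["index"].rank(ascending=False, method="min").astype(int)
    return df.sort_values(["year", "rank"]).reset_index(drop=True)
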