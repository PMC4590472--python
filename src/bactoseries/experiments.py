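"""Temperature-size incubation analysis and seasonal-window trends.

The incubation design manipulates only temperature (in situ -3, in situ,
in situ +3 deg C; triplicate bottles) and reads out mean cell size per
cytometric group.  The monthly response is the model I (ordinary least
squares) slope of bottle mean cell size on incubation temperature, in
um^3 per deg C; temperature is treated as fixed and error-free.

Seasonal-window statistics average a monthly series over a calendar-month
window (April-July by default) within each analysis year (April-March)
and regress the annual means on year, the standard way decadal warming is
quantified when trends are seasonally uneven.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import MonthlySeries

__all__ = [
    "SlopeResult",
    "WindowTrend",
    "size_temperature_slope",
    "cross_group_slope_regression",
    "window_mean_series",
    "annual_trend",
    "projected_size_change",
]

ANALYSIS_YEAR_START_MONTH = 4  # analysis years run April-March


@dataclass
class SlopeResult:
    month: int
    group: str
    slope: float  # um^3 per deg C
    intercept: float  # um^3
    r_squared: float
    p_value: float
    se: float
    n: int


@dataclass
class WindowTrend:
    window_months: tuple[int, ...]
    annual: pd.DataFrame  # columns: year, mean, se, n
    slope_per_year: float
    intercept: float
    r_squared: float
    p_value: float
    n_years: int


def _summarize_bottles(records: pd.DataFrame, summary: str) -> pd.DataFrame:
    """One size value per bottle (temperature x replicate).

    ``summary`` picks the time points entering the bottle mean:
    'growth_phase' (default; points up to the within-bottle abundance
    maximum, requires an abundance column), 'mean' (all points) or
    'final' (last point).
    """
    if summary not in {"growth_phase", "mean", "final"}:
        raise ValueError(f"unknown bottle summary {summary!r}")

    def one_bottle(g: pd.DataFrame) -> float:
        g = g.sort_values("timepoint_h")
        if summary == "final":
            return float(g["size_um3"].iloc[-1])
        if summary == "growth_phase" and "abundance_cells_ml" in g.columns:
            cutoff = g.loc[g["abundance_cells_ml"].idxmax(), "timepoint_h"]
            g = g[g["timepoint_h"] <= cutoff]
        return float(g["size_um3"].mean())

    out = (
        records.groupby(["temp_C", "replicate"], sort=True)
        .apply(one_bottle, include_groups=False)
        .rename("size_um3")
        .reset_index()
    )
    return out


def size_temperature_slope(
    records: pd.DataFrame, summary: str = "growth_phase"
) -> SlopeResult:
    """Model I regression of bottle mean cell size on incubation
    temperature for one month and one group.

    ``records`` must hold a single (month, group) cell with columns
    temp_C, replicate, timepoint_h, size_um3 (abundance_cells_ml optional,
    used by the growth-phase bottle summary).
    """
    months = records["month"].unique() if "month" in records.columns else [0]
    groups = records["group"].unique() if "group" in records.columns else ["?"]
    if len(months) != 1 or len(groups) != 1:
        raise ValueError("records must cover exactly one month and one group")
    if (records["size_um3"] <= 0).any():
        raise ValueError("cell sizes must be positive")
    bottles = _summarize_bottles(records, summary)
    if len(bottles) < 3:
        raise ValueError(f"need >= 3 bottle points, got {len(bottles)}")
    if bottles["temp_C"].nunique() < 2:
        raise ValueError("need at least two distinct temperature levels")
    res = stats.linregress(bottles["temp_C"], bottles["size_um3"])
    return SlopeResult(
        month=int(months[0]),
        group=str(groups[0]),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        se=float(res.stderr),
        n=len(bottles),
    )


def cross_group_slope_regression(
    lna_slopes: list[SlopeResult], hna_slopes: list[SlopeResult]
) -> dict[str, float]:
    """OLS of monthly HNA size-vs-temperature slopes on LNA slopes.

    Tests whether the two groups' thermal size responses covary across
    the year; months are matched, unmatched months dropped.
    """
    lna = {s.month: s.slope for s in lna_slopes}
    hna = {s.month: s.slope for s in hna_slopes}
    months = sorted(set(lna) & set(hna))
    if len(months) < 3:
        raise ValueError(f"need >= 3 matched months, got {len(months)}")
    x = np.array([lna[m] for m in months])
    y = np.array([hna[m] for m in months])
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "se": float(res.stderr),
        "n": len(months),
    }


def window_mean_series(
    series: MonthlySeries, window_months: list[int]
) -> pd.DataFrame:
    """Annual means over a calendar-month window, per April-March year.

    Returns a frame with columns year (the year containing the April),
    mean, se and n; years with no observed window month are omitted.
    """
    if not window_months:
        raise ValueError("window must be non-empty")
    if not set(window_months) <= set(range(1, 13)):
        raise ValueError("window months must be in 1..12")
    if series.n_months < 24:
        raise ValueError("series must span at least 2 years")
    months = series.calendar_months()
    years = series.calendar_years()
    analysis_year = np.where(months >= ANALYSIS_YEAR_START_MONTH, years, years - 1)
    in_window = np.isin(months, window_months) & series.observed
    rows = []
    for yr in np.unique(analysis_year):
        sel = (analysis_year == yr) & in_window
        n = int(sel.sum())
        if n == 0:
            continue
        vals = series.values[sel]
        rows.append(
            {
                "year": int(yr),
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def annual_trend(annual: pd.DataFrame, window_months: list[int]) -> WindowTrend:
    """OLS of the annual window means against year."""
    if len(annual) < 5:
        raise ValueError(f"need >= 5 annual means, got {len(annual)}")
    if annual["mean"].std() == 0.0 and annual["year"].std() == 0.0:
        raise ValueError("degenerate annual means")
    res = stats.linregress(annual["year"], annual["mean"])
    return WindowTrend(
        window_months=tuple(window_months),
        annual=annual,
        slope_per_year=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n_years=len(annual),
    )


def projected_size_change(
    slopes_um3_per_degC: dict[str, float],
    warming_degC: float,
    baseline_sizes_um3: dict[str, float],
    group_weights: dict[str, float] | None = None,
) -> float:
    """Community-level percentage cell-size change under a warming scenario.

    100 * sum_g w_g * (slope_g * warming) / baseline_g; weights default to
    equal and must sum to 1.  A useful aggregation when per-group thermal
    responses and baseline sizes differ.
    """
    groups = sorted(slopes_um3_per_degC)
    if group_weights is None:
        group_weights = {g: 1.0 / len(groups) for g in groups}
    if abs(sum(group_weights[g] for g in groups) - 1.0) > 1e-9:
        raise ValueError("group weights must sum to 1")
    total = 0.0
    for g in groups:
        base = baseline_sizes_um3[g]
        if base <= 0:
            raise ValueError(f"baseline size for {g} must be positive")
        total += group_weights[g] * (slopes_um3_per_degC[g] * warming_degC) / base
    return 100.0 * total
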