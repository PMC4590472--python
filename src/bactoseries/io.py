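"""Plain-text readers and writers: CSV tables with ISO-8601 dates.

Event tables carry their acquisition metadata as ``# key: value`` header
comment lines so a single file round-trips events plus flow-rate/duration.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cytometry import EventTable
from .decomposition import DecompositionResult
from .hydrography import Profile
from .series import MonthlySeries

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_events_csv",
    "read_events_csv",
    "write_casts_csv",
    "read_casts_csv",
    "ledger_frame",
]


def write_series_csv(series_list: list[MonthlySeries], path: str | Path) -> None:
    """Long-format monthly table: date, variable, value."""
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, date_format="%Y-%m-%d")


def read_series_csv(path: str | Path) -> dict[str, MonthlySeries]:
    """Rebuild MonthlySeries per variable; the month axis is derived from
    the dates, never stored in the file."""
    df = pd.read_csv(path, parse_dates=["date"])
    out: dict[str, MonthlySeries] = {}
    for name, g in df.groupby("variable", sort=False):
        g = g.sort_values("date")
        periods = g["date"].dt.to_period("M")
        start = periods.iloc[0]
        idx = (periods - start).apply(lambda off: off.n).to_numpy()
        values = np.full(int(idx.max()) + 1, np.nan)
        values[idx] = g["value"].to_numpy()
        out[str(name)] = MonthlySeries(
            values=values, name=str(name), start=(start.year, start.month)
        )
    return out


def write_events_csv(events: EventTable, path: str | Path) -> None:
    header = (
        f"# flow_rate_ul_min: {events.flow_rate_ul_min}\n"
        f"# acquisition_time_s: {events.acquisition_time_s}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        events.data.to_csv(fh, index=False)


def read_events_csv(path: str | Path) -> EventTable:
    meta: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = float(value)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = pd.read_csv(fh)
    return EventTable(
        data=data,
        flow_rate_ul_min=meta["flow_rate_ul_min"],
        acquisition_time_s=meta["acquisition_time_s"],
    )


def write_casts_csv(casts: dict[str, Profile], path: str | Path) -> None:
    """Cast table: date, depth_m, temp_C, density_kg_m3, extra columns."""
    rows = []
    for date, prof in casts.items():
        frame = pd.DataFrame(
            {
                "date": date,
                "depth_m": prof.depth_m,
                "temp_C": prof.temperature_C,
                "density_kg_m3": prof.density_kg_m3,
            }
        )
        for name, arr in prof.extras.items():
            frame[name] = arr
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_casts_csv(path: str | Path) -> dict[str, Profile]:
    df = pd.read_csv(path)
    base = {"date", "depth_m", "temp_C", "density_kg_m3"}
    extras = [c for c in df.columns if c not in base]
    out: dict[str, Profile] = {}
    for date, g in df.groupby("date", sort=True):
        g = g.sort_values("depth_m")
        out[str(date)] = Profile(
            depth_m=g["depth_m"].to_numpy(),
            temperature_C=g["temp_C"].to_numpy(),
            density_kg_m3=g["density_kg_m3"].to_numpy(),
            extras={name: g[name].to_numpy() for name in extras},
        )
    return out


def ledger_frame(fits: dict[str, DecompositionResult]) -> pd.DataFrame:
    """Variance-decomposition ledger, one row per variable per retained
    harmonic (trend/AR columns only on the first row of a variable).

    Columns follow the standard decadal-ledger layout: mean, b (per month
    and per year), a, %var_trend, T, A, theta, T_max, %var_periodic, lag,
    phi, %var_ar, %var_total.
    """
    rows = []
    for name, fit in fits.items():
        harmonics = fit.harmonics if fit.harmonics else [None]
        for i, h in enumerate(harmonics):
            row: dict[str, object] = {"variable": name}
            if i == 0:
                row["mean"] = fit.climatological_mean
                if fit.trend is not None:
                    row["b_per_month"] = fit.trend.slope_per_month
                    row["b_per_year"] = fit.trend.slope_per_year
                    row["a"] = fit.trend.intercept
                    row["pct_var_trend"] = fit.trend.pct_variance
                if fit.ar is not None:
                    row["lag"] = fit.ar.lag
                    row["phi"] = fit.ar.phi
                    row["pct_var_ar"] = fit.ar.pct_variance
                row["pct_var_total"] = fit.total_pct_variance
            if h is not None:
                row["T"] = h.period
                row["A"] = h.amplitude
                row["theta"] = h.phase
                row["T_max"] = h.t_max
                row["pct_var_periodic"] = h.pct_variance
            rows.append(row)
    cols = [
        "variable", "mean", "b_per_month", "b_per_year", "a", "pct_var_trend",
        "T", "A", "theta", "T_max", "pct_var_periodic",
        "lag", "phi", "pct_var_ar", "pct_var_total",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)
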