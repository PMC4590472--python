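"""End-to-end orchestration: simulate -> stocks -> hydro -> decompose ->
residuals -> experiments, with a run log naming the seed and config hash.

Every stage is wrapped so that a failure aborts the run with the stage
named; outputs are plain CSV/JSON and byte-identical under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .config import PipelineConfig
from .cytometry import SizeCalibration, gate_lna_hna, population_stats
from .decomposition import decompose
from .experiments import (
    annual_trend,
    cross_group_slope_regression,
    size_temperature_slope,
    window_mean_series,
)
from .hydrography import summarize_cast
from .residuals import correlation_matrix, format_matrix, prewhiten
from .series import MonthlySeries
from .synthetic import (
    CytogramSpec,
    ExperimentSpec,
    ancillary_scenario,
    generate_cytogram,
    generate_experiment,
    generate_profile,
    generate_series,
    decadal_scenario,
)

__all__ = ["PipelineStageError", "simulate_inputs", "run_pipeline"]

BACTERIAL_VARIABLES = [
    "total_abundance", "lna_abundance", "hna_abundance",
    "total_size", "lna_size", "hna_size",
    "total_biomass", "lna_biomass", "pct_lna_biomass",
]
ENVIRONMENTAL_VARIABLES = ["temperature", "stratification_index", "nitrate", "chlorophyll"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineStageError(name, exc) from exc

    return wrap


def simulate_inputs(
    config: PipelineConfig,
    input_dir: str | Path,
    n_months: int = 120,
    n_events_per_cytogram: int = 2000,
) -> dict[str, int]:
    """Write the full synthetic input bundle (series, casts, cytograms,
    experiment table) with ground truth set by the decadal scenario."""
    input_dir = Path(input_dir)
    input_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    specs = {**decadal_scenario(seed, n_months=n_months),
             **ancillary_scenario(seed + 1000, n_months=n_months)}
    series = [generate_series(s) for s in specs.values()]
    bio.write_series_csv(series, input_dir / "uml_series.csv")

    # monthly CTD casts with summer-shallow / winter-deep mixed layers
    temp = next(s for s in series if s.name == "temperature")
    months_cal = temp.calendar_months()
    casts = {}
    for t, date in enumerate(temp.dates()):
        m = months_cal[t]
        mld = 36.5 + 21.5 * math.cos(2.0 * math.pi * (m - 2) / 12.0)
        surface = float(temp.values[t]) if np.isfinite(temp.values[t]) else 15.7
        casts[str(date)] = generate_profile(
            mld_true=mld, surface_T=surface, deep_T=12.5,
            depths=np.arange(0.0, 111.0, 1.0),
        )
    bio.write_casts_csv(casts, input_dir / "casts.csv")

    # one cytogram per month of the final scenario year
    n_frac = int(0.54 * n_events_per_cytogram)
    for i in range(12):
        spec = CytogramSpec(
            n_lna=n_events_per_cytogram - n_frac,
            n_hna=n_frac,
            seed=seed + 2000 + i,
        )
        bio.write_events_csv(generate_cytogram(spec), input_dir / f"events_{i + 1:02d}.csv")

    # twelve monthly temperature-size incubations
    frames = []
    for i in range(12):
        in_situ = 15.7 + 3.89 * math.cos(2.0 * math.pi * (i + 1 - 8) / 12.0)
        frames.append(
            generate_experiment(
                ExperimentSpec(month=i + 1, in_situ_temp=in_situ, seed=seed + 3000 + i)
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(input_dir / "experiments.csv", index=False)
    return {"series": len(series), "casts": len(casts), "cytograms": 12, "experiments": 12}


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
    n_months: int = 120,
    n_events_per_cytogram: int = 2000,
) -> dict:
    """Run every stage and emit the report bundle under ``out_dir``.

    With ``input_dir`` unset, the synthetic scenario is generated under
    ``out_dir/inputs`` first.  Returns the run log (also written as JSON).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    if input_dir is None:
        input_dir = out_dir / "inputs"
        counts["simulate"] = _stage("synthetic_data")(
            simulate_inputs, config, input_dir, n_months, n_events_per_cytogram
        )
    input_dir = Path(input_dir)

    # --- cytometry_stocks ---------------------------------------------
    def stocks():
        cal = SizeCalibration(
            log_slope=config.calibration_log_slope,
            log_intercept=config.calibration_log_intercept,
        )
        rows = []
        for path in sorted(input_dir.glob("events_*.csv")):
            events = bio.read_events_csv(path)
            gating = gate_lna_hna(events, red_threshold=config.red_fl_threshold)
            for p in population_stats(events, gating.labels, cal):
                rows.append(
                    {
                        "sample": path.stem.replace("events_", ""),
                        "group": p.group,
                        "abundance_cells_ml": p.abundance_cells_ml,
                        "size_um3": p.mean_cell_size_um3,
                        "biomass_ugC_l": p.biomass_ugC_l,
                        "degenerate_gate": gating.degenerate,
                    }
                )
        frame = pd.DataFrame(rows)
        frame.to_csv(out_dir / "population_stats.csv", index=False)
        return len(frame)

    counts["stocks"] = _stage("cytometry_stocks")(stocks)

    # --- hydrography ---------------------------------------------------
    def hydro():
        casts = bio.read_casts_csv(input_dir / "casts.csv")
        rows = []
        for date, prof in casts.items():
            s = summarize_cast(
                prof,
                threshold=config.mld_threshold_kg_m3,
                span=config.mld_span_m,
                reference_depth=config.si_reference_depth_m,
            )
            rows.append(
                {
                    "date": date,
                    "mld_m": s.mld_m,
                    "stratification_index_C_m": s.stratification_index_C_m,
                    **{f"uml_{k}": v for k, v in s.uml_means.items()},
                }
            )
        frame = pd.DataFrame(rows).sort_values("date")
        frame.to_csv(out_dir / "uml_summary.csv", index=False)
        return len(frame)

    counts["hydro"] = _stage("hydrography")(hydro)

    # --- decomposition -------------------------------------------------
    def decomposition_stage():
        series = bio.read_series_csv(input_dir / "uml_series.csv")
        fits = {
            name: decompose(
                s,
                alpha=config.alpha,
                max_harmonics=config.max_harmonics,
                ar_max_lag=config.ar_max_lag,
            )
            for name, s in series.items()
        }
        bio.ledger_frame(fits).to_csv(out_dir / "variance_ledger.csv", index=False)
        return series, fits

    series, fits = _stage("decomposition")(decomposition_stage)
    counts["decompose"] = len(fits)

    # --- residuals -----------------------------------------------------
    def residual_stage():
        resid = {name: prewhiten(series[name], fits[name]) for name in fits}
        rows = [v for v in ENVIRONMENTAL_VARIABLES if v in resid]
        cols = [v for v in BACTERIAL_VARIABLES if v in resid]
        matrix = correlation_matrix(resid, rows, cols)
        long = []
        for rv in rows:
            for cv in cols:
                rec = matrix.loc[rv, cv]
                long.append(
                    {"environmental": rv, "bacterial": cv,
                     "r": rec.r, "p": rec.p, "n": rec.n, "stars": rec.stars}
                )
        pd.DataFrame(long).to_csv(out_dir / "residual_correlations.csv", index=False)
        format_matrix(matrix).to_csv(out_dir / "residual_matrix.csv")
        return len(long)

    counts["residuals"] = _stage("residuals")(residual_stage)

    # --- experiments ---------------------------------------------------
    def experiment_stage():
        table = pd.read_csv(input_dir / "experiments.csv")
        slopes = []
        for (month, group), g in table.groupby(["month", "group"], sort=True):
            slopes.append(size_temperature_slope(g, summary=config.bottle_summary))
        slope_frame = pd.DataFrame([asdict(s) for s in slopes])
        slope_frame.to_csv(out_dir / "experiment_slopes.csv", index=False)
        lna = [s for s in slopes if s.group == "LNA"]
        hna = [s for s in slopes if s.group == "HNA"]
        cross = cross_group_slope_regression(lna, hna)

        temp = series["temperature"]
        annual = window_mean_series(temp, config.window_months)
        trend = annual_trend(annual, config.window_months)
        report = {
            "cross_group_regression": cross,
            "window_trend_temperature": {
                "window_months": list(trend.window_months),
                "slope_per_year": trend.slope_per_year,
                "r_squared": trend.r_squared,
                "p_value": trend.p_value,
                "n_years": trend.n_years,
            },
        }
        (out_dir / "experiment_report.json").write_text(json.dumps(report, indent=2))
        annual.to_csv(out_dir / "window_means_temperature.csv", index=False)
        return len(slopes)

    counts["experiments"] = _stage("experiments")(experiment_stage)

    run_log = {"seed": config.seed, "config_hash": config.hash(), "stage_counts": counts}
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return run_log
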