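"""Temperature-size regressions and seasonal-window trend statistics."""

import numpy as np
import pandas as pd
import pytest

from bactoseries import (
    MonthlySeries,
    SeriesSpec,
    SlopeResult,
    add_window_trend,
    annual_trend,
    cross_group_slope_regression,
    generate_series,
    projected_size_change,
    size_temperature_slope,
    window_mean_series,
)


def experiment_frame(slope, intercept=0.06, temps=(12.0, 15.0, 18.0), reps=3):
    rows = []
    for T in temps:
        for rep in range(1, reps + 1):
            rows.append(
                {
                    "month": 5, "group": "LNA", "temp_C": T, "replicate": rep,
                    "timepoint_h": 0.0, "size_um3": intercept + slope * T,
                }
            )
    return pd.DataFrame(rows)


class TestSizeTemperatureSlope:
    def test_noiseless_slope_exact(self):
        res = size_temperature_slope(experiment_frame(-0.0005))
        assert res.slope == pytest.approx(-0.0005, abs=1e-15)
        assert res.r_squared == pytest.approx(1.0)

    def test_flat_response_gives_zero_slope(self):
        res = size_temperature_slope(experiment_frame(0.0))
        assert res.slope == pytest.approx(0.0, abs=1e-15)

    def test_single_temperature_level_rejected(self):
        frame = experiment_frame(-0.0005, temps=(15.0,))
        with pytest.raises(ValueError):
            size_temperature_slope(frame)

    def test_shift_invariance_and_scaling(self):
        base = size_temperature_slope(experiment_frame(-0.0005))
        shifted = experiment_frame(-0.0005)
        shifted["size_um3"] += 0.01
        assert size_temperature_slope(shifted).slope == pytest.approx(base.slope)
        scaled = experiment_frame(-0.0005)
        scaled["size_um3"] *= 3.0
        assert size_temperature_slope(scaled).slope == pytest.approx(3 * base.slope)

    def test_mixed_groups_rejected(self):
        frame = experiment_frame(-0.0005)
        frame.loc[0, "group"] = "HNA"
        with pytest.raises(ValueError):
            size_temperature_slope(frame)


class TestCrossGroupRegression:
    @staticmethod
    def slopes(values):
        return [
            SlopeResult(month=m + 1, group="x", slope=v, intercept=0.06,
                        r_squared=1.0, p_value=0.01, se=1e-5, n=9)
            for m, v in enumerate(values)
        ]

    def test_identical_slope_sets(self):
        vals = np.linspace(-0.001, 0.0, 12)
        res = cross_group_slope_regression(self.slopes(vals), self.slopes(vals))
        assert res["slope"] == pytest.approx(1.0)
        assert res["r_squared"] == pytest.approx(1.0)

    def test_known_scaling_recovered(self):
        rng = np.random.default_rng(0)
        lna = rng.normal(-0.0004, 0.0006, 12)
        hna = -0.0002 + 1.19 * lna + rng.normal(0, 0.0005, 12)
        res = cross_group_slope_regression(self.slopes(lna), self.slopes(hna))
        assert abs(res["slope"] - 1.19) <= 2 * res["se"]

    def test_uncorrelated_sets_have_low_r2(self):
        rng = np.random.default_rng(1)
        res = cross_group_slope_regression(
            self.slopes(rng.normal(0, 1e-3, 12)), self.slopes(rng.normal(0, 1e-3, 12))
        )
        assert res["r_squared"] < 0.3

    def test_insufficient_matched_months_rejected(self):
        with pytest.raises(ValueError):
            cross_group_slope_regression(self.slopes([1e-4]), self.slopes([1e-4]))


class TestWindowMeans:
    def test_constant_series_gives_constant_annual_means(self):
        s = MonthlySeries(np.full(120, 7.0), start=(2002, 4))
        annual = window_mean_series(s, [4, 5, 6, 7])
        assert (annual["mean"] == 7.0).all()
        assert len(annual) == 10

    def test_single_month_window_returns_that_value(self):
        values = np.arange(120.0)
        s = MonthlySeries(values, start=(2002, 4))
        annual = window_mean_series(s, [6])  # June = t 2, 14, 26, ...
        assert annual["mean"].tolist() == list(values[2::12])
        assert annual["n"].eq(1).all()

    def test_analysis_year_runs_april_to_march(self):
        # a January sample belongs to the PREVIOUS analysis year
        s = MonthlySeries(np.arange(24.0), start=(2002, 4))
        annual = window_mean_series(s, [1])
        assert annual.loc[0, "year"] == 2002  # Jan 2003 -> analysis year 2002

    def test_linear_series_trend_recovered_exactly(self):
        slope_month = 0.02
        s = MonthlySeries(slope_month * np.arange(120.0), start=(2002, 4))
        annual = window_mean_series(s, list(range(1, 13)))
        trend = annual_trend(annual, list(range(1, 13)))
        assert trend.slope_per_year == pytest.approx(12 * slope_month)
        assert trend.r_squared == pytest.approx(1.0)

    def test_window_confined_warming_detected(self):
        # +0.15 degC/yr in April-July over a decade -> ~1.5 degC total
        spec = SeriesSpec(
            n_months=120, mean=15.7, harmonics=((12.0, 3.89, 4.26),),
            noise_sd=0.5, seed=12,
        )
        s = add_window_trend(generate_series(spec), [4, 5, 6, 7], 0.15)
        annual = window_mean_series(s, [4, 5, 6, 7])
        trend = annual_trend(annual, [4, 5, 6, 7])
        warming_decade = trend.slope_per_year * 10
        assert warming_decade == pytest.approx(1.5, abs=0.5)
        assert trend.p_value < 0.05

    def test_null_trend_type_one_error(self):
        rejections = 0
        n_sims = 500
        rng = np.random.default_rng(7)
        for _ in range(n_sims):
            annual = pd.DataFrame(
                {"year": np.arange(2002, 2012), "mean": rng.normal(size=10), "n": 4}
            )
            trend = annual_trend(annual, [4])
            rejections += trend.p_value < 0.05
        assert 0.03 <= rejections / n_sims <= 0.07


class TestProjectedSizeChange:
    def test_zero_warming_is_zero_change(self):
        assert projected_size_change({"LNA": -0.0005}, 0.0, {"LNA": 0.05}) == 0.0

    def test_single_group_arithmetic(self):
        pct = projected_size_change({"LNA": -0.0005}, 2.0, {"LNA": 0.05})
        assert pct == pytest.approx(-2.0)

    def test_two_group_weightings(self):
        slopes = {"LNA": -0.00041, "HNA": -0.00091}
        baselines = {"LNA": 0.050, "HNA": 0.056}
        equal = projected_size_change(slopes, 1.5, baselines)
        weighted = projected_size_change(
            slopes, 1.5, baselines, group_weights={"LNA": 0.46, "HNA": 0.54}
        )
        assert equal < 0 and weighted < 0
        per_lna = 100 * (-0.00041 * 1.5) / 0.050
        per_hna = 100 * (-0.00091 * 1.5) / 0.056
        assert equal == pytest.approx(0.5 * (per_lna + per_hna))
        assert weighted == pytest.approx(0.46 * per_lna + 0.54 * per_hna)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            projected_size_change({"LNA": -0.0005}, 1.0, {"LNA": 0.0})
        with pytest.raises(ValueError):
            projected_size_change(
                {"LNA": -0.0005}, 1.0, {"LNA": 0.05}, group_weights={"LNA": 0.7}
            )
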