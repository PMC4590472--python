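"""Additive decomposition of monthly environmental/bacterial series.

The model is

    x_t = mean + b*t + sum_i A_i * cos(2*pi*t/T_i - theta_i) + eta_t
    eta_t = phi * eta_{t-lag} + eps_t

fitted stage-wise: climatological mean, then the linear trend (retained
only if its slope is significant), then periodic components found
iteratively with the Fisher G-test on the periodogram of the current
residual, and finally a single autoregressive coefficient at the first
lag whose partial autocorrelation leaves the +/-1.96/sqrt(n) band.

Each retained component carries the percentage of the ORIGINAL series
variance it explains, so the resulting ledger reads like the variance
decomposition tables of long-term monitoring studies: %var of the trend
is Var(b*t) / Var(x), %var of a harmonic is (A^2/2) / Var(x), and %var
of the AR term is the drop in residual variance it achieves, again
relative to Var(x).  The total is the exact sum of the parts.

Phase convention: A*cos(2*pi*t/T - theta) with theta in [0, 2*pi), so the
component peaks at t_max = theta*T/(2*pi) months after the series start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .series import MonthlySeries

__all__ = [
    "TrendComponent",
    "HarmonicComponent",
    "ArComponent",
    "DecompositionResult",
    "fit_trend",
    "periodogram",
    "fisher_g_test",
    "fit_harmonics",
    "t_max",
    "fit_ar",
    "decompose",
]

# residual variance below this fraction of the original variance is treated
# as numerically exhausted (stops the harmonic search on noiseless input)
_VAR_FLOOR = 1e-14


@dataclass
class TrendComponent:
    """Linear trend on the internal month axis (t = 0 at first sample)."""

    slope_per_month: float
    intercept: float  # value of the fitted line at t = 0, original scale
    pct_variance: float
    p_value: float

    @property
    def slope_per_year(self) -> float:
        return 12.0 * self.slope_per_month

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope_per_month * np.asarray(t, dtype=float)


@dataclass
class HarmonicComponent:
    period: float  # months
    amplitude: float  # series units, >= 0
    phase: float  # radians in [0, 2*pi)
    pct_variance: float

    @property
    def t_max(self) -> float:
        """Month (from series start) at which the component peaks."""
        return t_max(self.phase, self.period)

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.cos(2.0 * np.pi * t / self.period - self.phase)


@dataclass
class ArComponent:
    lag: int  # months
    phi: float
    pct_variance: float


@dataclass
class DecompositionResult:
    """Fitted additive model and its variance ledger."""

    series: MonthlySeries
    climatological_mean: float
    trend: TrendComponent | None
    harmonics: list[HarmonicComponent]
    ar: ArComponent | None
    residuals: np.ndarray  # pre-whitened residuals eps_t; NaN where undefined

    @property
    def total_pct_variance(self) -> float:
        total = 0.0
        if self.trend is not None:
            total += self.trend.pct_variance
        total += sum(h.pct_variance for h in self.harmonics)
        if self.ar is not None:
            total += self.ar.pct_variance
        return total

    def deterministic_part(self, t: np.ndarray | None = None) -> np.ndarray:
        """mean + trend + harmonics evaluated on the month axis."""
        if t is None:
            t = self.series.t
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.climatological_mean, dtype=float)
        if self.trend is not None:
            # trend intercept is on the original scale; it replaces the mean
            out = self.trend.predict(t)
        for h in self.harmonics:
            out = out + h.predict(t)
        return out

    def variance_ledger(self) -> dict[str, float]:
        ledger: dict[str, float] = {}
        if self.trend is not None:
            ledger["trend"] = self.trend.pct_variance
        for i, h in enumerate(self.harmonics):
            ledger[f"periodic_T{h.period:g}" if i == 0 else f"periodic_{i}_T{h.period:g}"] = (
                h.pct_variance
            )
        if self.ar is not None:
            ledger["ar"] = self.ar.pct_variance
        ledger["total"] = self.total_pct_variance
        return ledger


def _observed(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    t = np.arange(values.size, dtype=float)
    return t[mask], values[mask]


def fit_trend(series: MonthlySeries, alpha: float = 0.05) -> TrendComponent | None:
    """OLS linear trend on observed (t, x) pairs; None if not significant.

    The explained share is Var(b*t over observed t) / Var(x), the share of
    series variance the fitted line carries.
    """
    t_obs, x_obs = _observed(series.values)
    if x_obs.size == 0:
        raise ValueError("cannot fit a trend to an all-missing series")
    if x_obs.size < 24:
        raise ValueError(f"need >= 24 non-missing months, got {x_obs.size}")
    var_x = float(np.var(x_obs))
    if var_x == 0.0:
        return None
    res = stats.linregress(t_obs, x_obs)
    if not np.isfinite(res.pvalue) or res.pvalue >= alpha:
        return None
    fitted = res.intercept + res.slope * t_obs
    pct = 100.0 * float(np.var(fitted)) / var_x
    return TrendComponent(
        slope_per_month=float(res.slope),
        intercept=float(res.intercept),
        pct_variance=pct,
        p_value=float(res.pvalue),
    )


def periodogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Periodogram ordinates at the Fourier frequencies j/n, j = 1..(n-1)//2.

    Gap-free series use the classical FFT periodogram
    I(f_j) = |sum_t x_t exp(-2*pi*i*f_j*t)|^2 / n, for which Parseval gives
    (2/n) * sum_j I(f_j) = Var(x) up to the Nyquist term.  Series with gaps
    use the Lomb-Scargle generalization at the same frequencies.  Only the
    ordinate ratios enter the Fisher G-test, so the two normalizations are
    interchangeable downstream.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 8:
        raise ValueError(f"need at least 8 months for a periodogram, got {n}")
    m = (n - 1) // 2
    freqs = np.arange(1, m + 1) / n
    mask = np.isfinite(values)
    if mask.all():
        x = values - values.mean()
        X = np.fft.rfft(x)
        ords = np.abs(X[1 : m + 1]) ** 2 / n
    else:
        t_obs = np.arange(n, dtype=float)[mask]
        x = values[mask]
        if x.size < 8:
            raise ValueError("need at least 8 observed months for a periodogram")
        x = x - x.mean()
        ords = signal.lombscargle(t_obs, x, 2.0 * np.pi * freqs)
    return freqs, ords


def fisher_g_test(ordinates: np.ndarray) -> tuple[float, float]:
    """Fisher's exact test for a hidden periodicity.

    g = max_j I_j / sum_j I_j; under the white-noise null the ordinates are
    iid exponential and

        P(G > g) = sum_{j=1}^{floor(1/g)} (-1)^(j-1) C(m, j) (1 - j*g)^(m-1)

    for m ordinates.  Raises on zero-variance input.
    """
    I = np.asarray(ordinates, dtype=float)
    if I.size < 4:
        raise ValueError(f"need >= 4 periodogram ordinates, got {I.size}")
    if np.any(I < 0) or not np.all(np.isfinite(I)):
        raise ValueError("periodogram ordinates must be finite and non-negative")
    total = I.sum()
    if total <= 0.0:
        raise ValueError("zero-variance input: Fisher G-test undefined")
    m = I.size
    g = float(I.max() / total)
    p = _fisher_g_pvalue(g, m)
    return g, p


def _fisher_g_pvalue(g: float, m: int) -> float:
    kmax = min(m, int(math.floor(1.0 / g))) if g > 0 else m
    p = 0.0
    for j in range(1, kmax + 1):
        base = 1.0 - j * g
        if base < 0.0:  # guard floor(1/g) rounding at the boundary
            break
        term = math.comb(m, j) * base ** (m - 1)
        p += term if j % 2 == 1 else -term
    return float(min(max(p, 0.0), 1.0))


def _harmonic_lstsq(
    t: np.ndarray, x: np.ndarray, period: float
) -> tuple[float, float, float]:
    """Least-squares fit of A*cos(2*pi*t/T - theta); returns (A, theta, sse)."""
    w = 2.0 * np.pi / period
    design = np.column_stack([np.cos(w * t), np.sin(w * t)])
    coef, _, _, _ = np.linalg.lstsq(design, x, rcond=None)
    c1, c2 = float(coef[0]), float(coef[1])
    resid = x - design @ coef
    amplitude = math.hypot(c1, c2)
    theta = math.atan2(c2, c1) % (2.0 * math.pi)
    return amplitude, theta, float(resid @ resid)


def _refine_period(
    t: np.ndarray,
    x: np.ndarray,
    period0: float,
    window: float = 0.5,
    refine_alpha: float = 0.01,
) -> float:
    """Refine a Fourier-grid period by local least squares.

    The refined period replaces the grid period only when an F-test says
    the sum of squares drops significantly (one extra effective parameter);
    otherwise the grid value is kept, so exactly-periodic designs report
    the grid period unchanged.
    """
    nobs = t.size
    if nobs < 8:
        return period0
    lo = max(2.0, period0 - window)
    hi = min(nobs / 2.0 if nobs >= 8 else period0 + window, period0 + window)
    if hi <= lo:
        return period0
    _, _, sse0 = _harmonic_lstsq(t, x, period0)

    def objective(T: float) -> float:
        return _harmonic_lstsq(t, x, T)[2]

    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    sse1 = float(res.fun)
    if not np.isfinite(sse1) or sse1 >= sse0 or sse1 <= 0.0:
        return period0
    df_resid = nobs - 3
    if df_resid <= 0:
        return period0
    f_stat = (sse0 - sse1) / (sse1 / df_resid)
    p_f = float(stats.f.sf(f_stat, 1, df_resid))
    return float(res.x) if p_f < refine_alpha else period0


def fit_harmonics(
    series: MonthlySeries,
    alpha: float = 0.05,
    max_harmonics: int = 4,
    var_reference: float | None = None,
    refine: bool = True,
) -> list[HarmonicComponent]:
    """Iterative significant-periodicity extraction from a detrended series.

    On each pass, the Fisher G-test is applied to the periodogram of the
    current residual; while significant at ``alpha``, the winning period
    (lowest frequency on ties, optionally refined off-grid) is fitted by
    least squares as A*cos(2*pi*t/T - theta) and subtracted.  Each retained
    component's %variance is (A^2/2) / var_reference, where the reference
    defaults to the variance of the series handed in (pass the original
    series variance when the input is already detrended).

    The G-test's null distribution assumes white noise, and the residuals
    of monthly environmental series are typically red (lag-1 AR): the
    inflated low-frequency ordinates then produce spurious long-period
    "cycles".  Detection is therefore run on a lag-1 prewhitened copy of
    the residual whenever its lag-1 autocorrelation leaves the white-noise
    band; the harmonic itself is always fitted on the unwhitened residual,
    so amplitudes and phases keep their original units.  Returned
    components are sorted by decreasing amplitude.
    """
    values = np.asarray(series.values, dtype=float)
    n = values.size
    t_obs, x_obs = _observed(values)
    if x_obs.size == 0:
        raise ValueError("all-missing series")
    var_orig = float(np.var(x_obs)) if var_reference is None else float(var_reference)
    if var_orig <= 0.0:
        return []
    resid = values - np.nanmean(values)
    components: list[HarmonicComponent] = []
    for _ in range(max_harmonics):
        r_obs = resid[np.isfinite(resid)]
        if float(np.var(r_obs)) <= _VAR_FLOOR * var_orig:
            break
        detection = _whiten_for_detection(resid)
        freqs, ords = periodogram(detection)
        _, p = fisher_g_test(ords)
        if p >= alpha:
            break
        j_win = int(np.argmax(ords))  # argmax returns the lowest frequency on ties
        period = 1.0 / freqs[j_win]
        tr, rr = _observed(resid)
        if refine:
            period = _refine_period(tr, rr, period)
        amplitude, theta, _ = _harmonic_lstsq(tr, rr, period)
        comp = HarmonicComponent(
            period=float(period),
            amplitude=amplitude,
            phase=theta,
            pct_variance=100.0 * (amplitude**2 / 2.0) / var_orig,
        )
        components.append(comp)
        resid = resid - comp.predict(np.arange(n))
    components.sort(key=lambda c: c.amplitude, reverse=True)
    return components


def _whiten_for_detection(resid: np.ndarray) -> np.ndarray:
    """Lag-1 AR-adjusted copy of the residual for periodicity DETECTION.

    Applied only when the lag-1 autocorrelation is outside the
    +/-1.96/sqrt(n) band, so exactly white residuals are tested as-is and
    the exact null calibration of the G-test is preserved.
    """
    obs = resid[np.isfinite(resid)]
    if obs.size < 10 or float(np.var(obs)) == 0.0:
        return resid
    r1 = _pairwise_acf(resid, 1)[1]
    if abs(r1) <= 1.96 / math.sqrt(obs.size):
        return resid
    a, b = resid[:-1], resid[1:]
    ok = np.isfinite(a) & np.isfinite(b)
    xx = float(np.dot(a[ok], a[ok]))
    if xx == 0.0:
        return resid
    phi1 = float(np.dot(a[ok], b[ok]) / xx)
    if not -1.0 < phi1 < 1.0:
        phi1 = max(-0.99, min(0.99, phi1))
    return ar_adjust(resid, 1, phi1)


def t_max(theta: float, period_T: float) -> float:
    """Month of the cycle maximum under the cos(2*pi*t/T - theta) convention."""
    if period_T <= 0:
        raise ValueError("period must be positive")
    return theta * period_T / (2.0 * math.pi)


def _pairwise_acf(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation at lags 0..max_lag from pairwise-complete pairs.

    Handles gapped series, where the standard FFT estimator is undefined;
    on gap-free input it agrees with the usual estimator up to end effects.
    """
    x = np.asarray(values, dtype=float)
    acf = np.ones(max_lag + 1)
    for k in range(1, max_lag + 1):
        a, b = x[:-k], x[k:]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            acf[k] = 0.0
            continue
        aa, bb = a[ok], b[ok]
        sa, sb = aa.std(), bb.std()
        acf[k] = 0.0 if sa == 0 or sb == 0 else float(np.corrcoef(aa, bb)[0, 1])
    return acf


def _pacf_from_acf(acf: np.ndarray) -> np.ndarray:
    """Durbin-Levinson partial autocorrelations from an ACF (lag 0 = 1)."""
    p = acf.size - 1
    pacf = np.zeros(p + 1)
    pacf[0] = 1.0
    phi = np.zeros((p + 1, p + 1))
    for k in range(1, p + 1):
        if k == 1:
            phi[1, 1] = acf[1]
        else:
            num = acf[k] - np.dot(phi[k - 1, 1:k], acf[k - 1 : 0 : -1])
            den = 1.0 - np.dot(phi[k - 1, 1:k], acf[1:k])
            phi[k, k] = 0.0 if den == 0 else num / den
            for j in range(1, k):
                phi[k, j] = phi[k - 1, j] - phi[k, k] * phi[k - 1, k - j]
        pacf[k] = phi[k, k]
    return pacf


def fit_ar(
    residuals: np.ndarray,
    var_reference: float | None = None,
    max_lag: int = 1,
) -> ArComponent | None:
    """Single-lag AR term on the detrended/deseasonalized residual.

    The lag is the smallest one whose partial autocorrelation leaves the
    +/-1.96/sqrt(n) white-noise band; phi is then the no-intercept OLS
    coefficient of eta_t on eta_{t-lag}.  Returns None when no lag is
    significant.  %variance is the drop in residual variance achieved by
    the AR adjustment, relative to ``var_reference`` (defaults to the
    residual variance itself).
    """
    eta = np.asarray(residuals, dtype=float)
    obs = eta[np.isfinite(eta)]
    n_obs = obs.size
    if n_obs < 10:
        raise ValueError(f"need >= 10 observed residuals, got {n_obs}")
    var_before = float(np.var(obs))
    if var_before == 0.0:
        return None
    var_ref = var_before if var_reference is None else float(var_reference)
    max_lag = min(max_lag, n_obs // 4)
    acf = _pairwise_acf(eta, max_lag)
    pacf = _pacf_from_acf(acf)
    band = 1.96 / math.sqrt(n_obs)
    lag = None
    for k in range(1, max_lag + 1):
        if abs(pacf[k]) > band:
            lag = k
            break
    if lag is None:
        return None
    a, b = eta[:-lag], eta[lag:]
    ok = np.isfinite(a) & np.isfinite(b)
    xx = float(np.dot(a[ok], a[ok]))
    if xx == 0.0:
        return None
    phi = float(np.dot(a[ok], b[ok]) / xx)
    eps = ar_adjust(eta, lag, phi)
    var_after = float(np.nanvar(eps[np.isfinite(eps)]))
    pct = 100.0 * (var_before - var_after) / var_ref if var_ref > 0 else 0.0
    return ArComponent(lag=lag, phi=phi, pct_variance=pct)


def ar_adjust(eta: np.ndarray, lag: int, phi: float) -> np.ndarray:
    """eps_t = eta_t - phi * eta_{t-lag}; NaN where either term is missing."""
    eta = np.asarray(eta, dtype=float)
    eps = np.full_like(eta, np.nan)
    eps[lag:] = eta[lag:] - phi * eta[:-lag]
    return eps


def _polish_deterministic(
    values: np.ndarray,
    t_all: np.ndarray,
    trend: TrendComponent | None,
    harmonics: list[HarmonicComponent],
    var_x: float,
) -> tuple[TrendComponent | None, list[HarmonicComponent], float]:
    """Joint OLS of intercept (+ slope) + cos/sin pairs at the periods the
    stage-wise search identified; returns updated components and base level."""
    t_obs, x_obs = _observed(values)
    cols = [np.ones_like(t_obs)]
    if trend is not None:
        cols.append(t_obs)
    for h in harmonics:
        w = 2.0 * np.pi / h.period
        cols.append(np.cos(w * t_obs))
        cols.append(np.sin(w * t_obs))
    design = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(design, x_obs, rcond=None)
    k = 0
    intercept = float(coef[k])
    k += 1
    new_trend = trend
    if trend is not None:
        slope = float(coef[k])
        k += 1
        fitted_line = intercept + slope * t_obs
        pct = 100.0 * float(np.var(fitted_line)) / var_x if var_x > 0 else 0.0
        new_trend = TrendComponent(
            slope_per_month=slope, intercept=intercept,
            pct_variance=pct, p_value=trend.p_value,
        )
    new_harmonics: list[HarmonicComponent] = []
    for h in harmonics:
        c1, c2 = float(coef[k]), float(coef[k + 1])
        k += 2
        amplitude = math.hypot(c1, c2)
        theta = math.atan2(c2, c1) % (2.0 * math.pi)
        new_harmonics.append(
            HarmonicComponent(
                period=h.period, amplitude=amplitude, phase=theta,
                pct_variance=(
                    100.0 * (amplitude**2 / 2.0) / var_x if var_x > 0 else 0.0
                ),
            )
        )
    new_harmonics.sort(key=lambda c: c.amplitude, reverse=True)
    return new_trend, new_harmonics, intercept


def decompose(
    series: MonthlySeries,
    alpha: float = 0.05,
    max_harmonics: int = 4,
    ar_max_lag: int = 1,
    refine_periods: bool = True,
) -> DecompositionResult:
    """Full stage-wise fit: mean -> trend -> harmonics -> AR.

    Only components significant at ``alpha`` are retained; the returned
    residuals are the pre-whitened eps_t used downstream for correlation
    analysis between variables.
    """
    values = np.asarray(series.values, dtype=float)
    t_all = series.t
    _, x_obs = _observed(values)
    if x_obs.size == 0:
        raise ValueError("all-missing series")
    if x_obs.size < 24:
        raise ValueError(f"need >= 24 non-missing months, got {x_obs.size}")
    var_x = float(np.var(x_obs))
    mean = float(np.mean(x_obs))

    trend = fit_trend(series, alpha=alpha) if var_x > 0 else None
    if trend is not None:
        anomaly = values - trend.predict(t_all)
    else:
        anomaly = values - mean

    harmonics = fit_harmonics(
        MonthlySeries(anomaly, name=series.name, start=series.start),
        alpha=alpha,
        max_harmonics=max_harmonics,
        var_reference=var_x if var_x > 0 else None,
        refine=refine_periods,
    )
    # joint re-fit of the deterministic structure at the identified periods:
    # t and the cosine basis are not exactly orthogonal on a finite span, so
    # stage-wise estimates carry a small leakage that a single OLS removes
    if harmonics or trend is not None:
        trend, harmonics, mean_level = _polish_deterministic(
            values, t_all, trend, harmonics, var_x
        )
        if trend is None:
            mean = mean_level  # fitted base level; = sample mean on full cycles
            deterministic = np.full(values.shape, mean_level)
        else:
            deterministic = trend.predict(t_all)
        for h in harmonics:
            deterministic = deterministic + h.predict(t_all)
        eta = values - deterministic
    else:
        eta = anomaly.copy()

    ar: ArComponent | None = None
    eta_obs = eta[np.isfinite(eta)]
    if eta_obs.size >= 10 and float(np.var(eta_obs)) > _VAR_FLOOR * max(var_x, 1.0):
        ar = fit_ar(eta, var_reference=var_x if var_x > 0 else None, max_lag=ar_max_lag)
    residuals = ar_adjust(eta, ar.lag, ar.phi) if ar is not None else eta

    return DecompositionResult(
        series=series,
        climatological_mean=mean,
        trend=trend,
        harmonics=harmonics,
        ar=ar,
        residuals=residuals,
    )
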