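"""Pre-whitened residual correlation between bacterial and environmental
series.

Raw monthly series share seasonality and decadal trends, so their direct
correlations are spurious.  Correlation analysis is therefore run on the
pre-whitened residuals: what is left of each series after the
climatological mean, linear trend, significant harmonics and the AR term
have been removed.  Pairing is strictly by month, pairwise-complete, with
the per-cell n reported; no multiple-testing correction is applied by
default (a Benjamini-Hochberg option is exposed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import DecompositionResult, ar_adjust
from .series import MonthlySeries

__all__ = [
    "CorrelationRecord",
    "prewhiten",
    "correlate_residuals",
    "correlation_matrix",
    "format_matrix",
]

MIN_PAIRED_MONTHS = 10


@dataclass
class CorrelationRecord:
    r: float
    p: float
    n: int
    stars: str  # "***", "**", "*", "ns" or "undef"


def significance_band(p: float) -> str:
    """Star band from the two-tailed p-value (0.001 / 0.01 / 0.05)."""
    if not np.isfinite(p):
        return "undef"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def prewhiten(series: MonthlySeries, fit: DecompositionResult) -> np.ndarray:
    """Residuals eps_t = x_t - mean - trend - harmonics - AR prediction.

    ``fit`` must come from the very series handed in; a mismatch raises.
    """
    if fit.series.n_months != series.n_months:
        raise ValueError("fit and series month axes differ")
    same = np.isfinite(series.values) == np.isfinite(fit.series.values)
    if not (
        same.all()
        and np.allclose(
            series.values[np.isfinite(series.values)],
            fit.series.values[np.isfinite(fit.series.values)],
        )
    ):
        raise ValueError("fit was produced from a different series")
    eta = series.values - fit.deterministic_part()
    if fit.ar is not None:
        return ar_adjust(eta, fit.ar.lag, fit.ar.phi)
    return eta


def correlate_residuals(a: np.ndarray, b: np.ndarray) -> CorrelationRecord:
    """Pearson r on month-matched residual pairs, two-tailed p via the
    t transform with n - 2 degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("residual series must share their month axis")
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < MIN_PAIRED_MONTHS:
        raise ValueError(f"need >= {MIN_PAIRED_MONTHS} common months, got {n}")
    aa, bb = a[ok], b[ok]
    if aa.std() == 0.0 or bb.std() == 0.0:
        return CorrelationRecord(r=float("nan"), p=float("nan"), n=n, stars="undef")
    r = float(np.corrcoef(aa, bb)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationRecord(r=r, p=p, n=n, stars=significance_band(p))


def correlation_matrix(
    residuals: dict[str, np.ndarray],
    row_variables: list[str],
    col_variables: list[str],
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Matrix of CorrelationRecords, rows = environmental variables,
    columns = bacterial properties.

    With ``bh_correct`` the p-values (and hence the star bands) are
    Benjamini-Hochberg adjusted across all cells; off by default.
    """
    records: dict[tuple[str, str], CorrelationRecord] = {}
    for rv in row_variables:
        for cv in col_variables:
            records[(rv, cv)] = correlate_residuals(residuals[rv], residuals[cv])
    if bh_correct:
        keys = [k for k in records if np.isfinite(records[k].p)]
        ps = np.array([records[k].p for k in keys])
        order = np.argsort(ps)
        m = ps.size
        adj = np.empty(m)
        running_min = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running_min = min(running_min, ps[i] * m / (rank_pos + 1))
            adj[i] = running_min
        for k, p_adj in zip(keys, adj):
            rec = records[k]
            records[k] = CorrelationRecord(
                r=rec.r, p=float(p_adj), n=rec.n, stars=significance_band(float(p_adj))
            )
    return pd.DataFrame(
        {cv: {rv: records[(rv, cv)] for rv in row_variables} for cv in col_variables}
    )


def format_matrix(matrix: pd.DataFrame, show_all: bool = False) -> pd.DataFrame:
    """Human-readable matrix: "r(stars)" for significant cells, an em-dash
    for non-significant ones (``show_all`` reports every cell)."""

    def fmt(rec: CorrelationRecord) -> str:
        if rec.stars == "undef":
            return "undef"
        if rec.stars == "ns" and not show_all:
            return "—"
        star = "" if rec.stars == "ns" else rec.stars
        return f"{rec.r:.2f}{star}"

    return matrix.map(fmt)
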