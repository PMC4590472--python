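"""Regularly sampled monthly series with gaps.

The monitoring design is one cast per calendar month; the internal time
axis is the integer month index t = 0, 1, 2, ... from the first sample.
Missing months are NaN, never dropped or interpolated, so that t keeps
its calendar meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MonthlySeries:
    """One variable sampled at regular monthly steps.

    Parameters
    ----------
    values : array of float
        One value per month; NaN marks a missing month.
    name : str
        Variable name (e.g. ``"temperature"``, ``"lna_abundance"``).
    units : str
        Units of ``values`` after any transform (e.g. ``"log10(cells/ml)"``).
    log10_transformed : bool
        True if the raw variable was log10-transformed upstream.
    start : (year, month)
        Calendar anchor of t = 0 (defaults to April 2002, the start of the
        decade the defaults emulate).
    """

    values: np.ndarray
    name: str = ""
    units: str = ""
    log10_transformed: bool = False
    start: tuple[int, int] = (2002, 4)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        y, m = self.start
        if not 1 <= m <= 12:
            raise ValueError(f"start month must be in 1..12, got {m}")

    @property
    def n_months(self) -> int:
        return self.values.size

    @property
    def t(self) -> np.ndarray:
        """Integer month index, 0-based at the first sample."""
        return np.arange(self.n_months)

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing months."""
        return np.isfinite(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def calendar_months(self) -> np.ndarray:
        """Calendar month (1..12) of each sample."""
        _, m0 = self.start
        return (m0 - 1 + self.t) % 12 + 1

    def calendar_years(self) -> np.ndarray:
        """Calendar year of each sample."""
        y0, m0 = self.start
        return y0 + (m0 - 1 + self.t) // 12

    def dates(self) -> pd.PeriodIndex:
        y0, m0 = self.start
        return pd.period_range(f"{y0}-{m0:02d}", periods=self.n_months, freq="M")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates().to_timestamp(),
                "variable": self.name,
                "value": self.values,
            }
        )
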