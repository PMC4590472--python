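"""Independent brute-force oracles used only by the tests.

The harmonic oracle minimizes the residual sum of squares of
x_t - A*cos(2*pi*t/T - theta) over a dense (T, A, theta) grid with
multi-resolution refinement; it shares no code path with the package's
periodogram/least-squares fit.
"""

from __future__ import annotations

import numpy as np


def grid_search_harmonic(
    t: np.ndarray,
    x: np.ndarray,
    period_bounds: tuple[float, float] | None = None,
    levels: int = 4,
) -> tuple[float, float, float]:
    """Best-fit (T, A, theta) of a single cosine by direct SSE search."""
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    n = t.size
    if period_bounds is None:
        period_bounds = (2.0, n / 2.0)
    T_lo, T_hi = period_bounds
    A_hi = 2.0 * float(np.max(np.abs(x))) or 1.0
    A_lo = 0.0
    th_lo, th_hi = 0.0, 2.0 * np.pi

    best = (0.5 * (T_lo + T_hi), 0.5 * A_hi, np.pi)
    for _ in range(levels):
        Ts = np.linspace(T_lo, T_hi, 81)
        As = np.linspace(A_lo, A_hi, 41)
        ths = np.linspace(th_lo, th_hi, 65)
        best_sse = np.inf
        for T in Ts:
            # cos matrix over theta grid: (n_theta, n)
            C = np.cos(2.0 * np.pi * t[None, :] / T - ths[:, None])
            model = As[:, None, None] * C[None, :, :]
            sse = ((x[None, None, :] - model) ** 2).sum(axis=2)
            idx = np.unravel_index(np.argmin(sse), sse.shape)
            if sse[idx] < best_sse:
                best_sse = float(sse[idx])
                best = (float(T), float(As[idx[0]]), float(ths[idx[1]]))
        T0, A0, th0 = best
        dT = (T_hi - T_lo) / 80
        dA = (A_hi - A_lo) / 40
        dth = (th_hi - th_lo) / 64
        T_lo, T_hi = max(2.0, T0 - 2 * dT), min(n / 2.0, T0 + 2 * dT)
        A_lo, A_hi = max(0.0, A0 - 2 * dA), A0 + 2 * dA
        th_lo, th_hi = th0 - 2 * dth, th0 + 2 * dth
    T0, A0, th0 = best
    return T0, A0, th0 % (2.0 * np.pi)
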