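"""Independent brute-force oracles used to cross-check the regressions.

These deliberately avoid the closed-form least-squares path: a two-parameter
grid search over (slope, intercept) is refined around the running minimum of
the summed squared residuals until the grid resolution is far below the
comparison tolerance.
"""

from __future__ import annotations

import numpy as np


def grid_line_fit(
    x: np.ndarray,
    y: np.ndarray,
    slope_range: tuple[float, float],
    intercept_range: tuple[float, float],
    rounds: int = 30,
    n: int = 81,
) -> tuple[float, float]:
    """Minimize sum((y - (b + a*x))**2) over a refining (a, b) grid.

    The initial ranges must bracket the optimum.  Each round re-centres on
    the running minimum and shrinks the span only by a factor of 2.5 —
    slope and intercept are strongly correlated, so the joint optimum can
    sit well off the per-round minimum and aggressive shrinking would lose
    it.  Thirty rounds resolve ~1e-11 of the initial span.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s_lo, s_hi = slope_range
    i_lo, i_hi = intercept_range
    s_best = i_best = None
    for _ in range(rounds):
        ss = np.linspace(s_lo, s_hi, n)
        ii = np.linspace(i_lo, i_hi, n)
        S, I = np.meshgrid(ss, ii)
        sse = ((y[None, None, :] - (I[..., None] + S[..., None] * x[None, None, :])) ** 2).sum(
            axis=-1
        )
        k = np.unravel_index(np.argmin(sse), sse.shape)
        s_best, i_best = float(S[k]), float(I[k])
        s_half = (s_hi - s_lo) / 5.0
        i_half = (i_hi - i_lo) / 5.0
        s_lo, s_hi = s_best - s_half, s_best + s_half
        i_lo, i_hi = i_best - i_half, i_best + i_half
    return s_best, i_best
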