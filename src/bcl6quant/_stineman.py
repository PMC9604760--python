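"""Stineman's rational interpolation (Stineman 1980).

A monotonicity-respecting 1-D interpolation scheme: the interpolant
passes through every data point, reproduces straight-line data exactly,
and applies a rational correction to the secant line that suppresses
the overshoot cubic splines produce near steep gradients, so no new
local extrema appear between data points.  Used as the smoothing
operator for group-level intensity histograms.

Slopes at the data points are Stineman's own estimate: the slope at the
middle point of the circle passing through three consecutive points,
which reduces to the chord slope for collinear data.
"""

from __future__ import annotations

import numpy as np

from .errors import ContractError


def stineman_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Slope estimates at the data points (circle through three points).

    At interior point *i* the slope is that of the circumcircle of
    points *i-1*, *i*, *i+1* at point *i*.  End slopes extrapolate the
    adjacent chord (``2*s - yp_neighbour``), clamped to zero if that
    would flip the sign of the nearest chord slope, which preserves
    monotonicity at the boundary.
    """
    dx = np.diff(x)
    dy = np.diff(y)
    if np.any(dx <= 0):
        raise ContractError("x must be strictly increasing")
    yp = np.empty_like(y, dtype=np.float64)
    # squared chord lengths on either side of each interior point
    dd_prev = dx[:-1] ** 2 + dy[:-1] ** 2
    dd_next = dx[1:] ** 2 + dy[1:] ** 2
    yp[1:-1] = (dy[:-1] * dd_next + dy[1:] * dd_prev) / (
        dx[:-1] * dd_next + dx[1:] * dd_prev
    )
    s0, sn = dy[0] / dx[0], dy[-1] / dx[-1]
    e0 = 2.0 * s0 - yp[1]
    en = 2.0 * sn - yp[-2]
    yp[0] = e0 if e0 * s0 > 0 or s0 == e0 == 0 else 0.0
    yp[-1] = en if en * sn > 0 or sn == en == 0 else 0.0
    return yp


def stineman_interp(
    xi: np.ndarray, x: np.ndarray, y: np.ndarray, yp: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate Stineman's rational interpolant of (x, y) at ``xi``.

    Within each interval the value is the secant line plus a rational
    correction built from the slope mismatches at the two endpoints;
    the correction vanishes at both endpoints, so the interpolant
    passes through every data point, and it is identically zero for
    collinear data.  ``xi`` outside [x[0], x[-1]] extrapolates with the
    end-point slopes.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xi = np.asarray(xi, dtype=np.float64)
    if x.ndim != 1 or x.shape != y.shape:
        raise ContractError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ContractError("Stineman interpolation requires at least 3 points")
    if yp is None:
        yp = stineman_slopes(x, y)

    idx = np.clip(np.searchsorted(x, xi) - 1, 0, x.size - 2)
    x1, x2 = x[idx], x[idx + 1]
    y1, y2 = y[idx], y[idx + 1]
    s = (y2 - y1) / (x2 - x1)

    yo = y1 + s * (xi - x1)  # secant baseline
    dy1 = (yp[idx] - s) * (xi - x1)
    dy2 = (yp[idx + 1] - s) * (xi - x2)
    prod = dy1 * dy2
    out = yo.copy()
    pos = prod > 0
    neg = prod < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[pos] = yo[pos] + prod[pos] / (dy1[pos] + dy2[pos])
        out[neg] = yo[neg] + prod[neg] * (2.0 * xi[neg] - x1[neg] - x2[neg]) / (
            (dy1[neg] - dy2[neg]) * (x2[neg] - x1[neg])
        )
    # exact pass-through at the data points (guards rounding in dy1/dy2)
    exact = np.searchsorted(x, xi)
    hits = (exact < x.size) & (x[np.minimum(exact, x.size - 1)] == xi)
    out[hits] = y[exact[hits]]
    return out
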