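"""Piecewise-cubic interpolation of irregularly sampled streams.

A local 4-point Lagrange cubic is used: for an evaluation point inside
knot interval [t_i, t_{i+1}) the interpolant is the unique cubic through
knots i-1..i+2 (stencils clamped at the ends). The scheme passes through
every knot and reproduces cubic polynomials exactly; it is local, so it
runs in O(n) with O(1) memory per point, which matters at multi-day
50 Hz scale.
"""
from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _lagrange_cubic_py(t, y, grid, out):
    n = t.shape[0]
    i = np.searchsorted(t, grid, side="right") - 1
    i = np.clip(i, 1, n - 3)
    idx = i[:, None] + np.array([-1, 0, 1, 2])
    ts = t[idx]
    out[:] = 0.0
    for j in range(4):
        w = np.ones(len(grid))
        for k in range(4):
            if k != j:
                w *= (grid - ts[:, k]) / (ts[:, j] - ts[:, k])
        out += w[:, None] * y[idx[:, j]]


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _lagrange_cubic_nb(t, y, grid, out):  # pragma: no cover - jitted
        n = t.shape[0]
        m = grid.shape[0]
        nax = y.shape[1]
        i = 1
        for p in range(m):
            g = grid[p]
            while i < n - 3 and t[i + 1] <= g:
                i += 1
            ii = i
            if ii < 1:
                ii = 1
            t0, t1, t2, t3 = t[ii - 1], t[ii], t[ii + 1], t[ii + 2]
            w0 = (g - t1) * (g - t2) * (g - t3) / ((t0 - t1) * (t0 - t2) * (t0 - t3))
            w1 = (g - t0) * (g - t2) * (g - t3) / ((t1 - t0) * (t1 - t2) * (t1 - t3))
            w2 = (g - t0) * (g - t1) * (g - t3) / ((t2 - t0) * (t2 - t1) * (t2 - t3))
            w3 = (g - t0) * (g - t1) * (g - t2) / ((t3 - t0) * (t3 - t1) * (t3 - t2))
            for a in range(nax):
                out[p, a] = (
                    w0 * y[ii - 1, a]
                    + w1 * y[ii, a]
                    + w2 * y[ii + 1, a]
                    + w3 * y[ii + 2, a]
                )


def lagrange_cubic(
    t: np.ndarray, y: np.ndarray, grid: np.ndarray, out: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate the piecewise Lagrange cubic through ``(t, y)`` at ``grid``.

    Parameters
    ----------
    t : strictly increasing sample times, shape (n,), n >= 4.
    y : samples, shape (n,) or (n, k).
    grid : evaluation points, ascending, inside [t[0], t[-1]].
    out : optional preallocated output buffer, shape (len(grid), k),
        C-contiguous float64 (written in place when given).

    Returns
    -------
    Interpolated values with shape (len(grid),) or (len(grid), k).
    """
    t = np.ascontiguousarray(t, dtype=np.float64)
    grid = np.ascontiguousarray(grid, dtype=np.float64)
    squeeze = y.ndim == 1
    y2 = np.ascontiguousarray(y.reshape(len(y), -1), dtype=np.float64)
    if t.shape[0] < 4:
        raise ValueError("need at least 4 samples for cubic interpolation")
    if out is None:
        out = np.empty((grid.shape[0], y2.shape[1]), dtype=np.float64)
    if _HAVE_NUMBA:
        _lagrange_cubic_nb(t, y2, grid, out)
    else:
        _lagrange_cubic_py(t, y2, grid, out)
    return out[:, 0] if squeeze else out
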