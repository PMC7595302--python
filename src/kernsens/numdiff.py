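"""Finite-difference derivatives, used as the independent oracle in tests
and diagnostics.

Central differences with a per-coordinate relative step:
``h_j = step * max(1, |x_j|)`` with ``step = 1e-6`` for gradients and
``step = 1e-4`` for (nested central) Hessians.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def numeric_gradient(f: Callable[[np.ndarray], float], x, step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    g = np.empty_like(x)
    for j in range(x.size):
        h = step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        fp, fm = f(xp), f(xm)
        if not (np.isfinite(fp) and np.isfinite(fm)):
            raise ValueError("non-finite function value in finite difference")
        g[j] = (fp - fm) / (2.0 * h)
    return g


def numeric_hessian(f: Callable[[np.ndarray], float], x, step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    d = x.size
    H = np.empty((d, d))
    h = np.array([step * max(1.0, abs(x[j])) for j in range(d)])
    f0 = f(x)
    if not np.isfinite(f0):
        raise ValueError("non-finite function value in finite difference")
    for j in range(d):
        xp, xm = x.copy(), x.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        H[j, j] = (f(xp) - 2.0 * f0 + f(xm)) / h[j] ** 2
        for k in range(j + 1, d):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[j, k]] += [h[j], h[k]]
            xpm[j] += h[j]
            xpm[k] -= h[k]
            xmp[j] -= h[j]
            xmp[k] += h[k]
            xmm[[j, k]] -= [h[j], h[k]]
            H[j, k] = H[k, j] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * h[j] * h[k])
    return H


def numeric_derivative(f: Callable[[np.ndarray], float], x, order: int = 1, step: float | None = None):
    """Dispatch to :func:`numeric_gradient` (order 1) or :func:`numeric_hessian` (order 2)."""
    if order == 1:
        return numeric_gradient(f, x, step=step if step is not None else 1e-6)
    if order == 2:
        return numeric_hessian(f, x, step=step if step is not None else 1e-4)
    raise ValueError("order must be 1 or 2")
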