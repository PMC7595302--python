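"""Hilbert-Schmidt Independence Criterion: value, analytic derivatives,
derivative vector fields, and gradient flows.

The biased empirical estimator is ``HSIC = (1/n^2) Tr(K H L H)`` with
kernel matrices K (on X), L (on Y) and the centering matrix
``H = I - (1/n) 1 1'``.  Grouping the terms that do not depend on X as
``A = H L H`` gives ``HSIC = (1/n^2) Tr(K A)``, whose derivative in sample
``x_i``, feature q, is

    d HSIC / d x_i^q = (2/n^2) A_i . d_q k(x_i),

i.e. twice the A-weighted kernel gradient row (the factor two because x_i
appears in both kernel arguments).  For the RBF kernel with bandwidth
``sigma`` (``gamma = 1/(2 sigma^2)``) the same quantity has a trace form,

    d HSIC / d x_i^q = -(2 / (sigma^2 n^2)) Tr(H L H (K o M^q)),

where ``M^q`` is zero except for row i, holding ``x_i^q - x_j^q``, and
``o`` is the Hadamard product.  Both code paths are implemented and must
agree; the trace path is kept deliberately literal as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kernels import KernelSpec, default_spec, gram_gradient, gram_matrix


def _as_matrix(Z) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    return Z[:, None] if Z.ndim == 1 else Z


@dataclass
class HsicState:
    X: np.ndarray
    Y: np.ndarray
    specK: KernelSpec
    specL: KernelSpec
    K: np.ndarray
    L: np.ndarray
    A: np.ndarray              # H L H
    B: np.ndarray              # H K H
    value: float
    dX: Optional[np.ndarray] = None
    dY: Optional[np.ndarray] = None


@dataclass
class FieldSummary:
    """Per-point derivative fields and their joint modulus."""

    Sx: np.ndarray   # (n, d_x)
    Sy: np.ndarray   # (n, d_y)
    modulus: np.ndarray  # (n,)


def hsic(X, Y, specK: Optional[KernelSpec] = None,
         specL: Optional[KernelSpec] = None) -> HsicState:
    """Compute the empirical HSIC between paired samples X and Y.

    Kernels default to RBF with the median-heuristic bandwidth per variable.
    """
    X, Y = _as_matrix(X), _as_matrix(Y)
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("X and Y must have the same number of samples")
    if n < 2:
        raise ValueError("HSIC requires at least 2 samples")
    if specK is None:
        specK = default_spec("rbf", X)
    if specL is None:
        specL = default_spec("rbf", Y)
    K = gram_matrix(specK, X, X)
    L = gram_matrix(specL, Y, Y)
    H = np.eye(n) - np.ones((n, n)) / n
    A = H @ L @ H
    B = H @ K @ H
    value = float(np.trace(K @ A)) / n**2
    return HsicState(X=X, Y=Y, specK=specK, specL=specL, K=K, L=L, A=A, B=B, value=value)


def hsic_gradient(state: HsicState, wrt: str = "X") -> np.ndarray:
    """Analytic HSIC derivative matrix, one row per sample.

    ``wrt='X'`` returns (n, d_x) with entries ``(2/n^2) sum_j A_ij
    d k(x_i, x_j)/d x_i^q``; symmetrically for Y with B = H K H.  The
    result is cached on the state.
    """
    if wrt not in ("X", "Y"):
        raise ValueError("wrt must be 'X' or 'Y'")
    n = state.X.shape[0]
    if wrt == "X":
        T = gram_gradient(state.specK, state.X, state.X)  # (n, n, d)
        out = (2.0 / n**2) * np.einsum("ij,ijq->iq", state.A, T)
        state.dX = out
    else:
        T = gram_gradient(state.specL, state.Y, state.Y)
        out = (2.0 / n**2) * np.einsum("ij,ijq->iq", state.B, T)
        state.dY = out
    return out


def hsic_gradient_rbf_trace(state: HsicState, wrt: str = "X") -> np.ndarray:
    """RBF-only trace form of the HSIC derivative (independent code path).

    Builds, for each sample i and feature q, the matrix ``M^q`` whose i-th
    row holds ``x_i^q - x_j^q`` (zeros elsewhere) and evaluates
    ``-(2/(sigma^2 n^2)) Tr(H L H (K o M^q))``.
    """
    if wrt == "X":
        spec, Z, C, Kmat = state.specK, state.X, state.A, state.K
    elif wrt == "Y":
        spec, Z, C, Kmat = state.specL, state.Y, state.B, state.L
    else:
        raise ValueError("wrt must be 'X' or 'Y'")
    if spec.family != "rbf":
        raise ValueError("trace form requires the rbf kernel")
    sigma2 = spec.sigma**2
    n, d = Z.shape
    out = np.empty((n, d))
    for i in range(n):
        for q in range(d):
            M = np.zeros((n, n))
            M[i, :] = Z[i, q] - Z[:, q]
            out[i, q] = -(2.0 / (sigma2 * n**2)) * np.trace(C @ (Kmat * M))
    return out


def sensitivity_field(state: HsicState) -> FieldSummary:
    """Derivative vector field of HSIC over the paired samples, with the
    per-point modulus of the concatenated (x, y) directional derivative."""
    dX = state.dX if state.dX is not None else hsic_gradient(state, "X")
    dY = state.dY if state.dY is not None else hsic_gradient(state, "Y")
    modulus = np.sqrt(np.sum(dX**2, axis=1) + np.sum(dY**2, axis=1))
    return FieldSummary(Sx=dX, Sy=dY, modulus=modulus)


# ---------------------------------------------------------------------------
# gradient flow
# ---------------------------------------------------------------------------

@dataclass
class FlowResult:
    hsic_values: np.ndarray    # (iters + 1,)
    X_final: np.ndarray
    Y_final: np.ndarray
    step: float


def auto_step(state: HsicState, fraction: float = 0.1) -> float:
    """Scale-aware default step: ``fraction * data scale / max |gradient|``
    at the starting configuration."""
    dX = hsic_gradient(state, "X")
    dY = hsic_gradient(state, "Y")
    gmax = max(np.max(np.abs(dX)), np.max(np.abs(dY)), 1e-300)
    scale = 0.5 * (np.std(state.X) + np.std(state.Y))
    return fraction * max(scale, 1e-12) / gmax


def hsic_flow(X0, Y0, specK: Optional[KernelSpec] = None,
              specL: Optional[KernelSpec] = None, step: Optional[float] = None,
              iters: int = 50, direction: str = "maximize", move: str = "both",
              refresh_bandwidth: bool = False) -> FlowResult:
    """Move samples by explicit-Euler steps along the HSIC gradient.

    ``direction='maximize'`` ascends (samples organise into maximally
    dependent configurations); ``'minimize'`` descends toward independence.
    Bandwidths are frozen at their initial values by default so the
    objective stays fixed between steps; ``refresh_bandwidth`` re-applies
    the median heuristic each iteration.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    if move not in ("X", "Y", "both"):
        raise ValueError("move must be 'X', 'Y' or 'both'")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    X = _as_matrix(X0).copy()
    Y = _as_matrix(Y0).copy()
    state = hsic(X, Y, specK, specL)
    specK, specL = state.specK, state.specL
    if step is None:
        step = auto_step(state)
    if step < 0:
        raise ValueError("step must be nonnegative")
    sign = 1.0 if direction == "maximize" else -1.0
    values = [state.value]
    for _ in range(iters):
        if move in ("X", "both"):
            X = X + sign * step * hsic_gradient(state, "X")
        if move in ("Y", "both"):
            Y = Y + sign * step * hsic_gradient(state, "Y")
        state = hsic(X, Y,
                     None if refresh_bandwidth else specK,
                     None if refresh_bandwidth else specL)
        if not np.isfinite(state.value):
            raise FloatingPointError("HSIC diverged during the gradient flow")
        values.append(state.value)
    return FlowResult(hsic_values=np.asarray(values), X_final=X, Y_final=Y, step=float(step))
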