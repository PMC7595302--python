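"""Calculus on kernel expansions ``f(x) = sum_i alpha_i k(x, x_i) + b``.

Every model in this package — GP/kernel-ridge regression, the SVM decision
function, Parzen/KECA densities, and (after grouping terms) HSIC — reduces
to such an expansion, so its derivatives reduce to derivatives of the
kernel function contracted with the coefficient vector.  This module
provides gradients, Hessians, Laplacians, sensitivity maps and the four
derivative-based norms used to study regularisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .kernels import (
    KernelSpec,
    gram_gradient,
    gram_matrix,
    gram_second_partials,
    kernel_hessian,
    rbf_mth_partial,
)


@dataclass
class KernelExpansion:
    """Anchor points, coefficients and bias of a kernel expansion."""

    spec: KernelSpec
    anchors: np.ndarray  # (n, d)
    alpha: np.ndarray    # (n,)
    bias: float = 0.0

    def __post_init__(self):
        self.anchors = np.atleast_2d(np.asarray(self.anchors, dtype=float))
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if self.alpha.size != self.anchors.shape[0]:
            raise ValueError(
                f"alpha length {self.alpha.size} != anchor count {self.anchors.shape[0]}"
            )
        if not np.all(np.isfinite(self.anchors)):
            raise ValueError("anchors must be finite")

    @property
    def n_anchors(self) -> int:
        return self.anchors.shape[0]

    @property
    def dim(self) -> int:
        return self.anchors.shape[1]

    # convenience delegates
    def __call__(self, X):
        return evaluate(self, X)

    def save(self, path):
        """Serialise to a .npz container (spec stored as a YAML string)."""
        np.savez(
            path,
            anchors=self.anchors,
            alpha=self.alpha,
            bias=np.array(self.bias),
            spec=np.array(yaml.safe_dump(self.spec.to_dict())),
        )

    @classmethod
    def load(cls, path) -> "KernelExpansion":
        with np.load(path, allow_pickle=False) as z:
            spec = KernelSpec.from_dict(yaml.safe_load(str(z["spec"])))
            return cls(spec=spec, anchors=z["anchors"], alpha=z["alpha"], bias=float(z["bias"]))


@dataclass
class SensitivityReport:
    """Per-feature sensitivities ``s_j`` and per-point sensitivities ``q_i``.

    ``s_j`` is the empirical mean over evaluation points of the squared
    partial derivative of f with respect to feature j; ``q_i`` averages the
    squared partials over features instead.  Both summarise the same matrix
    of squared derivatives, hence ``n_eval * sum_j s_j == d * sum_i q_i``.
    """

    feature_sensitivity: np.ndarray  # (d,)
    point_sensitivity: np.ndarray    # (n_eval,)
    eval_points: np.ndarray          # (n_eval, d)

    def to_frame(self) -> pd.DataFrame:
        d = self.eval_points.shape[1]
        df = pd.DataFrame(self.eval_points, columns=[f"x{j+1}" for j in range(d)])
        df["point_sensitivity"] = self.point_sensitivity
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


@dataclass
class DerivativeNorms:
    """The four quadratic-form norms of a fitted expansion.

    rkhs_sq = alpha' K alpha         (RKHS norm of f)
    l2_sq   = alpha' K'K alpha       (empirical L2 norm of f)
    grad_sq = alpha' (dK)'(dK) alpha (empirical L2 norm of the gradient)
    curv_sq = alpha' (d2K)'(d2K) alpha (empirical L2 norm of unmixed seconds)
    """

    rkhs_sq: float
    l2_sq: float
    grad_sq: float
    curv_sq: float

    def as_dict(self) -> dict:
        return {
            "rkhs_sq": self.rkhs_sq,
            "l2_sq": self.l2_sq,
            "grad_sq": self.grad_sq,
            "curv_sq": self.curv_sq,
        }


# ---------------------------------------------------------------------------
# evaluation and derivatives
# ---------------------------------------------------------------------------

def evaluate(exp: KernelExpansion, X) -> np.ndarray | float:
    """f at one point (scalar) or at each row of X (vector)."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    K = gram_matrix(exp.spec, np.atleast_2d(X), exp.anchors)
    out = K @ exp.alpha + exp.bias
    return float(out[0]) if single else out


def gradient(exp: KernelExpansion, X) -> np.ndarray:
    """Gradient of f: shape (d,) for a single point, (n, d) for a matrix."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    G = gram_gradient(exp.spec, np.atleast_2d(X), exp.anchors)  # (n, m, d)
    out = np.einsum("nmd,m->nd", G, exp.alpha)
    return out[0] if single else out


def hessian(exp: KernelExpansion, x) -> np.ndarray:
    """Hessian of f at a single point, exactly symmetric d x d."""
    return hessian_batch(exp, np.asarray(x, dtype=float).ravel()[None, :])[0]


def hessian_batch(exp: KernelExpansion, X) -> np.ndarray:
    """Hessians of f at each row of X, shape (n, d, d).

    Contracts the per-family closed forms over the anchors in one einsum
    instead of looping over anchor pairs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    spec, A, a = exp.spec, exp.anchors, exp.alpha
    n, d = X.shape
    if spec.family == "linear" or (spec.family == "poly" and spec.degree == 1):
        return np.zeros((n, d, d))
    if spec.family == "poly":
        p, g = spec.degree, spec.gamma
        base = g * (X @ A.T) + spec.c0
        w = a * (p * (p - 1) * g**2 * base ** (p - 2))          # (n, m)
        H = np.einsum("nm,md,me->nde", w, A, A)
    elif spec.family == "tanh":
        g = spec.gamma
        u = g * (X @ A.T) + spec.c0
        w = a * (-2.0 * g**2 * np.tanh(u) / np.cosh(u) ** 2)
        H = np.einsum("nm,md,me->nde", w, A, A)
    elif spec.family == "rbf":
        g = spec.gamma
        wk = a * gram_matrix(spec, X, A)                         # (n, m)
        diff = X[:, None, :] - A[None, :, :]
        H = 4.0 * g**2 * np.einsum("nm,nmd,nme->nde", wk, diff, diff)
        H -= 2.0 * g * wk.sum(axis=1)[:, None, None] * np.eye(d)
    else:  # ard
        wk = a * gram_matrix(spec, X, A)
        z = (X[:, None, :] - A[None, :, :]) / spec.lengthscales**2
        H = np.einsum("nm,nmd,nme->nde", wk, z, z)
        H -= wk.sum(axis=1)[:, None, None] * np.diag(1.0 / spec.lengthscales**2)
    # einsum contraction order need not round identically across (d, e);
    # enforce exact symmetry
    return 0.5 * (H + H.transpose(0, 2, 1))


def laplacian(exp: KernelExpansion, X) -> np.ndarray | float:
    """Sum of unmixed second partials; computed from the stacked
    second-partials tensor rather than the full Hessian."""
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    S = gram_second_partials(exp.spec, np.atleast_2d(X), exp.anchors)
    out = np.einsum("nmd,m->n", S, exp.alpha)
    return float(out[0]) if single else out


def partial_derivative(exp: KernelExpansion, x, j: int, m: int = 1) -> float:
    """m-th unmixed partial of f with respect to feature j at point x.

    Orders m > 2 are available for the rbf family only (via the
    higher-order recursion); m = 1, 2 work for every family.
    """
    if m < 1:
        raise ValueError("order m must be >= 1")
    x = np.asarray(x, dtype=float).ravel()
    if m == 1:
        return float(gradient(exp, x)[j])
    if m == 2:
        S = gram_second_partials(exp.spec, x[None, :], exp.anchors)
        return float(S[0, :, j] @ exp.alpha)
    if exp.spec.family != "rbf":
        raise ValueError(f"order m={m} derivatives require the rbf family")
    return float(sum(a * rbf_mth_partial(exp.spec, x, xi, j, m)
                     for a, xi in zip(exp.alpha, exp.anchors)))


# ---------------------------------------------------------------------------
# sensitivity maps and derivative norms
# ---------------------------------------------------------------------------

def sensitivity_map(exp: KernelExpansion, Xeval=None) -> SensitivityReport:
    """Empirical sensitivity map of the expansion over an evaluation set.

    Defaults to evaluating at the training anchors.  Uses squared partial
    derivatives: ``s_j = mean_i (df(x_i)/dx_j)^2`` per feature and
    ``q_i = mean_j (df(x_i)/dx_j)^2`` per point.
    """
    Xeval = exp.anchors if Xeval is None else np.atleast_2d(np.asarray(Xeval, dtype=float))
    if Xeval.shape[0] == 0:
        raise ValueError("empty evaluation set")
    D2 = gradient(exp, Xeval) ** 2  # (n_eval, d)
    return SensitivityReport(
        feature_sensitivity=D2.mean(axis=0),
        point_sensitivity=D2.mean(axis=1),
        eval_points=Xeval,
    )


def sensitivity_from_derivatives(D: np.ndarray, Xeval: np.ndarray) -> SensitivityReport:
    """Sensitivity report from an explicit derivative matrix (n_eval, d)."""
    D = np.atleast_2d(np.asarray(D, dtype=float))
    D2 = D**2
    return SensitivityReport(D2.mean(axis=0), D2.mean(axis=1), np.atleast_2d(Xeval))


def derivative_norms(exp: KernelExpansion, Xeval=None) -> DerivativeNorms:
    """The four quadratic forms a' K a, a' K'K a, a'(dK)'(dK)a, a'(d2K)'(d2K)a.

    The RKHS norm uses the anchors-by-anchors Gram; the other three use the
    evaluation points (default: the anchors) as rows.  dK and d2K are the
    first- and second-derivative matrices stacked feature-wise
    ((n_eval * d) x n_anchors), so the forms are well defined for d > 1.
    """
    a = exp.alpha
    Kaa = gram_matrix(exp.spec, exp.anchors, exp.anchors)
    Xeval = exp.anchors if Xeval is None else np.atleast_2d(np.asarray(Xeval, dtype=float))
    K = gram_matrix(exp.spec, Xeval, exp.anchors)
    G = gram_gradient(exp.spec, Xeval, exp.anchors)
    S = gram_second_partials(exp.spec, Xeval, exp.anchors)
    Ga = np.einsum("nmd,m->nd", G, a)
    Sa = np.einsum("nmd,m->nd", S, a)
    return DerivativeNorms(
        rkhs_sq=float(a @ Kaa @ a),
        l2_sq=float(np.sum((K @ a) ** 2)),
        grad_sq=float(np.sum(Ga**2)),
        curv_sq=float(np.sum(Sa**2)),
    )
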