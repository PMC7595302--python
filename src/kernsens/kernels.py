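"""Kernel functions and their analytic derivatives with respect to the first argument.

Five kernel families are supported: linear, polynomial, Gaussian (RBF),
hyperbolic tangent, and automatic relevance determination (ARD).  For each
family the module provides the kernel value, the gradient and the full
Hessian (second/mixed partials) in the first argument, as well as vectorised
Gram-matrix and Gram-derivative builders.  Higher-order unmixed partials of
the RBF kernel are available through a chain-rule (Faa di Bruno) recursion.

Conventions
-----------
* Derivatives are always taken with respect to the FIRST argument ``x``.
  For stationary kernels (rbf, ard) the derivative in the second argument
  is the negative of the first-argument derivative.
* The RBF kernel is parameterised as ``k(x, y) = exp(-gamma * ||x - y||^2)``;
  a bandwidth ``sigma`` maps to ``gamma = 1 / (2 sigma^2)``.
* Derivative tensors are laid out ``(evaluation point, anchor, feature)``.

A note on ARD signs: differentiating
``k(x, y) = nu^2 exp(-1/2 sum_d ((x_d - y_d)/lambda_d)^2)`` gives
``d k / d x_j = -((x_j - y_j)/lambda_j^2) k`` and an unmixed second partial
``((x_j - y_j)^2/lambda_j^4 - 1/lambda_j^2) k``.  Formula tables in the
literature sometimes drop these minus signs; this module follows the
calculus, and the finite-difference oracle in :mod:`kernsens.numdiff`
verifies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

FAMILIES = ("linear", "poly", "rbf", "tanh", "ard")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its hyperparameters.

    Parameters
    ----------
    family : str
        One of ``linear``, ``poly``, ``rbf``, ``tanh``, ``ard``.
    gamma : float, optional
        Scale of the poly/rbf/tanh kernels.  For rbf, ``gamma = 1/(2 sigma^2)``.
    c0 : float
        Offset of the poly/tanh kernels.
    degree : int
        Polynomial degree ``p >= 1``.
    nu : float
        Amplitude of the ARD kernel.
    lengthscales : ndarray, optional
        Per-feature lengthscales ``lambda_d > 0`` of the ARD kernel; its
        length must equal the data dimension at evaluation time.
    """

    family: str
    gamma: Optional[float] = None
    c0: float = 0.0
    degree: int = 2
    nu: float = 1.0
    lengthscales: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {FAMILIES}")
        if self.family in ("poly", "rbf", "tanh"):
            if self.gamma is None or not np.isfinite(self.gamma) or self.gamma <= 0:
                raise ValueError(f"{self.family} kernel requires gamma > 0, got {self.gamma}")
        if self.family == "poly":
            if int(self.degree) != self.degree or self.degree < 1:
                raise ValueError(f"poly degree must be an integer >= 1, got {self.degree}")
        if self.family == "ard":
            if self.nu <= 0:
                raise ValueError("ard amplitude nu must be positive")
            if self.lengthscales is None:
                raise ValueError("ard kernel requires lengthscales")
            ls = np.asarray(self.lengthscales, dtype=float)
            if ls.ndim != 1 or not np.all(ls > 0):
                raise ValueError("ard lengthscales must be a 1-d vector of positive reals")
            object.__setattr__(self, "lengthscales", ls)

    # ---- sigma <-> gamma spelling -------------------------------------
    @property
    def sigma(self) -> Optional[float]:
        """RBF bandwidth ``sigma`` such that ``gamma = 1/(2 sigma^2)``."""
        if self.gamma is None:
            return None
        return 1.0 / np.sqrt(2.0 * self.gamma)

    @classmethod
    def rbf_from_sigma(cls, sigma: float) -> "KernelSpec":
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return cls(family="rbf", gamma=1.0 / (2.0 * sigma**2))

    # ---- (de)serialisation --------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"family": self.family}
        if self.gamma is not None:
            d["gamma"] = float(self.gamma)
        if self.family in ("poly", "tanh"):
            d["c0"] = float(self.c0)
        if self.family == "poly":
            d["degree"] = int(self.degree)
        if self.family == "ard":
            d["nu"] = float(self.nu)
            d["lengthscales"] = [float(v) for v in self.lengthscales]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        d = dict(d)
        if "sigma" in d and "gamma" not in d:
            sigma = float(d.pop("sigma"))
            d["gamma"] = 1.0 / (2.0 * sigma**2)
        ls = d.get("lengthscales")
        if ls is not None:
            d["lengthscales"] = np.asarray(ls, dtype=float)
        return cls(**d)


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _check_pair(spec: KernelSpec, x: np.ndarray, y: np.ndarray):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: x has {x.size} features, y has {y.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    if spec.family == "ard" and spec.lengthscales.size != x.size:
        raise ValueError(
            f"ard lengthscale count {spec.lengthscales.size} != data dimension {x.size}"
        )
    return x, y


def _check_matrices(spec: KernelSpec, X: np.ndarray, Y: np.ndarray):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]} features")
    if spec.family == "ard" and spec.lengthscales.size != X.shape[1]:
        raise ValueError("ard lengthscale count does not match data dimension")
    return X, Y


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def kernel_value(spec: KernelSpec, x, y) -> float:
    """Evaluate ``k(x, y)`` for a single pair of points."""
    x, y = _check_pair(spec, x, y)
    return float(gram_matrix(spec, x[None, :], y[None, :])[0, 0])


def kernel_gradient(spec: KernelSpec, x, y) -> np.ndarray:
    """Gradient ``d k(x, y) / d x`` as a length-d vector."""
    x, y = _check_pair(spec, x, y)
    return gram_gradient(spec, x[None, :], y[None, :])[0, 0]


def kernel_hessian(spec: KernelSpec, x, y) -> np.ndarray:
    """Hessian ``d^2 k(x, y) / dx dx^T`` as a symmetric d x d matrix."""
    x, y = _check_pair(spec, x, y)
    d = x.size
    if spec.family == "linear":
        return np.zeros((d, d))
    if spec.family == "poly":
        p, g, c0 = spec.degree, spec.gamma, spec.c0
        if p == 1:
            return np.zeros((d, d))
        base = g * float(x @ y) + c0
        return p * (p - 1) * g**2 * np.outer(y, y) * base ** (p - 2)
    if spec.family == "rbf":
        g = spec.gamma
        diff = x - y
        k = np.exp(-g * float(diff @ diff))
        return 4.0 * g**2 * np.outer(diff, diff) * k - 2.0 * g * k * np.eye(d)
    if spec.family == "tanh":
        g, c0 = spec.gamma, spec.c0
        u = g * float(x @ y) + c0
        sech2 = 1.0 / np.cosh(u) ** 2
        return -2.0 * g**2 * np.outer(y, y) * sech2 * np.tanh(u)
    # ard
    ls2 = spec.lengthscales**2
    z = (x - y) / ls2
    k = _ard_value(spec, x, y)
    return (np.outer(z, z) - np.diag(1.0 / ls2)) * k


def _ard_value(spec: KernelSpec, x, y) -> float:
    r = (x - y) / spec.lengthscales
    return spec.nu**2 * np.exp(-0.5 * float(r @ r))


def rbf_mth_partial(spec: KernelSpec, x, y, j: int, m: int) -> float:
    """m-th unmixed partial ``d^m k / d(x_j)^m`` of the RBF kernel.

    Uses the chain-rule recursion for ``exp(g(x))`` with the quadratic
    argument ``g = -gamma ||x - y||^2``: since ``g' = -2 gamma (x_j - y_j)``,
    ``g'' = -2 gamma`` and all higher derivatives of ``g`` vanish, the
    derivatives ``h_m = d^m exp(g) / dx_j^m`` satisfy

        h_m = g' h_{m-1} + (m - 1) g'' h_{m-2},   h_0 = k.
    """
    if spec.family != "rbf":
        raise ValueError("rbf_mth_partial is defined for the rbf family only")
    if m < 1:
        raise ValueError("derivative order m must be >= 1")
    x, y = _check_pair(spec, x, y)
    g = spec.gamma
    diff = x - y
    k = np.exp(-g * float(diff @ diff))
    gp = -2.0 * g * diff[j]  # g'
    gpp = -2.0 * g           # g''
    h_prev, h = k, gp * k    # h_0, h_1
    for order in range(2, m + 1):
        h_prev, h = h, gp * h + (order - 1) * gpp * h_prev
    return float(h if m >= 1 else h_prev)


# ---------------------------------------------------------------------------
# Gram builders (vectorised)
# ---------------------------------------------------------------------------

def gram_matrix(spec: KernelSpec, X, Y) -> np.ndarray:
    """Gram matrix ``[K]_il = k(X_i, Y_l)`` of shape (n, m)."""
    X, Y = _check_matrices(spec, X, Y)
    if spec.family == "linear":
        return X @ Y.T
    if spec.family == "poly":
        return (spec.gamma * (X @ Y.T) + spec.c0) ** spec.degree
    if spec.family == "rbf":
        return np.exp(-spec.gamma * cdist(X, Y, "sqeuclidean"))
    if spec.family == "tanh":
        return np.tanh(spec.gamma * (X @ Y.T) + spec.c0)
    # ard
    d2 = cdist(X / spec.lengthscales, Y / spec.lengthscales, "sqeuclidean")
    return spec.nu**2 * np.exp(-0.5 * d2)


def gram_gradient(spec: KernelSpec, Xeval, anchors) -> np.ndarray:
    """First-derivative tensor ``G[i, l, j] = d k(Xeval_i, anchors_l) / d x_j``.

    Shape (n_eval, n_anchor, d).  Contracting the anchor axis with a
    coefficient vector yields the gradient of the corresponding kernel
    expansion at every evaluation point.
    """
    X, A = _check_matrices(spec, Xeval, anchors)
    n, m, d = X.shape[0], A.shape[0], X.shape[1]
    if spec.family == "linear":
        return np.broadcast_to(A[None, :, :], (n, m, d)).copy()
    if spec.family == "poly":
        base = spec.gamma * (X @ A.T) + spec.c0
        return (spec.gamma * spec.degree * base ** (spec.degree - 1))[:, :, None] * A[None, :, :]
    if spec.family == "tanh":
        u = spec.gamma * (X @ A.T) + spec.c0
        sech2 = 1.0 / np.cosh(u) ** 2
        return (spec.gamma * sech2)[:, :, None] * A[None, :, :]
    diff = X[:, None, :] - A[None, :, :]
    K = gram_matrix(spec, X, A)
    if spec.family == "rbf":
        return -2.0 * spec.gamma * diff * K[:, :, None]
    # ard
    return -(diff / spec.lengthscales**2) * K[:, :, None]


def gram_second_partials(spec: KernelSpec, Xeval, anchors) -> np.ndarray:
    """Unmixed second-derivative tensor ``S[i, l, j] = d^2 k / d(x_j)^2``.

    Shape (n_eval, n_anchor, d); the per-feature slices stack into the
    second-derivative operator used for Laplacians and curvature norms.
    """
    X, A = _check_matrices(spec, Xeval, anchors)
    n, m, d = X.shape[0], A.shape[0], X.shape[1]
    if spec.family == "linear" or (spec.family == "poly" and spec.degree == 1):
        return np.zeros((n, m, d))
    if spec.family == "poly":
        p, g = spec.degree, spec.gamma
        base = g * (X @ A.T) + spec.c0
        return (p * (p - 1) * g**2 * base ** (p - 2))[:, :, None] * (A**2)[None, :, :]
    if spec.family == "tanh":
        u = spec.gamma * (X @ A.T) + spec.c0
        sech2 = 1.0 / np.cosh(u) ** 2
        return (-2.0 * spec.gamma**2 * sech2 * np.tanh(u))[:, :, None] * (A**2)[None, :, :]
    diff = X[:, None, :] - A[None, :, :]
    K = gram_matrix(spec, X, A)
    if spec.family == "rbf":
        g = spec.gamma
        return 2.0 * g * (2.0 * g * diff**2 - 1.0) * K[:, :, None]
    # ard
    ls2 = spec.lengthscales**2
    return ((diff / ls2) ** 2 - 1.0 / ls2) * K[:, :, None]


# ---------------------------------------------------------------------------
# default hyperparameters
# ---------------------------------------------------------------------------

def median_heuristic_gamma(X) -> float:
    """``gamma = 1 / (2 median^2)`` of the nonzero pairwise distances of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = cdist(X, X)
    vals = d[np.triu_indices_from(d, k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 1.0
    med = float(np.median(vals))
    return 1.0 / (2.0 * med**2)


def default_spec(family: str, X, **overrides) -> KernelSpec:
    """A KernelSpec with the package's default hyperparameters for data X.

    rbf: gamma from the median heuristic; poly: degree 2, c0 = 1, gamma = 1;
    ard: unit amplitude with per-feature standard-deviation lengthscales.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if family == "rbf":
        params = {"gamma": median_heuristic_gamma(X)}
    elif family == "poly":
        params = {"gamma": 1.0, "c0": 1.0, "degree": 2}
    elif family == "tanh":
        params = {"gamma": 1.0 / X.shape[1], "c0": 0.0}
    elif family == "ard":
        ls = np.std(X, axis=0)
        ls[ls == 0] = 1.0
        params = {"nu": 1.0, "lengthscales": ls}
    else:
        params = {}
    params.update(overrides)
    return KernelSpec(family=family, **params)
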