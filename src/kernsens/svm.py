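"""Binary SVM classification with a differentiable (tanh-masked) decision
function and its gradient decomposition.

The fitted decision function is the kernel expansion
``f(x) = sum_i y_i alpha_i k(x, x_i) + b``.  Replacing the sign mask by
``g = tanh`` makes the classifier differentiable, and the chain rule splits
its gradient into a scalar *mask factor* ``1 - tanh^2(f(x))`` (large only
near the decision boundary) times the *kernel part* ``dk*' (y o alpha)``.
Sensitivity maps of the two factors and of their product localise the
margin.

The dual quadratic program is solved by scikit-learn's SVC, called with
this package's Gram builder as the kernel; the resulting coefficients are
checked against the dual box and equality constraints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .expansion import (
    KernelExpansion,
    SensitivityReport,
    gradient,
    sensitivity_from_derivatives,
)
from .kernels import KernelSpec, default_spec, gram_matrix, median_heuristic_gamma


@dataclass
class SVMModel:
    """Fitted binary SVM: expansion coefficients are ``y_i alpha_i`` over
    the support vectors, with bias b."""

    expansion: KernelExpansion
    sv_labels: np.ndarray      # labels of the support vectors
    sv_alpha: np.ndarray       # Lagrange multipliers alpha_i >= 0 of the SVs
    C: float
    n_train: int

    @property
    def support_vectors(self) -> np.ndarray:
        return self.expansion.anchors

    def decision_value(self, X):
        return decision_value(self, X)

    def masked_value(self, X):
        return masked_value(self, X)

    def dual_feasibility(self, tol: float = 1e-6) -> dict:
        """Max violations of the dual constraints 0 <= alpha_i <= C and
        sum_i alpha_i y_i = 0."""
        box_low = float(np.max(-self.sv_alpha, initial=0.0))
        box_high = float(np.max(self.sv_alpha - self.C, initial=-self.C))
        eq = float(abs(np.sum(self.sv_alpha * self.sv_labels)))
        return {"box_low": box_low, "box_high": box_high, "equality": eq,
                "feasible": max(box_low, box_high) <= tol and eq <= tol}


def fit_svm(X, y, spec: Optional[KernelSpec] = None, C: float = 1.0,
            tol: float = 1e-6) -> SVMModel:
    """Fit a soft-margin binary SVM with labels in {-1, +1}."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).ravel().astype(int)
    classes = np.unique(y)
    if not np.array_equal(classes, [-1, 1]):
        raise ValueError(f"labels must contain both -1 and +1, got classes {classes}")
    if C <= 0:
        raise ValueError("C must be positive")
    if spec is None:
        spec = default_spec("rbf", X)

    clf = SVC(C=C, kernel=lambda A, B: gram_matrix(spec, A, B), tol=tol)
    clf.fit(X, y)
    sv = X[clf.support_]
    coef = clf.dual_coef_[0]              # y_i alpha_i
    sv_labels = y[clf.support_]
    exp = KernelExpansion(spec=spec, anchors=sv, alpha=coef, bias=float(clf.intercept_[0]))
    return SVMModel(expansion=exp, sv_labels=sv_labels, sv_alpha=coef * sv_labels,
                    C=float(C), n_train=X.shape[0])


def cv_fit_svm(X, y, C_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
               gamma_grid: Optional[Sequence[float]] = None, cv: int = 3,
               seed: int = 0) -> SVMModel:
    """Grid-search (C, gamma) of an RBF SVM by stratified k-fold
    cross-validation, then refit on all data with the best pair."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).ravel().astype(int)
    if gamma_grid is None:
        g0 = median_heuristic_gamma(X)
        gamma_grid = [g0 * f for f in (0.1, 0.3, 1.0, 3.0, 10.0)]
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    best, best_score = None, -np.inf
    for C in C_grid:
        for gamma in gamma_grid:
            score = cross_val_score(SVC(C=C, kernel="rbf", gamma=gamma),
                                    X, y, cv=splitter).mean()
            if score > best_score:
                best_score, best = score, (C, gamma)
    C, gamma = best
    return fit_svm(X, y, spec=KernelSpec(family="rbf", gamma=gamma), C=C)


# ---------------------------------------------------------------------------
# decision values and gradients
# ---------------------------------------------------------------------------

def decision_value(model: SVMModel, X):
    """Unmasked decision function f(x)."""
    return model.expansion(np.asarray(X, dtype=float))


def masked_value(model: SVMModel, X):
    """tanh-masked decision g(x) = tanh(f(x)), in (-1, 1); the predicted
    label is the sign of either form."""
    return np.tanh(decision_value(model, X))


def masked_gradient(model: SVMModel, x):
    """Chain-rule gradient of tanh(f) at a single point.

    Returns ``(full_gradient, mask_factor, kernel_part)`` with
    ``full_gradient = mask_factor * kernel_part``, where
    ``mask_factor = 1 - tanh^2(f(x))`` and ``kernel_part`` is the gradient
    of the unmasked expansion.
    """
    x = np.asarray(x, dtype=float).ravel()
    f = decision_value(model, x)
    mask = 1.0 - np.tanh(f) ** 2
    kpart = gradient(model.expansion, x)
    return mask * kpart, float(mask), kpart


def margin_sensitivity(model: SVMModel, Xeval):
    """Three sensitivity reports over an evaluation set: mask-only,
    kernel-only, and the composite tanh-masked gradient.

    The mask component is the scalar field ``1 - g^2(x)``, so its per-point
    sensitivity is that scalar squared; the composite per-point sensitivity
    equals the mask factor squared times the kernel-only one.
    """
    return margin_sensitivity_expansion(model.expansion, Xeval)


def margin_sensitivity_expansion(exp: KernelExpansion, Xeval):
    """Mask/kernel/composite sensitivity reports from a bare decision
    expansion (used when only the serialised expansion is at hand)."""
    Xeval = np.atleast_2d(np.asarray(Xeval, dtype=float))
    if Xeval.shape[0] == 0:
        raise ValueError("empty evaluation set")
    f = exp(Xeval)
    mask = 1.0 - np.tanh(f) ** 2                       # (n,)
    kgrad = gradient(exp, Xeval)                       # (n, d)
    mask_report = sensitivity_from_derivatives(mask[:, None], Xeval)
    kernel_report = sensitivity_from_derivatives(kgrad, Xeval)
    composite_report = sensitivity_from_derivatives(mask[:, None] * kgrad, Xeval)
    return mask_report, kernel_report, composite_report
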