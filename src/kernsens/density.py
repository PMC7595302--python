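"""Kernel density estimation and density-ridge (principal curve) extraction.

Two density estimators are provided as kernel expansions over a properly
normalised Gaussian bump:

* Parzen: equal weights 1/n on each sample.
* Eigendecomposition-restricted (KECA-style): the un-centred Gram matrix
  ``K = E D E'`` is truncated to r components, giving coefficients
  ``alpha = (1/n) E_r E_r' 1``.  Components are selected either by variance
  (top eigenvalues) or by their Renyi-entropy / information-potential
  contribution ``d_i (e_i' 1)^2``.  At r = n both reduce to Parzen exactly;
  for r < n the restricted estimate is an unnormalised approximation of the
  pdf (it need not integrate to one and may dip slightly negative).

The default bandwidth is Silverman's rule applied per dimension, realised
as an ARD (anisotropic Gaussian) kernel whose amplitude carries the pdf
normaliser ``(2 pi)^(-d/2) / prod_j lambda_j``; passing a scalar ``sigma``
selects the isotropic Gaussian instead.

Ridge points are evaluation points where the density gradient is (nearly)
orthogonal to the trailing Hessian eigenvectors: for a ``ridge_dim``-
dimensional ridge the score is ``||V' grad p(x)||`` with V the
``d - ridge_dim`` eigenvectors of the density Hessian with the smallest
(most negative) eigenvalues, and those eigenvalues must be negative for the
point to qualify.  A literal "top-r eigenvectors" projection is available
behind the ``eigvec_rule`` flag.  Retained points are ordered by Dijkstra
distance along a mutual k-NN graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import networkx as nx
import numpy as np
from sklearn.neighbors import NearestNeighbors

from .expansion import KernelExpansion, gradient, hessian, hessian_batch
from .kernels import KernelSpec, gram_matrix

Bandwidth = Union[float, np.ndarray]


def silverman_bandwidth(X) -> np.ndarray:
    """Silverman's rule of thumb per dimension:
    ``(4 / (d + 2))^(1/(d+4)) n^(-1/(d+4)) std_j``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    factor = (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))
    sd = np.std(X, axis=0, ddof=1) if n > 1 else np.ones(d)
    return factor * np.maximum(sd, 1e-12)


def _density_spec(sigma: Optional[Bandwidth], X) -> tuple[KernelSpec, np.ndarray]:
    """Kernel spec whose amplitude folds in the Gaussian pdf normaliser,
    so ``(1/n) sum_i k(x, x_i)`` is a proper density.  Returns the spec and
    the per-dimension bandwidth vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    if sigma is None:
        ls = silverman_bandwidth(X)
    else:
        ls = np.broadcast_to(np.asarray(sigma, dtype=float), (d,)).copy()
        if np.any(ls <= 0):
            raise ValueError("bandwidths must be positive")
    norm = (2.0 * np.pi) ** (-d / 2.0) / np.prod(ls)
    spec = KernelSpec(family="ard", nu=float(np.sqrt(norm)), lengthscales=ls)
    return spec, ls


@dataclass
class DensityModel:
    expansion: KernelExpansion
    mode: str                 # "parzen" | "keca"
    bandwidth: np.ndarray     # per-dimension bandwidths
    rank: int
    eigvecs: Optional[np.ndarray] = None  # (n, r)
    eigvals: Optional[np.ndarray] = None  # (r,)
    selection: str = "variance"

    def pdf(self, X):
        return self.expansion(np.asarray(X, dtype=float))

    def grad(self, X):
        return gradient(self.expansion, np.asarray(X, dtype=float))

    def hess(self, x):
        return hessian(self.expansion, x)


@dataclass
class RidgeResult:
    points: np.ndarray        # retained evaluation points
    indices: np.ndarray       # indices into the evaluation set
    scores: np.ndarray        # ridge scores of ALL evaluation points
    epsilon: float
    distances: np.ndarray     # Dijkstra distance per retained point
    components: np.ndarray    # connected-component label per retained point


def fit_parzen(X, sigma: Optional[Bandwidth] = None) -> DensityModel:
    """Parzen window estimate with a normalised Gaussian kernel.

    ``sigma`` may be a scalar or per-dimension vector; the default is
    Silverman's rule per dimension.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    spec, ls = _density_spec(sigma, X)
    exp = KernelExpansion(spec=spec, anchors=X, alpha=np.full(n, 1.0 / n))
    return DensityModel(expansion=exp, mode="parzen", bandwidth=ls, rank=n)


def fit_keca(X, sigma: Optional[Bandwidth] = None, r: Optional[int] = None,
             selection: str = "entropy") -> DensityModel:
    """Eigendecomposition-restricted density estimate.

    Decomposes the un-centred Gram matrix, keeps r components (by variance
    or by information-potential contribution ``d_i (e_i' 1)^2``), and sets
    ``alpha = (1/n) E_r E_r' 1``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if r is None:
        r = n
    if not 1 <= r <= n:
        raise ValueError(f"rank r={r} out of range [1, {n}]")
    if selection not in ("variance", "entropy"):
        raise ValueError("selection must be 'variance' or 'entropy'")
    spec, ls = _density_spec(sigma, X)
    K = gram_matrix(spec, X, X)
    evals, evecs = np.linalg.eigh(K)            # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]  # descending by eigenvalue
    if selection == "variance":
        keep = np.arange(r)
    else:
        contrib = evals * (evecs.T @ np.ones(n)) ** 2
        keep = np.argsort(contrib)[::-1][:r]
    Er, Dr = evecs[:, keep], evals[keep]
    alpha = (Er @ (Er.T @ np.ones(n))) / n
    exp = KernelExpansion(spec=spec, anchors=X, alpha=alpha)
    return DensityModel(expansion=exp, mode="keca", bandwidth=ls, rank=int(r),
                        eigvecs=Er, eigvals=Dr, selection=selection)


def entropy_contributions(model: DensityModel) -> np.ndarray:
    """Information-potential contribution ``d_i (e_i' 1)^2`` of the kept
    components of a KECA model."""
    if model.eigvecs is None:
        raise ValueError("model has no stored eigendecomposition")
    ones = np.ones(model.eigvecs.shape[0])
    return model.eigvals * (model.eigvecs.T @ ones) ** 2


# ---------------------------------------------------------------------------
# ridge extraction
# ---------------------------------------------------------------------------

def _ridge_scores(model: DensityModel, Xeval: np.ndarray, ridge_dim: int,
                  eigvec_rule: str):
    """Vectorised ridge scores: returns ``(scores, used_eigvals)`` with the
    used eigenvalues per point in a (n, d - ridge_dim or ridge_dim) array."""
    d = Xeval.shape[1]
    if not 1 <= ridge_dim < d:
        raise ValueError(f"ridge_dim must be in [1, {d - 1}]")
    if eigvec_rule == "smallest":
        sel = slice(0, d - ridge_dim)
    elif eigvec_rule == "top":
        sel = slice(d - ridge_dim, d)
    else:
        raise ValueError("eigvec_rule must be 'smallest' or 'top'")
    G = gradient(model.expansion, Xeval)            # (n, d)
    H = hessian_batch(model.expansion, Xeval)       # (n, d, d)
    w, V = np.linalg.eigh(H)                        # ascending eigenvalues
    proj = np.einsum("nd,nde->ne", G, V[:, :, sel])
    return np.linalg.norm(proj, axis=1), w[:, sel]


def ridge_score(model: DensityModel, x, ridge_dim: int = 1,
                eigvec_rule: str = "smallest"):
    """Orthogonality score of a candidate ridge point.

    Eigendecomposes the density Hessian at x and projects the density
    gradient onto the selected eigenvectors: with ``eigvec_rule='smallest'``
    (default, the density-ridge convention) the ``d - ridge_dim``
    eigenvectors with the smallest eigenvalues; with ``'top'`` the literal
    top-``ridge_dim`` eigenvectors.  Returns ``(score, used_eigenvalues)``;
    the score is the Euclidean norm of the projection and is zero at local
    maxima and on exact ridges.
    """
    x = np.asarray(x, dtype=float).ravel()
    scores, w_used = _ridge_scores(model, x[None, :], ridge_dim, eigvec_rule)
    return float(scores[0]), w_used[0]


def extract_ridge(model: DensityModel, Xeval, ridge_dim: int = 1,
                  epsilon: Optional[float] = None, eigvec_rule: str = "smallest",
                  require_negative: bool = True,
                  min_density: Union[str, float, None] = "median",
                  knn: int = 5) -> RidgeResult:
    """Retain the evaluation points that lie (approximately) on the density
    ridge, and order them by Dijkstra distance along the curve.

    A point is a ridge *candidate* if (i) the projected Hessian eigenvalues
    are negative (``require_negative``, default on, excluding valleys and
    saddles) and (ii) its estimated density is at least ``min_density``
    (default: the median of the density over the evaluation set; pass a
    number for an absolute threshold or ``None`` to disable).  The density
    floor matters because the orthogonality condition is also satisfied on
    low-density artefacts — isolated kernel bumps and the weakly-curved
    minor axes of elongated clouds — which a local score cannot tell apart
    from the main ridge.  Among candidates, points with score at most
    ``epsilon`` are retained; ``epsilon`` defaults to the 5th percentile of
    the candidate scores.
    """
    Xeval = np.atleast_2d(np.asarray(Xeval, dtype=float))
    scores, w_used = _ridge_scores(model, Xeval, ridge_dim, eigvec_rule)
    qualifies = np.all(w_used < 0, axis=1) if require_negative else np.ones(len(scores), bool)
    if min_density is not None:
        p = model.pdf(Xeval)
        floor = float(np.median(p)) if min_density == "median" else float(min_density)
        qualifies &= p >= floor
    if not np.any(qualifies):
        warnings.warn("no evaluation point passed the ridge candidacy filters")
        return RidgeResult(Xeval[:0], np.empty(0, dtype=int), scores,
                           float(epsilon or np.nan), np.empty(0), np.empty(0, dtype=int))
    if epsilon is None:
        epsilon = float(np.percentile(scores[qualifies], 5.0))
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    retained = np.flatnonzero((scores <= epsilon) & qualifies)
    if retained.size == 0:
        warnings.warn("no evaluation point passed the ridge criterion")
        return RidgeResult(Xeval[:0], retained, scores, float(epsilon),
                           np.empty(0), np.empty(0, dtype=int))
    dist, comp = order_curve(Xeval[retained], k=knn)
    return RidgeResult(Xeval[retained], retained, scores, float(epsilon), dist, comp)


def order_curve(points, k: int = 5):
    """Dijkstra ordering of curve points.

    Builds a mutual k-NN graph with Euclidean edge weights; within each
    connected component, distances are measured from an endpoint (the node
    of maximal weighted eccentricity).  Returns ``(distances, component_labels)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n == 0:
        raise ValueError("order_curve requires at least one point")
    if n == 1:
        return np.zeros(1), np.zeros(1, dtype=int)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(points)
    dmat, idx = nn.kneighbors(points)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    neigh_sets = [set(idx[i, 1:]) for i in range(n)]
    for i in range(n):
        for pos, j in enumerate(idx[i, 1:], start=1):
            if i in neigh_sets[j]:  # mutual neighbours
                G.add_edge(i, int(j), weight=float(dmat[i, pos]))
    distances = np.zeros(n)
    components = np.zeros(n, dtype=int)
    for label, comp in enumerate(nx.connected_components(G)):
        nodes = sorted(comp)
        components[nodes] = label
        if len(nodes) == 1:
            continue
        ecc = {}
        for u in nodes:
            lengths = nx.single_source_dijkstra_path_length(G, u, weight="weight")
            ecc[u] = max(lengths[v] for v in nodes)
        start = max(nodes, key=lambda u: ecc[u])
        lengths = nx.single_source_dijkstra_path_length(G, start, weight="weight")
        for v in nodes:
            distances[v] = lengths[v]
    return distances, components
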