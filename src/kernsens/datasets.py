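"""Seeded synthetic generators for every toy problem used in the examples
and tests: 1-D regression at controlled SNR, 2-D classification toys, 2-D
manifold density toys, paired dependence toys, and a piecewise-linear
two-input regression surface.

All randomness flows through a ``numpy.random.Generator`` created from the
``seed`` argument; a fixed seed yields bit-identical arrays.
"""

from __future__ import annotations

import numpy as np
from sklearn.datasets import make_circles, make_moons

REGRESSION_NAMES = ("sin3pix", "sinc", "composite")
CLASSIFICATION_NAMES = ("moons", "circles", "ellipsoids")
DENSITY_NAMES = ("arc", "ring", "blobs")
DEPENDENCE_NAMES = ("line_clusters", "noisy_ring", "near_independent", "sinusoid")


def _clean_regression(name: str, x: np.ndarray) -> np.ndarray:
    if name == "sin3pix":
        return np.sin(3.0 * np.pi * x)
    if name == "sinc":
        return np.sinc(4.0 * (x - 0.5))
    if name == "composite":
        return np.sin(2.0 * np.pi * x) + 0.5 * np.sign(x - 0.5)
    raise ValueError(f"unknown regression toy {name!r}; choose from {REGRESSION_NAMES}")


def regression_1d(name: str, n: int = 100, snr_db: float = 20.0, seed: int = 0,
                  rng: np.random.Generator | None = None):
    """1-D regression toy with additive white Gaussian noise at a target SNR.

    The noise variance is set from the empirical variance of the clean
    signal so that ``10 log10(var(clean)/var(noise)) = snr_db``.

    Returns ``(x, y_noisy, y_clean)``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    x = np.sort(rng.uniform(0.0, 1.0, size=n))
    clean = _clean_regression(name, x)
    if np.isinf(snr_db):
        return x, clean.copy(), clean
    sig_var = float(np.var(clean))
    noise_var = sig_var / 10.0 ** (snr_db / 10.0)
    y = clean + np.sqrt(noise_var) * rng.standard_normal(n)
    return x, y, clean


def classification_2d(name: str, n: int = 200, noise: float = 0.1, seed: int = 0):
    """Balanced two-class 2-D toys with labels in {-1, +1}.

    ``moons`` and ``circles`` follow the usual interleaving half-moons and
    concentric-circles constructions; ``ellipsoids`` draws two overlapping
    anisotropic Gaussian clouds.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if name == "moons":
        X, y01 = make_moons(n_samples=n, noise=noise, random_state=seed)
    elif name == "circles":
        X, y01 = make_circles(n_samples=n, noise=noise, factor=0.5, random_state=seed)
    elif name == "ellipsoids":
        rng = np.random.default_rng(seed)
        n1 = n // 2
        n2 = n - n1
        cov1 = np.array([[2.0, 0.0], [0.0, 0.3]])
        cov2 = np.array([[0.3, 0.0], [0.0, 2.0]])
        a = rng.multivariate_normal([-0.7, 0.0], cov1 * max(noise, 1e-12) * 10, size=n1)
        b = rng.multivariate_normal([0.7, 0.0], cov2 * max(noise, 1e-12) * 10, size=n2)
        X = np.vstack([a, b])
        y01 = np.r_[np.zeros(n1), np.ones(n2)].astype(int)
        perm = rng.permutation(n)
        X, y01 = X[perm], y01[perm]
    else:
        raise ValueError(f"unknown classification toy {name!r}; choose from {CLASSIFICATION_NAMES}")
    return X, 2 * y01 - 1


def density_2d(name: str, n: int = 500, noise: float = 0.1, seed: int = 0,
               radius: float = 1.0):
    """2-D manifold density toys: full noisy ring, half-ring arc, Gaussian blobs."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if name == "ring":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    elif name == "arc":
        theta = rng.uniform(0.0, np.pi, size=n)
    elif name == "blobs":
        centers = np.array([[-1.5, 0.0], [0.0, 1.5], [1.5, 0.0]])
        idx = rng.integers(0, len(centers), size=n)
        return centers[idx] + noise * rng.standard_normal((n, 2))
    else:
        raise ValueError(f"unknown density toy {name!r}; choose from {DENSITY_NAMES}")
    r = radius + noise * rng.standard_normal(n)
    return np.c_[r * np.cos(theta), r * np.sin(theta)]


def dependence_pair(name: str, n: int = 200, noise: float = 0.1, seed: int = 0):
    """Paired 1-D samples with controlled association, for dependence
    estimation: clusters along the 1-1 line, a noisy ring, (near)
    independent draws, and a sinusoid y = sin(omega x) + noise."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if name == "line_clusters":
        centers = rng.choice([-1.0, 0.0, 1.0], size=n)
        x = centers + noise * rng.standard_normal(n)
        y = centers + noise * rng.standard_normal(n)
    elif name == "noisy_ring":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        r = 1.0 + noise * rng.standard_normal(n)
        x, y = r * np.cos(theta), r * np.sin(theta)
    elif name == "near_independent":
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
    elif name == "sinusoid":
        x = rng.uniform(0.0, 2.0 * np.pi, size=n)
        y = np.sin(2.0 * x) + noise * rng.standard_normal(n)
    else:
        raise ValueError(f"unknown dependence toy {name!r}; choose from {DEPENDENCE_NAMES}")
    return x, y


def piecewise_linear_surface(n: int = 500, seed: int = 0, noise: float = 0.0):
    """Two-input piecewise-linear surface y = a(x1) x1 + b(x2) x2.

    Inputs are uniform on [-20, 20]^2; the x1 slope is 5 on x1 > 0 and 1 on
    x1 <= 0, while the x2 slope is 1 everywhere.  The function is continuous
    at the origin and its squared-slope ratio on the positive quadrant is
    (5/1)^2 = 25, which a feature-sensitivity analysis should recover.

    Returns ``(X, y_noisy, y_clean)``.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(-20.0, 20.0, size=(n, 2))
    a = np.where(X[:, 0] > 0, 5.0, 1.0)
    clean = a * X[:, 0] + 1.0 * X[:, 1]
    y = clean + noise * rng.standard_normal(n) if noise > 0 else clean.copy()
    return X, y, clean
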