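"""Kernel values, analytic derivatives, and their finite-difference and
symbolic oracles."""

import numpy as np
import pytest

from kernsens import (
    KernelSpec,
    default_spec,
    gram_gradient,
    gram_matrix,
    kernel_gradient,
    kernel_hessian,
    kernel_value,
    median_heuristic_gamma,
    numeric_gradient,
    numeric_hessian,
    rbf_mth_partial,
)


def test_kernel_values_closed_forms():
    assert kernel_value(KernelSpec("linear"), [1, 2], [3, 4]) == pytest.approx(11.0)
    assert kernel_value(KernelSpec("rbf", gamma=3.7), [0.3, -1], [0.3, -1]) == pytest.approx(1.0)
    assert kernel_value(KernelSpec("poly", gamma=1, c0=1, degree=2), [1, 0], [1, 0]) == pytest.approx(4.0)


def test_kernel_value_symmetric_in_arguments(family_spec, rng):
    for _ in range(20):
        x, y = rng.uniform(-2, 2, 5), rng.uniform(-2, 2, 5)
        assert kernel_value(family_spec, x, y) == pytest.approx(
            kernel_value(family_spec, y, x), rel=1e-12)


def test_dimension_mismatch_and_bad_family_raise():
    with pytest.raises(ValueError):
        kernel_value(KernelSpec("linear"), [1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        KernelSpec("matern")
    with pytest.raises(ValueError):
        kernel_value(KernelSpec("rbf", gamma=1.0), [np.nan, 0], [0, 0])
    with pytest.raises(ValueError):
        KernelSpec("rbf", gamma=-1.0)


def test_gradient_matches_finite_differences(family_spec, rng):
    """Analytic gradient vs central differences, 200 random pairs in d=5."""
    worst = 0.0
    for _ in range(200):
        x, y = rng.uniform(-2, 2, 5), rng.uniform(-2, 2, 5)
        g = kernel_gradient(family_spec, x, y)
        gn = numeric_gradient(lambda z: kernel_value(family_spec, z, y), x)
        denom = max(1.0, float(np.max(np.abs(gn))))
        worst = max(worst, float(np.max(np.abs(g - gn))) / denom)
    assert worst < 1e-5


def test_hessian_matches_finite_differences(family_spec, rng):
    worst = 0.0
    for _ in range(50):
        x, y = rng.uniform(-2, 2, 5), rng.uniform(-2, 2, 5)
        H = kernel_hessian(family_spec, x, y)
        Hn = numeric_hessian(lambda z: kernel_value(family_spec, z, y), x)
        worst = max(worst, float(np.max(np.abs(H - Hn))))
        assert np.array_equal(H, H.T)  # exact symmetry by construction
    assert worst < 1e-4


def test_linear_kernel_derivatives_closed_form(rng):
    spec = KernelSpec("linear")
    x, y = rng.normal(size=4), rng.normal(size=4)
    assert np.allclose(kernel_gradient(spec, x, y), y)
    assert np.array_equal(kernel_hessian(spec, x, y), np.zeros((4, 4)))


def test_rbf_closed_form_values():
    spec = KernelSpec("rbf", gamma=0.5)
    # d/dx exp(-0.5 (x-y)^2) at x=1, y=0 is -exp(-0.5)
    assert kernel_gradient(spec, [1.0], [0.0])[0] == pytest.approx(-np.exp(-0.5), rel=1e-10)
    assert np.allclose(kernel_gradient(spec, [0.3, 0.7], [0.3, 0.7]), 0.0)
    H = kernel_hessian(spec, [0.2, -1.0], [0.2, -1.0])
    assert np.allclose(np.diag(H), -2 * 0.5)
    assert H[0, 1] == 0.0


def test_stationary_antisymmetry_and_translation_invariance(rng):
    """rbf/ard gradients flip sign when arguments swap, and values and
    derivatives are unchanged under joint translation."""
    for family in ("rbf", "ard"):
        spec = default_spec(family, rng.normal(size=(30, 4)))
        for _ in range(20):
            x, y, t = rng.normal(size=4), rng.normal(size=4), rng.normal(size=4)
            g_xy = kernel_gradient(spec, x, y)
            g_yx = kernel_gradient(spec, y, x)
            assert np.allclose(g_xy, -g_yx, atol=1e-12)
            assert kernel_value(spec, x + t, y + t) == pytest.approx(
                kernel_value(spec, x, y), abs=1e-12)
            assert np.allclose(kernel_gradient(spec, x + t, y + t), g_xy, atol=1e-12)
            assert np.allclose(kernel_hessian(spec, x + t, y + t),
                               kernel_hessian(spec, x, y), atol=1e-12)


def test_ard_derivative_signs_follow_calculus(rng):
    """The ARD gradient carries the minus sign obtained by differentiating
    the kernel, and the unmixed second partial is ((dx/l^2)^2 - 1/l^2) k."""
    ls = np.array([0.7, 1.3])
    spec = KernelSpec("ard", nu=1.5, lengthscales=ls)
    x, y = np.array([0.4, -0.2]), np.array([-0.1, 0.5])
    k = kernel_value(spec, x, y)
    expected = -((x - y) / ls**2) * k
    assert np.allclose(kernel_gradient(spec, x, y), expected, atol=1e-14)
    H = kernel_hessian(spec, x, y)
    for j in range(2):
        assert H[j, j] == pytest.approx((((x[j] - y[j]) ** 2) / ls[j] ** 4 - 1 / ls[j] ** 2) * k)
    gn = numeric_gradient(lambda z: kernel_value(spec, z, y), x)
    assert np.allclose(kernel_gradient(spec, x, y), gn, atol=1e-7)


class TestHigherOrderRbf:
    spec = KernelSpec("rbf", gamma=1.0)

    def test_orders_one_two_match_closed_forms(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=3), rng.normal(size=3)
            for j in range(3):
                assert rbf_mth_partial(self.spec, x, y, j, 1) == pytest.approx(
                    kernel_gradient(self.spec, x, y)[j], abs=1e-12)
                assert rbf_mth_partial(self.spec, x, y, j, 2) == pytest.approx(
                    kernel_hessian(self.spec, x, y)[j, j], abs=1e-12)

    @pytest.mark.parametrize("m", [3, 4])
    def test_orders_three_four_match_symbolic_oracle(self, m):
        sympy = pytest.importorskip("sympy")
        xs, ys = sympy.symbols("x y")
        expr = sympy.exp(-((xs - ys) ** 2))
        dm = sympy.lambdify((xs, ys), sympy.diff(expr, xs, m))
        for xv in (0.7, -0.3, 1.9):
            got = rbf_mth_partial(self.spec, [xv], [0.0], 0, m)
            want = float(dm(xv, 0.0))
            assert got == pytest.approx(want, rel=1e-8)

    def test_rejects_wrong_family_and_order(self):
        with pytest.raises(ValueError):
            rbf_mth_partial(KernelSpec("linear"), [1.0], [0.0], 0, 2)
        with pytest.raises(ValueError):
            rbf_mth_partial(self.spec, [1.0], [0.0], 0, 0)


class TestGram:
    def test_single_point_and_rbf_diagonal(self, rng):
        spec = KernelSpec("rbf", gamma=2.0)
        x = rng.normal(size=(1, 3))
        assert gram_matrix(spec, x, x).shape == (1, 1)
        assert gram_matrix(spec, x, x)[0, 0] == pytest.approx(1.0)
        X = rng.normal(size=(20, 3))
        assert np.allclose(np.diag(gram_matrix(spec, X, X)), 1.0)

    def test_psd_on_random_points(self, rng):
        X = rng.normal(size=(50, 4))
        for family in ("linear", "poly", "rbf", "ard"):
            spec = default_spec(family, X)
            K = gram_matrix(spec, X, X)
            assert np.allclose(K, K.T, atol=1e-12)
            assert np.linalg.eigvalsh(K).min() >= -1e-8 * np.trace(K) / 50

    def test_gram_matches_pairwise_values(self, family_spec, rng):
        X, Y = rng.uniform(-2, 2, (6, 5)), rng.uniform(-2, 2, (4, 5))
        K = gram_matrix(family_spec, X, Y)
        loop = [[kernel_value(family_spec, x, y) for y in Y] for x in X]
        assert np.allclose(K, loop, atol=1e-12)

    def test_gram_gradient_matches_pairwise_gradients(self, family_spec, rng):
        X, Y = rng.uniform(-2, 2, (5, 5)), rng.uniform(-2, 2, (7, 5))
        G = gram_gradient(family_spec, X, Y)
        assert G.shape == (5, 7, 5)
        for i, x in enumerate(X):
            for l, y in enumerate(Y):
                assert np.allclose(G[i, l], kernel_gradient(family_spec, x, y), atol=1e-12)

    def test_gram_gradient_linear_is_anchor_constant(self, rng):
        A = rng.normal(size=(6, 3))
        G = gram_gradient(KernelSpec("linear"), rng.normal(size=(4, 3)), A)
        for i in range(4):
            assert np.array_equal(G[i], A)

    def test_gram_gradient_rbf_zero_fibres_at_anchors(self, rng):
        X = rng.normal(size=(8, 2))
        G = gram_gradient(KernelSpec("rbf", gamma=1.3), X, X)
        for i in range(8):
            assert np.allclose(G[i, i], 0.0)


def test_median_heuristic_and_sigma_mapping(rng):
    X = rng.normal(size=(100, 2))
    gamma = median_heuristic_gamma(X)
    assert gamma > 0
    spec = KernelSpec.rbf_from_sigma(2.0)
    assert spec.gamma == pytest.approx(1.0 / 8.0)
    assert spec.sigma == pytest.approx(2.0)


def test_spec_yaml_roundtrip_accepts_sigma_spelling():
    spec = KernelSpec.from_dict({"family": "rbf", "sigma": 2.0})
    assert spec.gamma == pytest.approx(0.125)
    d = KernelSpec("ard", nu=1.2, lengthscales=np.array([1.0, 2.0])).to_dict()
    back = KernelSpec.from_dict(d)
    assert back.nu == 1.2 and np.allclose(back.lengthscales, [1.0, 2.0])
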