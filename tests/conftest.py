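import numpy as np
import pytest

from kernsens import KernelSpec, default_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["linear", "poly", "rbf", "tanh", "ard"])
def family_spec(request, rng):
    """One spec per kernel family with sensible hyperparameters for d=5."""
    X = rng.uniform(-2, 2, size=(40, 5))
    return default_spec(request.param, X)


def random_expansion(rng, family="rbf", n=10, d=3, bias=0.0):
    from kernsens import KernelExpansion

    anchors = rng.normal(size=(n, d))
    spec = default_spec(family, anchors)
    return KernelExpansion(spec=spec, anchors=anchors,
                           alpha=rng.normal(size=n), bias=bias)
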