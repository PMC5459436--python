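import numpy as np
import pytest

from porecall import NetworkParams, SimConfig, build_pore_model


@pytest.fixture(scope="session")
def pore_model_k3():
    return build_pore_model(3, seed=11)


@pytest.fixture(scope="session")
def pore_model_k6():
    return build_pore_model(6, seed=11)


@pytest.fixture
def noiseless_cfg():
    return SimConfig(k=3, seed=5).noiseless()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_net(rng):
    """A 2-layer bidirectional net with non-trivial weights."""
    p = NetworkParams.init_random(3, [4, 3], rng)
    flat = p.pack()
    p.unpack_(flat + rng.normal(0, 0.3, flat.size))
    return p


def random_dists(n, rng, peaked=False):
    """Random normalised dual output distributions of length n."""
    from porecall import OutputDistributions

    a = rng.exponential(1.0, size=(n, 5))
    b = rng.exponential(1.0, size=(n, 5))
    if peaked:
        a[np.arange(n), rng.integers(0, 5, n)] += 20
        b[np.arange(n), rng.integers(0, 5, n)] += 20
    return OutputDistributions(p1=a / a.sum(1, keepdims=True),
                               p2=b / b.sum(1, keepdims=True))
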