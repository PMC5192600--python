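import numpy as np
import pytest

from plsnet import as_gold_standard, generate_network, simulate_expression


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_benchmark():
    """A 10-gene synthetic bundle shared by inference and CLI tests."""
    net = generate_network(p=10, avg_out_degree=2, seed=7)
    expr = simulate_expression(net, n_conditions=80)
    return net, expr, as_gold_standard(net)


def centered_instance(rng, n, p):
    """Random centered design and response."""
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X - X.mean(axis=0), y - y.mean()
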