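"""Shared fixtures: analytic model fixtures and the (expensive) trained
benchmark, built once per session and only when a test asks for it."""

from __future__ import annotations

import numpy as np
import pytest

import dfim
from dfim.models import SequenceModel


class ProductModel(SequenceModel):
    """Y = X[A, 0] * X[A, 1]: the smallest genuinely interacting network.

    Its gradients follow the product rule, so every interaction score
    has a short hand computation.
    """

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            return float(x[0, 0] * x[0, 1])
        return x[:, 0, 0] * x[:, 0, 1]

    def input_gradient(self, x):
        x = np.asarray(x, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        g = np.zeros_like(x)
        g[:, 0, 0] = x[:, 0, 1]
        g[:, 0, 1] = x[:, 0, 0]
        return g[0] if single else g


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def product_model():
    return ProductModel()


@pytest.fixture
def linear_model(rng):
    return dfim.wrap_linear_model(rng.normal(size=(4, 30)), bias=0.5)


@pytest.fixture
def random_sequence(rng):
    return "".join(rng.choice(list("ACGT"), size=30))


def random_conv_model(rng, seq_length=30):
    """Small randomly initialized CNN: nonlinear but cheap."""
    return dfim.ConvNet(
        seq_length, n_filters=4, filter_width=5, n_hidden=6, pooling="lse", rng=rng
    )


@pytest.fixture(scope="session")
def benchmark_run():
    """Scaled benchmark: simulate, train, score motif pairs, test.

    Session-scoped because training takes about a minute; every value
    derived from it in the tests comes from this single run (seed 1).
    """
    config = dfim.BenchmarkConfig(n_per_set=2000, seed=1)
    dataset = dfim.simulate_benchmark(config)
    model, history = dfim.train_benchmark_cnn(dataset, seed=1)
    return {"config": config, "dataset": dataset, "model": model, "history": history}
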