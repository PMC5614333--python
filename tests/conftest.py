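import numpy as np
import pytest

from wormcode import DiscreteChannel, WormRecord


def make_channel(P, states=None, shape=None):
    P = np.asarray(P, dtype=float)
    states = tuple(states) if states is not None else tuple(f"f{i}" for i in range(P.shape[0]))
    return DiscreteChannel(states=states, P=P, shape=shape)


def random_channel(rng, F, M, shape=None):
    """Row-stochastic F x M matrix with strictly positive entries."""
    P = rng.gamma(1.0, 1.0, size=(F, M)) + 1e-6
    return make_channel(P / P.sum(axis=1, keepdims=True), shape=shape)


def make_records(values, condition="f0", genotype="N2", batch="b1"):
    """WormRecords from an (n, D) array of response vectors."""
    values = np.atleast_2d(values)
    return [
        WormRecord(batch=batch, worm=f"w{i:04d}", genotype=genotype,
                   condition=condition, g=tuple(row))
        for i, row in enumerate(values)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
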