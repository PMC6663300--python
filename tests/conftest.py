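import numpy as np
import pytest

from mtenet import GroundTruthNetwork, TimeSeriesData


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_net(n, links, beta=0.5):
    """Hand-built ground truth: links as (source, target, lag, weight)."""
    adjacency = np.zeros((n, n), dtype=bool)
    lags = np.zeros((n, n), dtype=int)
    weights = np.zeros((n, n))
    for s, t, lag, w in links:
        adjacency[s, t] = True
        lags[s, t] = lag
        weights[s, t] = w
    return GroundTruthNetwork(
        adjacency=adjacency,
        lags=lags,
        weights=weights,
        beta=np.full(n, beta, dtype=float),
    )


@pytest.fixture
def two_node_lag2_net():
    """X (process 0) drives Y (process 1) at lag 2 with coupling 0.4."""
    return make_net(2, [(0, 1, 2, 0.4)])


@pytest.fixture
def white_noise():
    def _make(t, n, seed=0, r=1):
        g = np.random.default_rng(seed)
        return TimeSeriesData(g.standard_normal((t, n, r)))

    return _make
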