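"""Ground-truth networks and synthetic dynamics for validation.

Structural networks are sparse directed Erdős–Rényi graphs.  Each link
carries a single random interaction lag in {1..5} and a cross-coupling
weight; weights into each target are uniform and normalized so that they
sum to 0.4, and every node has self-coupling beta = 0.5 at lag 1.  Two
dynamics run on these networks:

* a vector autoregressive (VAR) process,
  ``Y_t = beta * Y_{t-1} + sum_X alpha_X * X_{t-l_X} + eta_t``,
  with i.i.d. Gaussian noise (mean 0, sd 0.1, uncorrelated across nodes);
  stable and stationary Gaussian whenever the companion-matrix spectral
  radius is below one;
* a coupled logistic maps (CLM) process, which feeds the same weighted
  input ``a_t`` through the fully chaotic logistic map r = 4 and wraps the
  noisy output into [0, 1):
  ``Y_t = (4 a_t (1 - a_t) + eta_t) mod 1``.

Self-dynamics live exclusively in beta; Erdős–Rényi links are sampled over
off-diagonal ordered pairs only, so at p = 3/N the expected in-degree is
3 (N-1)/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import TimeSeriesData

__all__ = [
    "GroundTruthNetwork",
    "NoiseSpec",
    "erdos_renyi_digraph",
    "assign_couplings",
    "generate_network",
    "companion_spectral_radius",
    "simulate_var",
    "simulate_clm",
]

DEFAULT_BETA = 0.5
DEFAULT_TOTAL_CROSS = 0.4
DEFAULT_LAG_RANGE = (1, 2, 3, 4, 5)

# reject radii this close to the unit circle instead of silently resampling
_STABILITY_LIMIT = 0.999


@dataclass(frozen=True)
class NoiseSpec:
    """Innovation noise: i.i.d. Gaussian, uncorrelated across processes."""

    mean: float = 0.0
    sd: float = 0.1

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("noise sd must be positive")


@dataclass
class GroundTruthNetwork:
    """Directed structural network with per-link lags and weights.

    ``adjacency[s, t]`` is True when source s drives target t; ``lags``
    and ``weights`` are aligned with it (zero where no link).  ``beta``
    holds each node's lag-1 self-coupling, which is not a link.
    """

    adjacency: np.ndarray
    lags: np.ndarray
    weights: np.ndarray
    beta: np.ndarray
    link_probability: float | None = None

    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        self.n = self.adjacency.shape[0]
        if self.adjacency.shape != (self.n, self.n):
            raise ValueError("adjacency must be square")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-links are not allowed; use beta")
        self.lags = np.asarray(self.lags, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.lags[self.adjacency] < 1):
            raise ValueError("every link needs a lag >= 1")

    @property
    def max_lag(self) -> int:
        lags = self.lags[self.adjacency]
        return max(1, int(lags.max()) if lags.size else 1)

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    def coefficient_matrices(self) -> np.ndarray:
        """Lagged coefficient stack A of shape (L, N, N), Y_t = sum A_l @ Y_{t-l}.

        ``A[l-1][target, source]``; beta sits on the diagonal of the lag-1
        slice.
        """
        L = self.max_lag
        A = np.zeros((L, self.n, self.n))
        A[0][np.diag_indices(self.n)] = self.beta
        srcs, tgts = np.nonzero(self.adjacency)
        for s, t in zip(srcs, tgts):
            A[self.lags[s, t] - 1, t, s] += self.weights[s, t]
        return A


def erdos_renyi_digraph(n: int, p: float, seed: int | None = None) -> np.ndarray:
    """Directed G(n, p) adjacency over off-diagonal ordered pairs.

    Returns a boolean matrix with ``adj[s, t]`` indicating a link s -> t.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"link probability must be in [0, 1], got {p}")
    g = nx.gnp_random_graph(n, p, seed=seed, directed=True)
    adj = nx.to_numpy_array(g, nodelist=range(n), dtype=bool)
    np.fill_diagonal(adj, False)
    return adj


def assign_couplings(
    adjacency: np.ndarray,
    beta: float = DEFAULT_BETA,
    total_cross: float = DEFAULT_TOTAL_CROSS,
    lag_range=DEFAULT_LAG_RANGE,
    seed: int | None = None,
    link_probability: float | None = None,
) -> GroundTruthNetwork:
    """Attach lags and weights to an adjacency matrix.

    Each link draws one lag uniformly from ``lag_range``; weights into a
    target with d >= 1 parents are all ``total_cross / d`` so that they sum
    to ``total_cross``; every node gets self-coupling ``beta``.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    n = adjacency.shape[0]
    rng = np.random.default_rng(seed)
    lags = np.zeros((n, n), dtype=int)
    weights = np.zeros((n, n))
    lag_range = np.asarray(list(lag_range), dtype=int)
    for t in range(n):
        parents = np.nonzero(adjacency[:, t])[0]
        if parents.size == 0:
            continue
        lags[parents, t] = rng.choice(lag_range, size=parents.size)
        weights[parents, t] = total_cross / parents.size
    return GroundTruthNetwork(
        adjacency=adjacency,
        lags=lags,
        weights=weights,
        beta=np.full(n, beta),
        link_probability=link_probability,
    )


def generate_network(
    n: int,
    p: float | None = None,
    seed: int | None = None,
    beta: float = DEFAULT_BETA,
    total_cross: float = DEFAULT_TOTAL_CROSS,
    lag_range=DEFAULT_LAG_RANGE,
) -> GroundTruthNetwork:
    """Random ground truth: ER digraph (default p = 3/N) plus couplings."""
    if p is None:
        p = 3.0 / n
    ss = np.random.SeedSequence(seed)
    graph_seed, coupling_seed = (int(s) for s in ss.generate_state(2) >> 1)
    adj = erdos_renyi_digraph(n, p, seed=graph_seed)
    return assign_couplings(
        adj,
        beta=beta,
        total_cross=total_cross,
        lag_range=lag_range,
        seed=coupling_seed,
        link_probability=p,
    )


def companion_spectral_radius(net: GroundTruthNetwork) -> float:
    """Spectral radius of the NL x NL companion matrix of the VAR system.

    A radius below one certifies stability (and hence stationarity) of the
    linear dynamics.
    """
    A = net.coefficient_matrices()
    L, n = A.shape[0], net.n
    companion = np.zeros((n * L, n * L))
    companion[:n] = np.concatenate(list(A), axis=1)
    if L > 1:
        companion[n:, : n * (L - 1)] = np.eye(n * (L - 1))
    return float(np.abs(np.linalg.eigvals(companion)).max())


def _simulate(
    net: GroundTruthNetwork,
    t: int,
    r: int,
    noise: NoiseSpec,
    seed,
    burn_in: int,
    kind: str,
) -> TimeSeriesData:
    rng = np.random.default_rng(seed)
    A = net.coefficient_matrices()
    L, n = A.shape[0], net.n
    total = t + burn_in
    out = np.empty((t, n, r))
    for rep in range(r):
        y = np.zeros((total + L, n))
        if kind == "clm":
            y[:L] = rng.uniform(0.0, 1.0, size=(L, n))
        eta = noise.mean + noise.sd * rng.standard_normal((total, n))
        for i in range(total):
            ti = i + L
            a = np.zeros(n)
            for l in range(L):
                a += A[l] @ y[ti - 1 - l]
            if kind == "var":
                y[ti] = a + eta[i]
            else:
                y[ti] = np.mod(4.0 * a * (1.0 - a) + eta[i], 1.0)
        out[:, :, rep] = y[L + burn_in :]
    return TimeSeriesData(out)


def simulate_var(
    net: GroundTruthNetwork,
    t: int,
    r: int = 1,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | None = None,
    burn_in: int = 1000,
) -> TimeSeriesData:
    """Simulate the VAR process on ``net``; burn-in is discarded.

    Initial conditions are zeros; the stationary distribution is reached
    within the burn-in for stable systems.  Raises if the companion
    spectral radius is at or beyond the stability guard.
    """
    radius = companion_spectral_radius(net)
    if radius >= _STABILITY_LIMIT:
        raise ValueError(
            f"unstable VAR system: companion spectral radius {radius:.4f}"
        )
    return _simulate(net, t, r, noise, seed, burn_in, "var")


def simulate_clm(
    net: GroundTruthNetwork,
    t: int,
    r: int = 1,
    noise: NoiseSpec = NoiseSpec(),
    seed: int | None = None,
    burn_in: int = 1000,
) -> TimeSeriesData:
    """Simulate the coupled logistic maps process on ``net``.

    Initial conditions are uniform on (0, 1); the modulo-1 wrap keeps all
    outputs in [0, 1).
    """
    return _simulate(net, t, r, noise, seed, burn_in, "clm")
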