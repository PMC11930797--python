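import itertools

import numpy as np
import pytest

from comagraph import CohortConfig, ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Reduced-size cohort: fast enough for repeated pipeline runs."""
    return CohortConfig(
        n_good=10, n_poor=8, n_nodes=16, n_volumes=80, n_modules=4, seed=7
    )


def random_weight_matrix(rng, n, p_edge=0.6):
    """Random symmetric non-negative weight matrix with zero diagonal."""
    w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < p_edge), 1)
    return w + w.T


def random_connectivity(rng, n):
    """A valid ConnectivityMatrix from random series."""
    from comagraph import connectivity_from_timeseries

    ts = rng.standard_normal((n, 4 * n + 20))
    return connectivity_from_timeseries(ts)


def set_partitions(n):
    """All set partitions of n items as label arrays (restricted growth)."""

    def rec(i, labels, mx):
        if i == n:
            yield labels.copy()
            return
        for c in range(mx + 1):
            labels[i] = c
            yield from rec(i + 1, labels, max(mx, c + 1))

    yield from rec(0, np.zeros(n, dtype=int), 0)


def triangle_clustering_bruteforce(W):
    """Onnela clustering by explicit triangle enumeration (O(N^3))."""
    W = np.asarray(W, float).copy()
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    wn = W / W.max()
    c = np.zeros(n)
    for i in range(n):
        neigh = np.flatnonzero(W[i])
        k = neigh.size
        if k < 2:
            continue
        s = 0.0
        for j, h in itertools.permutations(neigh, 2):
            s += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        c[i] = s / (k * (k - 1))
    return c.mean()


def floyd_warshall_efficiency(W):
    """Global efficiency via an independent Floyd-Warshall all-pairs pass."""
    W = np.asarray(W, float).copy()
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[W > 0] = 1.0 / W[W > 0]
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    off = ~np.eye(n, dtype=bool)
    inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return inv[off].mean()
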