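"""From node time series to normalized connectivity and its summaries.

Pipeline stage: per-node series are z-scored, pairwise Pearson
correlations computed, the matrix Fisher z-transformed (arctanh) with
negative correlations zeroed, and the diagonal forced to zero.  Whole-brain
functional connectivity is the mean of the positive edges; nodewise
connectivity is each node's mean edge weight to all other nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "compute_correlations",
    "normalize_connectivity",
    "whole_brain_fc",
    "nodewise_connectivity",
    "connectivity_from_timeseries",
]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric, non-negative Fisher-z edge-weight matrix, zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.isfinite(w).all():
            raise ValueError("weights must be finite")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if (np.diag(w) != 0).any():
            raise ValueError("diagonal must be exactly zero")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def compute_correlations(timeseries: np.ndarray, discard_first: int = 0) -> np.ndarray:
    """Pairwise Pearson correlation matrix of node time series.

    Each node's series is mean-centred and unit-scaled before correlating;
    ``discard_first`` drops initial volumes (default 0; the synthetic
    pipeline path uses 5 to mimic dropped pre-steady-state volumes).

    Raises ``ValueError`` naming the offending node if any series has zero
    variance (a constant series has no defined correlation).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (nodes x volumes)")
    if discard_first:
        ts = ts[:, discard_first:]
    n, t = ts.shape
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if t < 3:
        raise ValueError("need at least 3 volumes after discarding")
    sd = ts.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance (constant) series at node index {bad[0]}")
    z = (ts - ts.mean(axis=1, keepdims=True)) / sd[:, None]
    r = np.corrcoef(z)
    # guard against floating-point drift outside [-1, 1]
    return np.clip(r, -1.0, 1.0)


def normalize_connectivity(raw: np.ndarray) -> ConnectivityMatrix:
    """Fisher z-transform positive correlations, zero the negatives.

    Off-diagonal entries with ``|r| = 1`` are rejected: their z-value is
    infinite and signals duplicated node series.
    """
    r = np.asarray(raw, dtype=float)
    if r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(r, r.T):
        raise ValueError("correlation matrix must be symmetric")
    if (np.abs(r) > 1).any():
        raise ValueError("correlations must lie in [-1, 1]")
    off = ~np.eye(r.shape[0], dtype=bool)
    if (np.abs(r[off]) >= 1.0).any():
        i, j = np.argwhere(off & (np.abs(r) >= 1.0))[0]
        raise ValueError(
            f"|r| = 1 between nodes {i} and {j}: infinite Fisher z "
            "(duplicated node series?)"
        )
    z = np.where(r > 0, np.arctanh(np.where(off, r, 0.0)), 0.0)
    z = np.where(off, z, 0.0)
    z = (z + z.T) / 2.0  # restore exact symmetry after float ops
    return ConnectivityMatrix(z)


def whole_brain_fc(conn: ConnectivityMatrix, include_zeros: bool = False) -> float:
    """Mean of the positive edges (upper triangle, each pair once).

    With ``include_zeros=True`` the zeroed (originally negative or null)
    edges enter the denominator instead — the alternative reading of the
    positive-edge average.
    """
    w = conn.weights
    iu = np.triu_indices(conn.n_nodes, k=1)
    vals = w[iu]
    if include_zeros:
        return float(vals.mean())
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("no positive edges in connectivity matrix")
    return float(pos.mean())


def nodewise_connectivity(conn: ConnectivityMatrix) -> np.ndarray:
    """Per-node mean edge weight to the other N-1 nodes (zeros included)."""
    w = conn.weights
    return w.sum(axis=1) / (conn.n_nodes - 1)


def connectivity_from_timeseries(
    timeseries: np.ndarray, discard_first: int = 0
) -> ConnectivityMatrix:
    """Convenience: correlation + normalization in one step."""
    return normalize_connectivity(compute_correlations(timeseries, discard_first))
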