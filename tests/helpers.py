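"""Shared test utilities: independent oracles and matrix builders."""

from __future__ import annotations

import numpy as np


def single_linkage_oracle(X: np.ndarray, maxclust: int) -> set[frozenset[int]]:
    """Brute-force agglomerative single-linkage clustering.

    Performs ``n - maxclust`` merges, at each step joining the pair of
    clusters with the smallest minimum pairwise Euclidean row distance;
    ties break on the lexicographically lowest cluster-index pair.
    Independent of scipy.cluster: distances come from plain numpy and the
    merge loop is explicit.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=-1))
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    while len(clusters) > maxclust:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = min(D[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return set(clusters)


def partition_of(codes: np.ndarray) -> set[frozenset[int]]:
    """Label array -> partition as a set of frozensets (relabel-invariant)."""
    codes = np.asarray(codes)
    return {frozenset(np.flatnonzero(codes == c).tolist()) for c in np.unique(codes)}


def random_symmetric_pae(rng: np.random.Generator, n: int, high: float = 30.0) -> np.ndarray:
    """Random symmetric matrix with zero diagonal, entries in [0, high]."""
    m = rng.uniform(0.0, high, size=(n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def band_matrix(n: int, half_width: int = 2, low: float = 1.0, high: float = 20.0) -> np.ndarray:
    """Symmetric matrix that is low only within |i - j| <= half_width."""
    idx = np.arange(n)
    m = np.where(np.abs(idx[:, None] - idx[None, :]) <= half_width, low, high)
    m = m.astype(float)
    np.fill_diagonal(m, 0.0)
    return m
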