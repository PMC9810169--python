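"""From self-expressive matrix to cell labels: affinity building + spectral clustering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.manifold import spectral_embedding

from scsem.errors import ConfigError

log = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    labels: np.ndarray
    affinity: np.ndarray
    K: int
    subspace_dim: int


def sem_to_affinity(
    C: np.ndarray,
    subspace_dim: int = 4,
    K: int = 2,
    enhance: bool = True,
) -> np.ndarray:
    """Symmetric non-negative affinity from the learned coefficient matrix.

    Base rule: A = (|C| + |C^T|) / 2 with the diagonal zeroed.  With
    ``enhance=True`` (default), a rank-limited smoothing is applied first:
    the symmetrized C is projected onto its top (K*d + 1) singular subspace
    via U sqrt(S) with L2-normalized rows, and the affinity is the absolute
    value of Z = U U^T scaled to max 1.  The subspace dimension d is the
    assumed intrinsic dimension of each cell-type subspace; the rank bound
    K*d + 1 covers K subspaces of dimension d plus one for the affine
    offset.
    """
    C = np.asarray(C, dtype=np.float64)
    n = C.shape[0]
    if C.shape[0] != C.shape[1]:
        raise ConfigError("C must be square")
    if not np.all(np.isfinite(C)):
        raise ConfigError("C contains non-finite entries")
    if enhance:
        r = K * subspace_dim + 1
        if r + 1 > n:
            raise ConfigError(
                f"rank K*d+1 = {r} too large for {n} cells; lower subspace_dim"
            )
        sym = 0.5 * (C + C.T)
        u, s, _ = np.linalg.svd(sym, full_matrices=False)
        u, s = u[:, :r], s[:r]
        u = u * np.sqrt(s)
        norms = np.linalg.norm(u, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        u = u / norms
        z = np.abs(u @ u.T)
        if z.max() > 0:
            z = z / z.max()
        a = 0.5 * (z + z.T)
    else:
        a = 0.5 * (np.abs(C) + np.abs(C.T))
    np.fill_diagonal(a, 0.0)
    return a


def spectral_cluster(
    A: np.ndarray,
    K: int,
    seed: int = 0,
    subspace_dim: int = 4,
    n_restarts: int = 20,
) -> ClusterResult:
    """Normalized-Laplacian spectral embedding + seeded multi-restart K-means.

    Labels are arbitrary up to permutation.  Cells with zero degree get a
    tiny self-loop before Laplacian normalization; a graph with more than K
    connected components triggers a warning but still clusters.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.shape[0] != A.shape[1]:
        raise ConfigError("affinity must be square")
    if (A < 0).any():
        raise ConfigError("affinity must be non-negative")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ConfigError("affinity must be symmetric")
    n = A.shape[0]
    if K < 1 or K > n:
        raise ConfigError(f"K={K} invalid for {n} cells")
    if K == 1:
        return ClusterResult(np.zeros(n, dtype=int), A, 1, subspace_dim)
    A = A.copy()
    deg = A.sum(axis=1)
    isolated = deg == 0
    if isolated.any():
        A[isolated, isolated] = 1e-8
    n_comp, _ = connected_components(scipy.sparse.csr_matrix(A > 0), directed=False)
    if n_comp > K:
        log.warning("affinity graph has %d components for K=%d clusters", n_comp, K)
    emb = spectral_embedding(
        A, n_components=K, random_state=seed, drop_first=False,
        norm_laplacian=True, eigen_solver="arpack",
    )
    # sign-fix each eigenvector: largest-magnitude entry positive
    for j in range(emb.shape[1]):
        k = np.argmax(np.abs(emb[:, j]))
        if emb[k, j] < 0:
            emb[:, j] = -emb[:, j]
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(emb)
    return ClusterResult(labels.astype(int), A, K, subspace_dim)


def cluster_sem(
    C: np.ndarray,
    K: int,
    subspace_dim: int = 4,
    seed: int = 0,
    enhance: bool = True,
) -> ClusterResult:
    """Convenience: affinity from C, then spectral clustering."""
    a = sem_to_affinity(C, subspace_dim=subspace_dim, K=K, enhance=enhance)
    return spectral_cluster(a, K=K, seed=seed, subspace_dim=subspace_dim)
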