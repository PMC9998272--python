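"""Shared linear-algebra kernels over labeled tissue graphs.

All routines work on a sparse adjacency matrix ``A`` (n x n, 0/1, symmetric)
and an integer label vector.  They are the vectorized equivalents of a
per-node neighbor census and are used by the labeling engines and the
adjacency statistics alike.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["onehot", "observed_H", "pair_edge_counts"]


def onehot(labels: np.ndarray, K: int) -> np.ndarray:
    """Dense n x K one-hot encoding B of an integer label vector."""
    labels = np.asarray(labels, dtype=int)
    B = np.zeros((labels.shape[0], K), dtype=float)
    B[np.arange(labels.shape[0]), labels] = 1.0
    return B


def observed_H(A: sp.csr_matrix, labels: np.ndarray, K: int) -> np.ndarray:
    """Observed neighborhood probability matrix for a one-hot labeling.

    Row ``i`` is the mean, over nodes of type ``i``, of the fraction of each
    node's neighbors that carry type ``j``:

        H(B) = diag(B^T B)^-1  B^T  diag(A A^T)^-1  A B

    Isolated nodes (degree 0) contribute a zero neighbor row; types with no
    assigned node yield a row of NaN.
    """
    labels = np.asarray(labels, dtype=int)
    B = onehot(labels, K)
    deg = np.asarray(A.sum(axis=1)).ravel()
    safe_deg = np.where(deg > 0, deg, 1.0)
    N = A @ B  # per-node neighbor counts by type
    frac = N / safe_deg[:, None]
    W = B.T @ frac
    counts = np.bincount(labels, minlength=K).astype(float)
    H = np.full((K, K), np.nan)
    present = counts > 0
    H[present] = W[present] / counts[present, None]
    return H


def pair_edge_counts(A: sp.csr_matrix, labels: np.ndarray, K: int) -> np.ndarray:
    """K x K matrix of edge counts between type pairs.

    Computed as ``C = B^T A B``; the off-diagonal entry (i, j) is the number
    of i-j edges, and the diagonal is halved (each same-type edge is counted
    twice in C).
    """
    B = onehot(labels, K)
    C = B.T @ (A @ B)
    counts = C.copy()
    np.fill_diagonal(counts, np.diag(C) / 2.0)
    return counts
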