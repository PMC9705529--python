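"""Compiled inner kernels (numba) for community detection.

Pure-array routines only: all graph bookkeeping stays in
:mod:`dynmodnet.community`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def louvain_sweep(B: np.ndarray, labels: np.ndarray, order: np.ndarray) -> int:
    """One pass of greedy node moves on a dense (generalized) modularity matrix.

    Each vertex, visited in ``order``, moves to the community maximizing the
    modularity gain 2*(sum of B[u, members(c)] - sum of B[u, members(own)]);
    empty community slots (labels 0..n-1 never assigned) have zero affinity,
    so a vertex can also split off on its own.  Ties resolve to the
    lowest-index community with a strictly best gain (first-found best in the
    randomized scan order).  Mutates ``labels``; returns the number of moves.
    """
    n = B.shape[0]
    n_moves = 0
    comm_sum = np.zeros(n, dtype=np.float64)
    for idx in range(n):
        u = order[idx]
        cu = labels[u]
        for c in range(n):
            comm_sum[c] = 0.0
        for v in range(n):
            if v != u:
                comm_sum[labels[v]] += B[u, v]
        base = comm_sum[cu]
        best_c = cu
        best_gain = 0.0
        for c in range(n):
            g = comm_sum[c] - base
            if g > best_gain + 1e-12:
                best_gain = g
                best_c = c
        if best_c != cu:
            labels[u] = best_c
            n_moves += 1
    return n_moves


@njit(cache=True)
def max_partition_pair_sum(B: np.ndarray):
    """Exhaustively maximize sum_{u<v, g_u==g_v} B[u, v] over all partitions.

    Depth-first enumeration of restricted growth strings (every set partition
    of the vertices exactly once), accumulating the pairwise score
    incrementally.  Independent of any heuristic optimizer; intended for
    graphs with at most ~13 vertices.

    Returns (best pair-sum, best label vector).
    """
    n = B.shape[0]
    labels = np.zeros(n, dtype=np.int64)
    choice = np.zeros(n, dtype=np.int64)       # block tried at each depth
    n_blocks = np.zeros(n + 1, dtype=np.int64)  # blocks in use before depth d
    acc = np.zeros(n + 1, dtype=np.float64)     # pair-sum of prefix
    best = -np.inf
    best_labels = np.zeros(n, dtype=np.int64)
    depth = 0
    while depth >= 0:
        b = choice[depth]
        if b > n_blocks[depth]:        # exhausted choices at this depth
            depth -= 1
            if depth >= 0:
                choice[depth] += 1
            continue
        gain = 0.0
        for m in range(depth):
            if labels[m] == b:
                gain += B[depth, m]
        labels[depth] = b
        acc[depth + 1] = acc[depth] + gain
        n_blocks[depth + 1] = n_blocks[depth] + (1 if b == n_blocks[depth] else 0)
        if depth == n - 1:
            if acc[depth + 1] > best:
                best = acc[depth + 1]
                best_labels[:] = labels
            choice[depth] += 1
        else:
            depth += 1
            choice[depth] = 0
    return best, best_labels
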