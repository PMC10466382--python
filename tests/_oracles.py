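"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the DBSCAN oracle
works from a full distance matrix with an explicit BFS, and the alignment
oracle enumerates every global alignment of two short sequences.
"""

from __future__ import annotations

from collections import deque
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_dbscan(points: np.ndarray, eps: float, min_n: int) -> np.ndarray:
    """Reference DBSCAN labels with canonical border-tie resolution.

    Points are ranked by coordinate-sorted order; core points are those
    with >= min_n neighbors within eps (self included); clusters are BFS
    components of the core-core eps graph; a border point joins the
    cluster of its lowest-ranked core neighbor.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    rank_order = sorted(range(n), key=lambda i: tuple(points[i]))
    pos = points[rank_order]
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    adj = dist <= eps
    core = adj.sum(axis=1) >= min_n
    lab = np.full(n, -1, dtype=int)
    cid = 0
    for s in range(n):
        if not core[s] or lab[s] != -1:
            continue
        queue = deque([s])
        lab[s] = cid
        while queue:
            i = queue.popleft()
            for j in np.flatnonzero(adj[i]):
                if core[j] and lab[j] == -1:
                    lab[j] = cid
                    queue.append(j)
        cid += 1
    for i in range(n):
        if core[i]:
            continue
        cores = [j for j in np.flatnonzero(adj[i]) if core[j]]
        if cores:
            lab[i] = lab[min(cores)]
    for r, orig in enumerate(rank_order):
        labels[orig] = lab[r]
    return labels


def partition_of(labels: np.ndarray) -> tuple[frozenset, ...]:
    """Label-permutation-invariant view: clusters as frozensets + noise set."""
    labels = np.asarray(labels)
    clusters = frozenset(
        frozenset(np.flatnonzero(labels == v).tolist())
        for v in np.unique(labels) if v >= 0)
    noise = frozenset(np.flatnonzero(labels < 0).tolist())
    return clusters, noise


def brute_align_score(seq_a: str, seq_b: str,
                      gap_open: float = -10.0,
                      gap_extend: float = -0.5) -> float:
    """Optimal global affine-gap alignment score by exhaustive recursion.

    Memoized three-state recursion over all alignment columns, written
    independently of the production aligner. The gap state tracks whether
    the previous column was a gap in the same sequence, so affine costs
    (open for the first gap character, extend afterwards) are exact.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 = previous column was a match, 1 = gap in b, 2 = gap in a
        if i == len(seq_a) and j == len(seq_b):
            return 0.0
        options = []
        if i < len(seq_a) and j < len(seq_b):
            options.append(_BLOSUM62[seq_a[i], seq_b[j]]
                           + best(i + 1, j + 1, 0))
        if i < len(seq_a):
            cost = gap_extend if state == 1 else gap_open
            options.append(cost + best(i + 1, j, 1))
        if j < len(seq_b):
            cost = gap_extend if state == 2 else gap_open
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)
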