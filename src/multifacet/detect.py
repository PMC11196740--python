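"""Modularity computation and optimization over partitions.

The optimizer is a generalized Louvain procedure that accepts *any* real
modularity matrix ``B`` (entries may be negative, the matrix asymmetric).
Because the modularity ``Q = (1/L) sum_ij B_ij delta(c_i, c_j)`` sums over
ordered pairs, it is invariant under symmetrization ``B' = (B + B^T)/2``, so
the optimizer works on ``B'`` without changing the objective.

Runs are deterministic given ``(seed, restarts, node_order)``: every restart
re-shuffles the node visiting order from one seeded random stream, ties in
the local-moving phase keep the current community or fall to the lowest
community label, and the best-Q restart (first found on ties) is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import MultifacetError
from .multiplex import Partition
from .nulls import ModularityMatrix

_TIE_TOL = 1e-12


def modularity(Bm: ModularityMatrix, part: Partition) -> float:
    """Global modularity ``Q = (1/L) sum_ij B_ij delta(c_i, c_j)``.

    The sum runs over ordered node pairs, including ``i = j`` (the diagonal
    is zero except for the configuration null's ``k_i``-product terms).
    """
    labels = part.labels_for(Bm.node_order)
    same = labels[:, None] == labels[None, :]
    return float(Bm.B[same].sum() / Bm.L)


def local_modularity(Bm: ModularityMatrix, part: Partition, community_id: int) -> float:
    """Community contribution ``Q_c = (1/L) sum_{i,j in C} B_ij``.

    Summing ``Q_c`` over all communities recovers the global ``Q``.
    """
    if not 1 <= community_id <= part.K:
        raise MultifacetError(f"unknown community id {community_id} (partition has K={part.K})")
    labels = part.labels_for(Bm.node_order)
    idx = np.flatnonzero(labels == community_id)
    return float(Bm.B[np.ix_(idx, idx)].sum() / Bm.L)


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of one optimization: best partition, its Q, and run metadata."""

    partition: Partition
    Q: float
    restarts_used: int
    seed: int
    trace: tuple[float, ...] = field(default_factory=tuple)


def _local_moving(M: np.ndarray, order: np.ndarray) -> np.ndarray:
    """One Louvain level: greedy node moves on symmetric matrix M.

    Returns the community label of each node (labels are recycled slots in
    ``0..n-1``).  A node moves only on a strictly positive gain; when the
    best attainable neighbourhood weight is negative the node detaches into
    a free singleton slot.  Ties keep the current community, else take the
    lowest label.
    """
    n = M.shape[0]
    comm = np.arange(n)
    sizes = np.ones(n, dtype=int)
    improved = True
    while improved:
        improved = False
        for i in order:
            cur = comm[i]
            row = M[i]
            # weight from i to each community, excluding i itself
            totals = np.bincount(comm, weights=row, minlength=n)
            totals[cur] -= row[i]  # self-loop moves with the node; drop it everywhere
            best_val = totals.max()
            stay_val = totals[cur]
            if best_val <= stay_val + _TIE_TOL:
                # no strictly better occupied community; consider detaching
                if stay_val < -_TIE_TOL and sizes[cur] > 1:
                    free = np.flatnonzero(sizes == 0)
                    target = int(free[0])
                else:
                    continue
            else:
                candidates = np.flatnonzero(totals >= best_val - _TIE_TOL)
                target = int(candidates[0])
                if target == cur:
                    continue
                # detaching still beats joining a negative-best community
                if best_val < -_TIE_TOL and sizes[cur] > 1:
                    free = np.flatnonzero(sizes == 0)
                    target = int(free[0])
            if target == cur:
                continue
            sizes[cur] -= 1
            sizes[target] += 1
            comm[i] = target
            improved = True
    return comm


def _aggregate(M: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse communities into coarse nodes, summing B' entries (L preserved)."""
    labels, dense = np.unique(comm, return_inverse=True)
    k = labels.size
    ind = np.zeros((k, M.shape[0]))
    ind[dense, np.arange(M.shape[0])] = 1.0
    return ind @ M @ ind.T, dense


def _louvain_once(
    Bsym: np.ndarray, L: float, rng: np.random.Generator, shuffle: bool
) -> tuple[np.ndarray, list[float]]:
    n0 = Bsym.shape[0]
    membership = np.arange(n0)
    M = Bsym.copy()
    trace: list[float] = []
    while True:
        n = M.shape[0]
        order = np.arange(n)
        if shuffle:
            rng.shuffle(order)
        comm = _local_moving(M, order)
        if np.array_equal(comm, np.arange(n)) and len(np.unique(comm)) == n:
            break
        M, dense = _aggregate(M, comm)
        membership = dense[comm[membership]]
        trace.append(float(np.trace(M)) / L)  # Q after this level
        if M.shape[0] == n:
            break
    return membership, trace


def louvain(
    Bm: ModularityMatrix,
    seed: int = 0,
    restarts: int = 20,
    node_order: str = "shuffled",
) -> DetectionResult:
    """Two-phase generalized Louvain optimization of ``Q`` over partitions.

    Parameters
    ----------
    Bm
        Modularity matrix to optimize; asymmetric matrices are symmetrized
        (the objective is unchanged).
    seed
        Seed for the visiting-order stream; results are bit-reproducible for
        identical ``(Bm, seed, restarts, node_order)``.
    restarts
        Independent greedy runs; the best-Q partition is returned.  Empirical
        null landscapes are rugged, so the default keeps several restarts.
    node_order
        ``"shuffled"`` draws a fresh visiting order per level and restart;
        ``"sorted"`` visits nodes in index order (then one restart suffices).
    """
    if restarts < 1:
        raise MultifacetError("restarts must be >= 1")
    if node_order not in ("shuffled", "sorted"):
        raise MultifacetError(f"unknown node_order {node_order!r}")
    Bsym = (Bm.B + Bm.B.T) / 2.0
    rng = np.random.default_rng(seed)
    shuffle = node_order == "shuffled"
    n_runs = restarts if shuffle else 1
    best: tuple[float, np.ndarray, list[float]] | None = None
    for _ in range(n_runs):
        membership, trace = _louvain_once(Bsym, Bm.L, rng, shuffle)
        part = Partition.from_labels(Bm.node_order, membership + 1)
        q = modularity(Bm, part)
        if best is None or q > best[0] + _TIE_TOL:
            best = (q, membership, trace)
    q, membership, trace = best
    part = Partition.from_labels(Bm.node_order, membership + 1)
    return DetectionResult(
        partition=part, Q=q, restarts_used=n_runs, seed=seed, trace=tuple(trace)
    )


def _set_partitions(n: int) -> Iterator[np.ndarray]:
    """All set partitions of {0..n-1} as restricted-growth label strings.

    Yields labels in lexicographic order; the buffer is reused, so callers
    must copy any array they keep.
    """
    a = np.zeros(n, dtype=int)

    def rec(i: int, mx: int) -> Iterator[np.ndarray]:
        if i == n:
            yield a
            return
        for v in range(mx + 2):
            a[i] = v
            yield from rec(i + 1, max(mx, v))

    if n == 1:
        yield a
    else:
        yield from rec(1, 0)


def exhaustive_best_partition(Bm: ModularityMatrix) -> DetectionResult:
    """Enumerate all set partitions (N <= 10) and return the max-Q one.

    Intended as a ground-truth oracle on small problems.  Ties are broken
    toward fewer communities, then toward the lexicographically smallest
    canonical label string.
    """
    n = Bm.n_nodes
    if n > 10:
        raise MultifacetError(
            f"exhaustive enumeration refused for N={n} > 10 (Bell number explosion)"
        )
    B = Bm.B
    best_q = -np.inf
    best_labels: np.ndarray | None = None
    best_k = n + 1
    for labels in _set_partitions(n):
        same = labels[:, None] == labels[None, :]
        q = float(B[same].sum() / Bm.L)
        k = int(labels.max()) + 1
        if q > best_q + _TIE_TOL:
            better = True
        elif q >= best_q - _TIE_TOL:
            better = k < best_k or (k == best_k and tuple(labels) < tuple(best_labels))
        else:
            better = False
        if better:
            best_q, best_labels, best_k = q, labels.copy(), k
    part = Partition.from_labels(Bm.node_order, best_labels + 1)
    return DetectionResult(
        partition=part,
        Q=modularity(Bm, part),
        restarts_used=1,
        seed=0,
        trace=(best_q,),
    )
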