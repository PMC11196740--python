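"""Evaluation of community structures.

Covers the three quantities used to characterize detected modules:

* normalized mutual information (NMI) between two partitions, from their
  confusion matrix — 1 for identical structures, 0 for unrelated ones;
* within-module edge-overlap probability ``P(l_m | l_k)``: the fraction of
  observed-layer edges that co-occur with a null-layer edge on the same
  ordered node pair, globally or restricted to pairs inside one community;
* per-module summary rows (size, local modularity, overlap), and the
  layer-contribution scan that compares each promoted layer subset's
  community structure against the configuration-model baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import MultifacetError, NonBinaryLayerError
from .multiplex import MultiplexNetwork, Partition, merge_layers
from .nulls import ModularityMatrix, configuration_null, multi_matrix
from .detect import DetectionResult, local_modularity, louvain, modularity


def nmi(X: Partition, Y: Partition) -> float:
    """Normalized mutual information of two partitions of the same node set.

    Computed from the confusion matrix ``N_ij`` (number of nodes in community
    ``i`` of X and ``j`` of Y) as ``-2 sum N_ij log(N_ij N / (N_i. N_.j))``
    over ``sum N_i. log(N_i./N) + sum N_.j log(N_.j/N)``, with natural
    logarithms and ``0 log 0 = 0``.  Returns 1 when the structures coincide
    (including the degenerate case of two whole-set partitions) and 0 when
    the confusion matrix carries no mutual information.
    """
    nodes = sorted(X.assignment)
    if set(nodes) != set(Y.assignment):
        raise MultifacetError("partitions cover different node sets")
    if X == Y:  # identical structure: exactly 1 by convention (and algebra)
        return 1.0
    n = len(nodes)
    xl = np.array([X.assignment[v] for v in nodes]) - 1
    yl = np.array([Y.assignment[v] for v in nodes]) - 1
    confusion = np.zeros((X.K, Y.K))
    np.add.at(confusion, (xl, yl), 1.0)
    row = confusion.sum(axis=1)
    col = confusion.sum(axis=0)
    nz = confusion > 0
    num = -2.0 * float(
        (confusion[nz] * np.log(confusion[nz] * n / np.outer(row, col)[nz])).sum()
    )
    den = float((row * np.log(row / n)).sum() + (col * np.log(col / n)).sum())
    if den == 0.0:  # both partitions are the single whole-set community
        return 1.0
    return float(min(1.0, max(0.0, num / den)))


def _binary_or_raise(M: MultiplexNetwork, name: str) -> np.ndarray:
    layer = M.layer(name)
    if not layer.is_binary():
        raise NonBinaryLayerError(
            f"layer {name!r} is weighted; binarize explicitly before overlap analysis"
        )
    return layer.weights


def overlap_probability(
    M: MultiplexNetwork,
    base: str,
    cond: str,
    part: Optional[Partition] = None,
):
    """Probability that a ``base``-layer edge co-occurs with a ``cond``-layer edge.

    Counting unit is the directed ordered pair: a reciprocal pair contributes
    two trials.  With ``part=None`` the ratio is global; with a partition it
    is computed per community over pairs internal to that community, and a
    community with no internal base edges yields ``None`` (undefined, never 0).
    """
    A = _binary_or_raise(M, base)
    C = _binary_or_raise(M, cond)
    if part is None:
        base_edges = A.sum()
        if base_edges == 0:
            return None
        return float((A * C).sum() / base_edges)
    labels = part.labels_for(M.nodes)
    out: dict[int, Optional[float]] = {}
    for k in range(1, part.K + 1):
        idx = np.flatnonzero(labels == k)
        sub_a = A[np.ix_(idx, idx)]
        internal = sub_a.sum()
        if internal == 0:
            out[k] = None
        else:
            out[k] = float((sub_a * C[np.ix_(idx, idx)]).sum() / internal)
    return out


@dataclass(frozen=True)
class ModuleSummary:
    """One community's row in a module characterization table."""

    community_id: int
    n_members: int
    Q_c: float
    overlap_prob: Optional[float]


def module_summary(
    Bm: ModularityMatrix,
    M: MultiplexNetwork,
    part: Partition,
    base: str,
    cond: str,
) -> list[ModuleSummary]:
    """Per-community size, local modularity and within-module overlap."""
    if tuple(Bm.node_order) != tuple(M.nodes):
        raise MultifacetError("modularity matrix and multiplex node orders differ")
    overlaps = overlap_probability(M, base, cond, part)
    rows = []
    for k in range(1, part.K + 1):
        rows.append(
            ModuleSummary(
                community_id=k,
                n_members=len(part.members(k)),
                Q_c=local_modularity(Bm, part, k),
                overlap_prob=overlaps[k],
            )
        )
    return rows


@dataclass(frozen=True)
class ScanRow:
    """One promoted-layer subset in a layer-contribution scan."""

    promoted_layers: tuple[str, ...]
    Q: Optional[float]
    nmi_vs_baseline: Optional[float]
    error: Optional[str] = None


def layer_contribution_scan(
    M: MultiplexNetwork,
    observed: Sequence[str],
    candidate_nulls: Sequence[Sequence[str]],
    gamma: float = 1.0,
    seed: int = 0,
    restarts: int = 20,
) -> tuple[DetectionResult, list[ScanRow]]:
    """Measure each layer subset's pull on the merged network's communities.

    The baseline is the configuration-model (NG) community structure of the
    merged observed network.  For every candidate subset, communities are
    re-detected with the weighted-complement null promoting that subset, and
    the row reports the resulting ``Q`` and its NMI against the baseline.
    A degenerate null (e.g. saturated weights) is reported in the row's
    ``error`` field rather than aborting the scan.

    Returns the baseline detection result and the scan rows.
    """
    candidate_nulls = [tuple(c) for c in candidate_nulls]
    if not candidate_nulls:
        raise MultifacetError("candidate null list must not be empty")
    rng = np.random.default_rng(seed)
    baseline_seed, row_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    baseline_Bm = configuration_null(merge_layers(M, observed))
    baseline = louvain(baseline_Bm, seed=baseline_seed, restarts=restarts)
    rows: list[ScanRow] = []
    # one shared optimizer seed across rows: subsets differ only in their
    # null network, so rows are directly comparable (and structurally
    # identical subsets give identical rows)
    for subset in candidate_nulls:
        try:
            Bm = multi_matrix(M, observed, subset, gamma)
            res = louvain(Bm, seed=row_seed, restarts=restarts)
            rows.append(
                ScanRow(
                    promoted_layers=subset,
                    Q=res.Q,
                    nmi_vs_baseline=nmi(res.partition, baseline.partition),
                )
            )
        except MultifacetError as exc:
            rows.append(ScanRow(promoted_layers=subset, Q=None, nmi_vs_baseline=None, error=str(exc)))
    return baseline, rows


def all_subsets_up_to(names: Sequence[str], max_size: int = 2) -> list[tuple[str, ...]]:
    """All non-empty layer subsets up to ``max_size`` (singletons, pairs, ...)."""
    names = list(names)
    if max_size < 1:
        raise MultifacetError("max_size must be >= 1")
    out: list[tuple[str, ...]] = []
    for r in range(1, min(max_size, len(names)) + 1):
        out.extend(itertools.combinations(names, r))
    return out
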