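"""Null networks and modularity matrices ``B = A - P``.

Four modes are supported:

``ng``
    Classical configuration-model null, ``P_ij`` proportional to the product
    of node degrees/strengths; detects ordinary density-based communities.
``exclusion``
    The null network is another *empirical* layer of the multiplex, so that
    modularity maximization gives less weight to edges of the observed layer
    that overlap edges of the null layer: communities avoid edge overlap.
``inclusion``
    The null network is the *complement graph* of another binary layer; the
    penalty now falls on observed edges that do **not** co-occur with null
    layer edges, so communities favour multidimensional (overlapping) edges.
``multi``
    Observed network is a weighted merge of layers; the null is the weighted
    (max-minus-weight) complement of a chosen sub-merge, promoting the chosen
    layers' edges inside communities.

In every empirical mode the raw null matrix is rescaled so its total mass
equals ``gamma * L`` where ``L`` is the observed layer's total weight: at
``gamma = 1`` observed and null networks carry the same weight, and ``gamma``
linearly adjusts the strength of the null consideration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateNullError, EmptyLayerError, MultifacetError, NonBinaryLayerError
from .multiplex import (
    Layer,
    MultiplexNetwork,
    Node,
    complement_binary,
    complement_weighted,
    merge_layers,
    total_weight,
)


@dataclass(frozen=True)
class ModularityMatrix:
    """``B = A - P`` with provenance.

    ``B`` may contain negative entries and be asymmetric.  ``L`` is the total
    weight of the observed network and is the normalizing constant of the
    modularity ``Q = (1/L) sum_ij B_ij delta(c_i, c_j)``.
    """

    B: np.ndarray
    node_order: tuple[Node, ...]
    L: float
    gamma: float
    mode: str
    observed_layers: tuple[str, ...]
    null_layers: tuple[str, ...]
    A: np.ndarray | None = None
    P: np.ndarray | None = None

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=float)
        n = len(self.node_order)
        if B.shape != (n, n):
            raise MultifacetError(f"B has shape {B.shape}, expected ({n}, {n})")
        if not np.all(np.isfinite(B)):
            raise MultifacetError("B must be finite")
        if not self.L > 0:
            raise MultifacetError("observed total weight L must be positive")
        if self.gamma < 0:
            raise MultifacetError("gamma must be non-negative")
        B = B.copy()
        B.setflags(write=False)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "node_order", tuple(self.node_order))

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)


def normalize_null(P_raw: np.ndarray, L: float, gamma: float) -> np.ndarray:
    """Rescale a raw null matrix to total mass ``gamma * L``.

    Implements the equal-weight convention ``sum A = sum P = L``: the raw
    null is first scaled so its total equals the observed total weight ``L``,
    then multiplied by ``gamma``.  E.g. a 440-edge binary null against a
    305-edge observed layer at ``gamma = 1`` scales every unit edge to
    ``305/440``.  ``gamma = 0`` disables the null entirely (``B = A``).
    """
    P_raw = np.asarray(P_raw, dtype=float)
    if np.any(P_raw < 0):
        raise MultifacetError("raw null matrix must be non-negative")
    if not L > 0:
        raise MultifacetError("observed total weight L must be positive")
    if gamma < 0:
        raise MultifacetError("gamma must be non-negative")
    s = float(P_raw.sum())
    if s <= 0:
        raise DegenerateNullError("null network is empty (zero total weight)")
    return gamma * (L / s) * P_raw


def configuration_null(layer: Layer, degree_mode: str = "as_printed") -> ModularityMatrix:
    """Configuration-model (Newman–Girvan) modularity matrix of one layer.

    ``degree_mode="as_printed"`` uses total (in+out) strengths ``k_i`` with
    ``P_ij = k_i k_j / (2 * 2L)``; on a symmetrically stored undirected graph
    this reduces to the textbook ``k_i k_j / 2m`` and in either case
    ``sum_ij P_ij = L`` exactly.  ``degree_mode="directed"`` uses the
    Leicht–Newman form ``P_ij = k_i^out k_j^in / L`` (also mass-preserving).
    The diagonal of ``P`` keeps its ``k_i``-product terms, as in the standard
    configuration model.
    """
    L = total_weight(layer)
    if L <= 0:
        raise EmptyLayerError(f"layer {layer.name!r} has zero total weight")
    w = layer.weights
    if degree_mode == "as_printed":
        k = w.sum(axis=1) + w.sum(axis=0)  # in+out strength; sums to 2L
        P = np.outer(k, k) / (4.0 * L)
    elif degree_mode == "directed":
        k_out = w.sum(axis=1)
        k_in = w.sum(axis=0)
        P = np.outer(k_out, k_in) / L
    else:
        raise MultifacetError(f"unknown degree_mode {degree_mode!r}")
    return ModularityMatrix(
        B=w - P,
        node_order=layer.node_order,
        L=L,
        gamma=1.0,
        mode="ng",
        observed_layers=(layer.name,),
        null_layers=("configuration",),
        A=w.copy(),
        P=P,
    )


def exclusion_matrix(
    M: MultiplexNetwork, observed: str, null: str, gamma: float = 1.0
) -> ModularityMatrix:
    """Modularity matrix that discourages edge overlap inside communities.

    Observed adjacency is layer ``observed``; the null network is layer
    ``null`` itself, rescaled to mass ``gamma * L``.  Overlapping edges lose
    weight in ``B``; null-only pairs go negative.
    """
    if observed == null:
        raise MultifacetError(
            "observed and null layers must differ in exclusion mode (B would be (1-gamma*s)A)"
        )
    A = M.layer(observed).weights
    L = total_weight(M.layer(observed))
    if L <= 0:
        raise EmptyLayerError(f"observed layer {observed!r} has zero total weight")
    P = normalize_null(M.layer(null).weights, L, gamma)
    return ModularityMatrix(
        B=A - P,
        node_order=M.nodes,
        L=L,
        gamma=gamma,
        mode="exclusion",
        observed_layers=(observed,),
        null_layers=(null,),
        A=A.copy(),
        P=P,
    )


def inclusion_matrix(
    M: MultiplexNetwork, observed: str, null: str, gamma: float = 1.0
) -> ModularityMatrix:
    """Modularity matrix that favours overlapping (multidimensional) edges.

    The null network is the complement graph of the binary layer ``null``:
    observed edges that co-occur with a null-layer edge are not penalized,
    while observed edges missing from the null layer are.
    """
    if observed == null:
        raise MultifacetError("observed and null layers must differ in inclusion mode")
    null_layer = M.layer(null)
    if not null_layer.is_binary():
        raise NonBinaryLayerError(
            f"null layer {null!r} is weighted; inclusion mode needs a binary layer "
            "(use multi mode for weighted complements)"
        )
    A = M.layer(observed).weights
    L = total_weight(M.layer(observed))
    if L <= 0:
        raise EmptyLayerError(f"observed layer {observed!r} has zero total weight")
    P = normalize_null(complement_binary(null_layer).weights, L, gamma)
    return ModularityMatrix(
        B=A - P,
        node_order=M.nodes,
        L=L,
        gamma=gamma,
        mode="inclusion",
        observed_layers=(observed,),
        null_layers=(null,),
        A=A.copy(),
        P=P,
    )


def multi_matrix(
    M: MultiplexNetwork,
    observed: Sequence[str],
    null: Sequence[str],
    gamma: float = 1.0,
) -> ModularityMatrix:
    """Merged-network modularity matrix promoting chosen layers in communities.

    Observed adjacency is the weighted merge of ``observed``; the null is the
    weighted complement (max-minus-weight) of the merge of ``null``, which
    must be a subset of the observed layers.  Pairs connected in all promoted
    dimensions incur no penalty; fully absent pairs incur the maximal one.
    """
    observed = list(observed)
    null = list(null)
    if not observed or not null:
        raise MultifacetError("multi mode needs non-empty observed and null layer lists")
    if not set(null) <= set(observed):
        raise MultifacetError(
            f"null layers {null} must be a subset of the observed layers {observed}"
        )
    obs_layer = merge_layers(M, observed)
    L = total_weight(obs_layer)
    if L <= 0:
        raise EmptyLayerError("merged observed network has zero total weight")
    comp = complement_weighted(merge_layers(M, null))
    if comp.weights.sum() <= 0:
        raise DegenerateNullError(
            "weighted complement of the null merge is empty (all pairs at maximal weight)"
        )
    P = normalize_null(comp.weights, L, gamma)
    return ModularityMatrix(
        B=obs_layer.weights - P,
        node_order=M.nodes,
        L=L,
        gamma=gamma,
        mode="multi",
        observed_layers=tuple(observed),
        null_layers=tuple(null),
        A=obs_layer.weights.copy(),
        P=P,
    )


def build_modularity_matrix(
    M: MultiplexNetwork,
    mode: str,
    observed: Sequence[str],
    null: Sequence[str] = (),
    gamma: float = 1.0,
    degree_mode: str = "as_printed",
) -> ModularityMatrix:
    """Dispatch to the mode-specific constructor from a flat configuration."""
    observed = list(observed)
    null = list(null)
    if mode == "ng":
        if null:
            raise MultifacetError("ng mode takes no null layers (configuration model)")
        return configuration_null(merge_layers(M, observed), degree_mode=degree_mode)
    if mode == "exclusion":
        if len(observed) != 1 or len(null) != 1:
            raise MultifacetError("exclusion mode needs exactly one observed and one null layer")
        return exclusion_matrix(M, observed[0], null[0], gamma)
    if mode == "inclusion":
        if len(observed) != 1 or len(null) != 1:
            raise MultifacetError("inclusion mode needs exactly one observed and one null layer")
        return inclusion_matrix(M, observed[0], null[0], gamma)
    if mode == "multi":
        return multi_matrix(M, observed, null, gamma)
    raise MultifacetError(f"unknown mode {mode!r}; expected ng/exclusion/inclusion/multi")
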