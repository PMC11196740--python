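"""In-memory model of directed, weighted multiplex networks.

A multiplex network is a family of directed graphs (*layers*) on one shared,
ordered node set, with no interlayer edges.  Each layer stores a dense
``N x N`` weight matrix whose entry ``(i, j)`` is the weight of the directed
edge ``i -> j`` (0 = absent); the diagonal is always zero (no self-loops).
Undirected inputs are stored as two symmetric directed entries, making the
undirected case a special case of the directed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

from .errors import EmptyLayerError, MultifacetError, NonBinaryLayerError, UnknownLayerError

Node = Hashable


def _as_weight_matrix(weights: np.ndarray, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n, n):
        raise MultifacetError(
            f"weight matrix has shape {w.shape}, expected ({n}, {n}) from node_order"
        )
    if not np.all(np.isfinite(w)):
        raise MultifacetError("weights must be finite")
    if np.any(w < 0):
        raise MultifacetError("weights must be non-negative")
    if np.any(np.diagonal(w) != 0):
        raise MultifacetError("self-loops are not allowed (diagonal must be zero)")
    w = w.copy()
    w.setflags(write=False)
    return w


@dataclass(frozen=True)
class Layer:
    """One directed weighted graph on the shared node set.

    Parameters
    ----------
    name
        Layer label, e.g. ``"friendship"`` or a merged label ``"l1+l2"``.
    node_order
        The shared node identifiers, fixing row/column order of ``weights``.
    weights
        ``N x N`` matrix of non-negative edge weights; entry ``(i, j)`` is the
        weight of ``i -> j``.  Zero diagonal.
    directed
        Whether the layer is interpreted as directed.  Undirected layers are
        stored with symmetric entries; the flag is informational.
    """

    name: str
    node_order: tuple[Node, ...]
    weights: np.ndarray
    directed: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_order", tuple(self.node_order))
        object.__setattr__(
            self, "weights", _as_weight_matrix(self.weights, len(self.node_order))
        )

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    def is_binary(self) -> bool:
        w = self.weights
        return bool(np.all((w == 0) | (w == 1)))


def total_weight(layer: Layer) -> float:
    """Total weight ``L = sum_ij A_ij`` of a layer (edge count when binary)."""
    return float(layer.weights.sum())


@dataclass(frozen=True)
class MultiplexNetwork:
    """An ordered node set and a named collection of layers sharing it."""

    nodes: tuple[Node, ...]
    layers: Mapping[str, Layer]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        layers = dict(self.layers)
        for name, layer in layers.items():
            if layer.node_order != self.nodes:
                raise MultifacetError(
                    f"layer {name!r} node order differs from the multiplex node set"
                )
        object.__setattr__(self, "layers", layers)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def layer(self, name: str) -> Layer:
        try:
            return self.layers[name]
        except KeyError:
            raise UnknownLayerError(
                f"unknown layer {name!r}; available: {sorted(self.layers)}"
            ) from None

    @classmethod
    def from_layers(cls, layers: Iterable[Layer]) -> "MultiplexNetwork":
        layers = list(layers)
        if not layers:
            raise MultifacetError("a multiplex network needs at least one layer")
        nodes = layers[0].node_order
        return cls(nodes=nodes, layers={l.name: l for l in layers})

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Node, Node, str, float]],
        directed: bool = True,
    ) -> "MultiplexNetwork":
        """Build from ``(source, target, layer, weight)`` tuples.

        The shared node order is the sorted union of node identifiers appearing
        in any layer; nodes isolated in a given layer get all-zero rows/columns.
        Duplicate (source, target, layer) entries are summed.  Undirected input
        edges are stored as two symmetric directed entries.
        """
        edges = list(edges)
        node_set = sorted({e[0] for e in edges} | {e[1] for e in edges})
        index = {v: i for i, v in enumerate(node_set)}
        n = len(node_set)
        by_layer: dict[str, np.ndarray] = {}
        for src, dst, layer_name, w in edges:
            if src == dst:
                raise MultifacetError(f"self-loop {src!r} -> {dst!r} in layer {layer_name!r}")
            m = by_layer.setdefault(layer_name, np.zeros((n, n)))
            m[index[src], index[dst]] += w
            if not directed:
                m[index[dst], index[src]] += w
        layers = {
            name: Layer(name=name, node_order=tuple(node_set), weights=m, directed=directed)
            for name, m in by_layer.items()
        }
        return cls(nodes=tuple(node_set), layers=layers)


@dataclass(frozen=True)
class Partition:
    """A hard partition of the node set into communities ``1..K``.

    Community ids are canonicalized to the contiguous integers ``1..K`` in
    order of first appearance when scanning nodes in sorted identifier order,
    so that structurally identical partitions compare equal.
    """

    assignment: Mapping[Node, int]
    K: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.assignment:
            raise MultifacetError("partition must cover at least one node")
        nodes = sorted(self.assignment)
        relabel: dict[int, int] = {}
        canonical: dict[Node, int] = {}
        for v in nodes:
            old = self.assignment[v]
            if old not in relabel:
                relabel[old] = len(relabel) + 1
            canonical[v] = relabel[old]
        object.__setattr__(self, "assignment", canonical)
        object.__setattr__(self, "K", len(relabel))

    @classmethod
    def from_labels(cls, node_order: Sequence[Node], labels: Sequence[int]) -> "Partition":
        if len(node_order) != len(labels):
            raise MultifacetError("node_order and labels must have equal length")
        return cls(assignment=dict(zip(node_order, (int(l) for l in labels))))

    @property
    def nodes(self) -> tuple[Node, ...]:
        return tuple(sorted(self.assignment))

    def labels_for(self, node_order: Sequence[Node]) -> np.ndarray:
        """Community labels aligned to an explicit node order."""
        try:
            return np.array([self.assignment[v] for v in node_order], dtype=int)
        except KeyError as e:
            raise MultifacetError(f"node {e.args[0]!r} missing from partition") from None

    def members(self, community_id: int) -> tuple[Node, ...]:
        if not 1 <= community_id <= self.K:
            raise MultifacetError(f"unknown community id {community_id}")
        return tuple(v for v in sorted(self.assignment) if self.assignment[v] == community_id)

    def communities(self) -> dict[int, tuple[Node, ...]]:
        out: dict[int, list[Node]] = {k: [] for k in range(1, self.K + 1)}
        for v in sorted(self.assignment):
            out[self.assignment[v]].append(v)
        return {k: tuple(vs) for k, vs in out.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return dict(self.assignment) == dict(other.assignment)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.assignment.items(), key=lambda kv: repr(kv[0]))))


def merge_layers(M: MultiplexNetwork, subset: Sequence[str]) -> Layer:
    """Merge layers into one weighted directed layer by elementwise summation.

    The merged weight of a pair is proportional to the number of dimensions
    connecting it: binary layers each containing edge ``(u, v)`` contribute 1
    apiece, so a pair linked in all three of three layers gets weight 3.
    """
    subset = list(subset)
    if not subset:
        raise MultifacetError("merge_layers requires a non-empty layer subset")
    layers = [M.layer(name) for name in subset]
    weights = np.sum([l.weights for l in layers], axis=0)
    return Layer(
        name="+".join(subset),
        node_order=M.nodes,
        weights=weights,
        directed=any(l.directed for l in layers),
    )


def complement_binary(layer: Layer) -> Layer:
    """Complement graph of a binary layer: off-diagonal 1 -> 0, 0 -> 1.

    The complement has the same vertices but exactly the edges missing from
    the original; the diagonal stays zero (no self-loops).
    """
    if not layer.is_binary():
        raise NonBinaryLayerError(
            f"layer {layer.name!r} is weighted; use complement_weighted for "
            "max-minus-weight complements"
        )
    comp = 1.0 - layer.weights
    np.fill_diagonal(comp, 0.0)
    return Layer(
        name=f"~{layer.name}", node_order=layer.node_order, weights=comp, directed=layer.directed
    )


def complement_weighted(layer: Layer) -> Layer:
    """Weighted complement: off-diagonal ``max_ij(A_ij) - A_ij``, zero diagonal.

    The maximum is the global maximum off-diagonal weight of *this* layer
    (for a merged network, the largest number of dimensions any pair attains).
    Pairs at the maximum become 0; absent pairs become the maximum.
    """
    w = layer.weights
    mx = float(w.max())
    if mx <= 0:
        raise EmptyLayerError(
            f"layer {layer.name!r} has no positive weights; its complement is undefined"
        )
    comp = mx - w
    np.fill_diagonal(comp, 0.0)
    return Layer(
        name=f"~{layer.name}", node_order=layer.node_order, weights=comp, directed=layer.directed
    )
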