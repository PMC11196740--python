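"""Seeded synthetic multiplex networks with planted blocks and controlled overlap.

The generator emulates the structure of small directed organizational
multiplexes (a few hundred directed edges per layer on tens of nodes, with
inter-layer edge overlap concentrated inside cohesive groups): layer 1 is a
directed planted-partition graph; each further layer *copies* layer-1 edges
with a within-/between-block overlap probability and adds independent noise
edges.  Copying (rather than drawing layers independently) is deliberate —
the methods here exist precisely because edge overlap is not uniformly and
randomly distributed across a real multiplex.

All randomness flows from a single seed: the generator spawns one child
stream per layer from ``numpy``'s ``SeedSequence``, so adding layers never
perturbs earlier ones and generator seeds never collide with optimizer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import MultifacetError
from .multiplex import Layer, MultiplexNetwork, Partition


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-block directed multiplex.

    ``layer_probs[l] = (p_within, p_between)`` gives layer ``l``'s independent
    edge probabilities inside and between blocks; for layers after the first
    these act as noise rates on top of the copied layer-1 edges.
    ``overlap_rho = (rho_within, rho_between)`` is the probability that a
    layer-1 edge is copied into each later layer, by block position of the
    pair.  Defaults emulate a 67-actor organizational network: layer 1 at
    roughly 300 directed edges, layer 2 at roughly 440, with overlap
    concentrated within blocks.
    """

    block_sizes: tuple[int, ...] = (12, 11, 11, 11, 11, 11)
    layer_probs: tuple[tuple[float, float], ...] = ((0.35, 0.02), (0.15, 0.035))
    overlap_rho: tuple[float, float] = (0.8, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "block_sizes", tuple(int(s) for s in self.block_sizes))
        object.__setattr__(
            self, "layer_probs", tuple((float(a), float(b)) for a, b in self.layer_probs)
        )
        object.__setattr__(self, "overlap_rho", tuple(float(r) for r in self.overlap_rho))
        if not self.block_sizes or any(s < 1 for s in self.block_sizes):
            raise MultifacetError("block sizes must be positive")
        probs = [p for pair in self.layer_probs for p in pair] + list(self.overlap_rho)
        if len(self.overlap_rho) != 2:
            raise MultifacetError("overlap_rho must be (within, between)")
        if not self.layer_probs:
            raise MultifacetError("at least one layer is required")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise MultifacetError("probabilities must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return sum(self.block_sizes)

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    @property
    def n_layers(self) -> int:
        return len(self.layer_probs)


def _node_names(n: int) -> tuple[str, ...]:
    width = max(2, len(str(n)))
    return tuple(f"v{i + 1:0{width}d}" for i in range(n))


def generate(spec: SyntheticSpec) -> tuple[MultiplexNetwork, Partition]:
    """Draw a multiplex from ``spec``; returns it with the planted partition.

    Deterministic per ``spec.seed``: the same spec always yields bit-identical
    networks.
    """
    n = spec.n_nodes
    nodes = _node_names(n)
    block_labels = np.repeat(np.arange(1, spec.n_blocks + 1), spec.block_sizes)
    within = block_labels[:, None] == block_labels[None, :]
    off_diag = ~np.eye(n, dtype=bool)

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_layers)
    layers: list[Layer] = []

    p_w, p_b = spec.layer_probs[0]
    rng = np.random.default_rng(streams[0])
    prob = np.where(within, p_w, p_b)
    A1 = ((rng.random((n, n)) < prob) & off_diag).astype(float)
    layers.append(Layer(name="l1", node_order=nodes, weights=A1))

    rho = np.where(within, spec.overlap_rho[0], spec.overlap_rho[1])
    for l in range(1, spec.n_layers):
        rng = np.random.default_rng(streams[l])
        p_w, p_b = spec.layer_probs[l]
        copied = (A1 > 0) & (rng.random((n, n)) < rho)
        noise = (rng.random((n, n)) < np.where(within, p_w, p_b)) & off_diag
        Al = (copied | noise).astype(float)
        layers.append(Layer(name=f"l{l + 1}", node_order=nodes, weights=Al))

    M = MultiplexNetwork.from_layers(layers)
    truth = Partition.from_labels(nodes, block_labels)
    return M, truth


def fig1_toy() -> MultiplexNetwork:
    """Deterministic 12-node two-layer toy network.

    Two dense blocks of six nodes in the ``black`` layer (fully connected
    within each block, plus one reciprocal bridge), and a sparse ``red``
    layer whose 18 edges overlap black edges only inside the first block
    (across its two halves).  With the red layer as null network, exclusion
    mode at ``gamma=1`` splits the overlapped block along the red edges,
    while inclusion mode keeps it intact.  The edge list ships with the
    package as ``data/fig1_toy.csv``.
    """
    from .io import read_multiplex  # local import: io depends on multiplex only

    ref = resources.files("multifacet").joinpath("data/fig1_toy.csv")
    with resources.as_file(ref) as path:
        return read_multiplex(path)
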