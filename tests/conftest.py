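"""Shared fixture builders.

Everything here is generated programmatically and seeded; no stored data
beyond the packaged 12-node toy edge list.
"""

from __future__ import annotations

import numpy as np
import pytest

from multifacet import Layer, ModularityMatrix, MultiplexNetwork, Partition


def raw_matrix(B: np.ndarray, L: float = 1.0) -> ModularityMatrix:
    """Wrap a bare real matrix as a ModularityMatrix for optimizer tests."""
    B = np.asarray(B, dtype=float)
    return ModularityMatrix(
        B=B,
        node_order=tuple(range(B.shape[0])),
        L=float(L),
        gamma=1.0,
        mode="custom",
        observed_layers=(),
        null_layers=(),
    )


def random_binary_layer(rng: np.random.Generator, n: int, p: float, name: str = "x") -> Layer:
    w = (rng.random((n, n)) < p).astype(float)
    np.fill_diagonal(w, 0.0)
    nodes = tuple(f"v{i + 1:02d}" for i in range(n))
    return Layer(name=name, node_order=nodes, weights=w)


def random_multiplex(rng: np.random.Generator, n: int = 10, n_layers: int = 3) -> MultiplexNetwork:
    nodes = tuple(f"v{i + 1:02d}" for i in range(n))
    layers = []
    for l in range(n_layers):
        w = (rng.random((n, n)) < rng.uniform(0.2, 0.6)).astype(float)
        np.fill_diagonal(w, 0.0)
        if w.sum() == 0:  # guarantee positive mass
            w[0, 1] = 1.0
        layers.append(Layer(name=f"l{l + 1}", node_order=nodes, weights=w))
    return MultiplexNetwork.from_layers(layers)


def planted_two_block_matrix(
    rng: np.random.Generator, n: int = 8, noise: float = 0.4
) -> tuple[ModularityMatrix, np.ndarray]:
    """Modularity-like matrix with a planted 2-block optimum plus noise."""
    labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
    B = np.where(labels[:, None] == labels[None, :], 1.0, -1.0)
    B = B + rng.normal(0.0, noise, (n, n))
    np.fill_diagonal(B, 0.0)
    return raw_matrix(B, L=float(n)), labels


def overlap_contrast_multiplex(seed: int = 1) -> tuple[MultiplexNetwork, Partition]:
    """Two-layer multiplex with overlap concentrated in two of three blocks.

    Blocks A and B (10 nodes each, dense) are joined by 60 deterministic
    cross edges, every one of which also carries a ``red`` (second-layer)
    edge; half of A's and B's internal edges are red too.  Block C (sparser)
    has no red edges at all.  The construction makes the three null modes
    pull in known directions: the exclusion null cuts along overlapping
    edges, the configuration model recovers the three blocks, and the
    complement (inclusion) null pulls the fully-overlapped A-B cross edges
    inside communities.
    """
    rng = np.random.default_rng(seed)
    n = 30
    blocks = np.repeat([1, 2, 3], 10)
    within = blocks[:, None] == blocks[None, :]
    off = ~np.eye(n, dtype=bool)
    in_a = (blocks[:, None] == 1) & (blocks[None, :] == 1)
    in_b = (blocks[:, None] == 2) & (blocks[None, :] == 2)
    in_c = (blocks[:, None] == 3) & (blocks[None, :] == 3)
    p = np.where(in_a | in_b, 0.7, np.where(in_c, 0.35, 0.02))
    p = np.where(within, p, 0.02)
    black = ((rng.random((n, n)) < p) & off).astype(float)
    cross_ab = np.zeros((n, n), dtype=bool)
    for a in range(10):
        for t in range(3):
            cross_ab[a, 10 + (a + t) % 10] = True
            cross_ab[10 + a, (a + t) % 10] = True
    black[cross_ab] = 1.0
    other_ab = ((blocks[:, None] == 1) & (blocks[None, :] == 2)) | (
        (blocks[:, None] == 2) & (blocks[None, :] == 1)
    )
    black[other_ab & ~cross_ab] = 0.0
    red = ((black > 0) & (in_a | in_b) & (rng.random((n, n)) < 0.5)).astype(float)
    red[cross_ab] = 1.0
    nodes = tuple(f"v{i + 1:02d}" for i in range(n))
    M = MultiplexNetwork.from_layers(
        [Layer("black", nodes, black), Layer("red", nodes, red)]
    )
    return M, Partition.from_labels(nodes, blocks)


def pooled_within_overlap(M: MultiplexNetwork, part: Partition, base: str, cond: str) -> float:
    """Overlap probability pooled over all within-community ordered pairs."""
    A = M.layer(base).weights
    C = M.layer(cond).weights
    lab = part.labels_for(M.nodes)
    same = lab[:, None] == lab[None, :]
    denom = (A * same).sum()
    return float((A * C * same).sum() / denom)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240624)
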