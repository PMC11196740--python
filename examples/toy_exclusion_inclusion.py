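"""Exclusion vs inclusion nulls on the packaged 12-node toy network.

The toy has two dense blocks in the `black` layer; `red` edges overlap black
edges only across the two halves of the first block.  Using the red layer as
an empirical null network flips the meaning of those overlapping edges:
exclusion mode treats them as weak ties and cuts the block apart, inclusion
mode treats them as strong multidimensional ties and keeps it whole.
"""

from multifacet import (
    configuration_null,
    exclusion_matrix,
    fig1_toy,
    inclusion_matrix,
    louvain,
    overlap_probability,
)

M = fig1_toy()
print(f"toy network: N={M.n_nodes}, layers={M.layer_names}")
print(f"global P(red|black) = {overlap_probability(M, 'black', 'red'):.4f}\n")

for label, Bm in [
    ("configuration (NG)", configuration_null(M.layer("black"))),
    ("exclusion  (null = red)", exclusion_matrix(M, "black", "red", gamma=1.0)),
    ("inclusion  (null = ~red)", inclusion_matrix(M, "black", "red", gamma=1.0)),
]:
    res = louvain(Bm, seed=1, restarts=20)
    overlaps = overlap_probability(M, "black", "red", res.partition)
    shown = {k: "NA" if v is None else f"{v:.3f}" for k, v in overlaps.items()}
    print(f"{label:26s} Q={res.Q:.4f} K={res.partition.K}")
    print(f"{'':26s} communities={res.partition.communities()}")
    print(f"{'':26s} within-module P(red|black)={shown}\n")

print(
    "Exclusion separates v01-v03 from v04-v06 (their connecting edges are\n"
    "red-overlapped), driving within-module overlap to zero; inclusion keeps\n"
    "the overlapped block intact."
)
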