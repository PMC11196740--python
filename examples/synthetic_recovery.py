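"""Planted-block recovery and module characterization on synthetic data.

Generates a 67-node, two-layer directed multiplex with six planted blocks
(layer 1 about 300 edges, layer 2 about 440, overlap concentrated within
blocks), recovers the blocks with the classical configuration-model null,
and prints the per-module summary table: size, local modularity Q_c, and the
within-module probability that a layer-1 edge co-occurs with a layer-2 edge.
"""

from multifacet import (
    SyntheticSpec,
    configuration_null,
    generate,
    louvain,
    module_summary,
    nmi,
    overlap_probability,
    total_weight,
)

spec = SyntheticSpec(seed=1)
M, truth = generate(spec)
print(
    f"synthetic multiplex: N={M.n_nodes}, "
    f"L1={total_weight(M.layer('l1')):.0f}, L2={total_weight(M.layer('l2')):.0f}, "
    f"global P(l2|l1)={overlap_probability(M, 'l1', 'l2'):.3f}"
)

Bm = configuration_null(M.layer("l1"))
res = louvain(Bm, seed=101, restarts=20)
print(f"NG detection: Q={res.Q:.4f} K={res.partition.K} "
      f"NMI vs planted truth={nmi(res.partition, truth):.3f}\n")

print("module  n_members  Q_c       P(l2|l1)")
for row in module_summary(Bm, M, res.partition, "l1", "l2"):
    overlap = "NA" if row.overlap_prob is None else f"{row.overlap_prob:.3f}"
    print(f"{row.community_id:>6d}  {row.n_members:>9d}  {row.Q_c:.6f}  {overlap}")
print("\nSum of Q_c equals the global Q; overlap is higher inside blocks"
      " because layer-2 edges were copied from layer-1 edges there.")
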