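"""Which layer shapes the merged network's community structure most?

Merges a three-layer synthetic multiplex into one weighted directed network,
takes its configuration-model (NG) community structure as the baseline, then
re-detects communities while promoting each layer and each pair of layers
via the weighted-complement null.  A high NMI against the baseline means the
promoted layer(s) pull the communities in the same direction as plain edge
density, i.e. similar cohesive forces shape the modules.
"""

from multifacet import SyntheticSpec, generate
from multifacet.evaluate import all_subsets_up_to, layer_contribution_scan

# noisier blocks than the defaults, so the layers genuinely disagree about
# the mesostructure and promoting them visibly shifts the communities
spec = SyntheticSpec(
    layer_probs=((0.25, 0.05), (0.10, 0.06), (0.08, 0.05)),
    overlap_rho=(0.6, 0.3),
    seed=1,
)
M, _ = generate(spec)
names = list(M.layer_names)
candidates = all_subsets_up_to(names, max_size=2)

baseline, rows = layer_contribution_scan(
    M, names, candidates, gamma=1.0, seed=5, restarts=20
)
print(f"merged {'+'.join(names)}: baseline NG Q={baseline.Q:.4f} "
      f"K={baseline.partition.K}\n")
print("promoted    Q_multi   NMI vs NG")
for row in rows:
    name = "+".join(row.promoted_layers)
    if row.error:
        print(f"{name:10s}  (degenerate null: {row.error})")
    else:
        print(f"{name:10s}  {row.Q:.4f}    {row.nmi_vs_baseline:.4f}")
print("\nEach row re-optimizes modularity with the weighted complement of the"
      "\npromoted layer(s) as null network; rows share one optimizer seed so"
      "\nthey are directly comparable.")
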