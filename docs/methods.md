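# Methods

## Model and assumptions

A multiplex network here is a family of directed graphs `G_α` on one shared,
ordered node set `V` (|V| = N), with no interlayer edges and no self-loops.
Each layer is stored as a dense `N×N` non-negative weight matrix; undirected
input is stored symmetrically, so the undirected case needs no special
handling anywhere downstream. Layer merging is elementwise summation: in a
merge of `m` binary layers, a pair's weight is the number of dimensions in
which it is connected (maximum `m`).

Community structure is scored by directed modularity

    Q = (1/L) Σ_{i,j} (A_ij − P_ij) δ(c_i, c_j),   L = Σ_ij A_ij,

summed over ordered pairs including `i = j`. The method's point is the
choice of the null network `P`:

* **ng** — configuration model. With total (in+out) strengths
  `k_i = Σ_j A_ij + Σ_j A_ji` (which sum to `2L`), the default
  (`degree_mode="as_printed"`) is `P_ij = k_i k_j / (2·2L)`. On a
  symmetrically stored undirected graph this is exactly the textbook
  `k_i k_j / 2m`, and in all cases `Σ_ij P_ij = L` exactly, so observed and
  null networks carry equal mass. `degree_mode="directed"` gives the
  Leicht–Newman form `P_ij = k_i^out k_j^in / L`, also mass-preserving. The
  `k_i k_j` diagonal terms are kept, as in the standard configuration model;
  only here does `B` have a nonzero diagonal.
* **exclusion** — `P` is another empirical layer of the same multiplex,
  rescaled (below). Edges of the observed layer that overlap null-layer
  edges lose weight in `B`; null-only pairs go negative. Maximizing `Q`
  therefore cuts modules along overlapping edges.
* **inclusion** — `P` is the complement graph of a binary layer
  (off-diagonal `1−A`). The penalty falls on observed edges *missing* from
  the null layer, so overlapping (multidimensional) edges become the strong
  ties that hold modules together.
* **multi** — observed is a weighted merge of layers; `P` is the weighted
  complement `max_ij(A^null) − A^null_ij` of a sub-merge (diagonal forced to
  zero; the max is taken over the specific sub-merge being complemented).
  Pairs connected in all promoted dimensions incur no penalty, absent pairs
  the maximal one; intermediate weights get the residual to the maximum.

### Null-mass normalization and γ

Every empirical null is normalized to the observed layer's mass before the
strength parameter is applied: `P = γ · (L/Σ P_raw) · P_raw`, so
`Σ P = γ·L`, and `B(γ) = A − γ(A − B(1))` is affine in γ. The order of
operations (normalize first, then scale by γ) makes `γ = 1` the exact
equal-weight point: when observed and null layers have equal density, the
scaled null entries are exactly 0/1 and the entries of `B` fall into the
three interpretable cases 0 (overlap, no surplus), +1 (observed-only
surplus) and −1 (null-only deficit). The reference mass is always the
*observed* network's `L`, in all modes.

Practical consequence of the normalization: a sparse null layer yields large
per-edge penalties (strong interference with the structure — small γ steps
already fragment modules), while a dense null such as a complement graph
yields small per-edge penalties (mild interference; γ can be raised without
destroying the partition). Degenerate inputs are refused explicitly: an
empty null (or the complement of a saturated merge) raises a dedicated
error rather than producing a zero matrix.

## Optimization

A generalized two-phase Louvain procedure operates on arbitrary real
matrices. Since `Q` sums over ordered pairs it is invariant under
symmetrization, so the optimizer works on `B' = (B + Bᵀ)/2`:

* **Local moving.** Starting from singletons, nodes are visited in a
  (seeded) shuffled order; node `i` moves to the community maximizing its
  summed `B'` weight to members. Moves require a strictly positive gain
  (> 1e−12 tie tolerance); ties keep the current community, otherwise the
  lowest community label wins. A node whose best attainable neighbourhood
  weight is negative detaches into a free singleton slot — necessary for
  matrices with negative entries, where the classical algorithm would trap
  nodes in harmful communities.
* **Aggregation.** Communities collapse into coarse nodes whose matrix sums
  all `B'` entries between (and within, as self-loops) communities,
  preserving `L`; self-loops move with their node and never affect move
  gains. Levels repeat until no move improves `Q`.
* **Restarts.** The default 20 restarts re-shuffle the visiting order from
  one seeded stream and the best-`Q` partition is returned (first found on
  ties). Empirical-null landscapes are rugged — sparse nulls at higher γ
  produce many small modules — hence the multi-restart default.
  `node_order="sorted"` gives a seed-independent single deterministic run.

Results are bit-reproducible for identical `(B, seed, restarts,
node_order)`. The returned `Q` is always recomputed from scratch from the
original (unsymmetrized) matrix. Community ids are canonicalized to `1..K`
by first appearance in sorted node order, so structurally equal partitions
compare equal.

`exhaustive_best_partition` enumerates all set partitions (refused above
N = 10, Bell(10) = 115 975) as the ground-truth oracle; ties break toward
fewer communities, then the lexicographically smallest label string.

## Evaluation measures

* **NMI** uses the confusion-matrix form
  `−2 ΣΣ N_ij log(N_ij N / (N_i· N_·j))` over
  `Σ N_i· log(N_i·/N) + Σ N_·j log(N_·j/N)` with natural logarithms (the
  ratio is base-invariant; fixing the base makes intermediate values
  reproducible) and `0·log 0 = 0`. Structurally identical partitions return
  exactly 1 (this also covers the two-whole-set case, where both sums are
  zero); plain (unadjusted) NMI is used throughout.
* **Overlap probability** `P(l_m | l_k)` counts directed ordered pairs — a
  reciprocal dyad contributes two trials, consistent with `L` counting
  directed edges. Per-community values are restricted to within-community
  pairs; a community with no internal base edges reports an undefined
  marker (`None` in memory, `NA` in files), never 0, since 0 is an
  informative value ("edges present, none overlapping").
* **Layer-contribution scan** detects the configuration-model baseline on
  the merged network, then one `multi`-mode detection per promoted subset.
  All rows share a single optimizer seed (derived from the scan seed) so
  that rows differ only in their null network; degenerate subsets are
  reported per-row instead of failing the scan.

## Synthetic generator

`SyntheticSpec`/`generate` draw layer 1 as a directed planted-partition
graph and build later layers by copying each layer-1 edge with probability
`rho_within` or `rho_between` (by block position of the pair) plus
independent noise edges. Copying is deliberate: the methods exist because
edge overlap in real multiplexes concentrates inside cohesive groups rather
than falling uniformly, and independent layers cannot reproduce that.

Defaults emulate a small organizational multiplex: 67 actors in six blocks
(12+5×11), layer 1 with `p_within = 0.35`, `p_between = 0.02` (≈300 directed
edges), layer 2 copying at `rho = (0.8, 0.2)` plus noise `(0.15, 0.035)`
(≈400 directed edges, global overlap ≈0.7 concentrated within blocks).
These sizes mirror the densities of the directed organizational networks the
method targets. All randomness flows from one `SeedSequence` with one
spawned child stream per layer, so generator and optimizer seeds never
collide and adding a layer never perturbs earlier ones.

What the generator does **not** emulate: degree heterogeneity (no hubs),
reciprocity preference, weighted ties, block-dependent overlap, or missing
actors per layer. Passing tests therefore demonstrate correctness of the
machinery and the *direction* of each null's effect, not performance on
degree-heterogeneous or attribute-driven real data.

The packaged `fig1_toy` (12 nodes, two layers, shipped as
`data/fig1_toy.csv`) is a behaviour-equivalent illustration, constructed —
not measured — so that the red layer overlaps exactly the cross-half edges
of one black block: exclusion at γ=1 must split that block and inclusion
must keep it. The overlap-direction test fixture extends the same idea to
three blocks with 60 deterministic fully-overlapped cross edges between two
of them, making the expected ordering (exclusion < NG < inclusion of
within-module overlap) a structural property rather than a sampling
accident.

## Numerical choices and degenerate inputs

* Tie tolerance 1e−12 in the optimizer and exhaustive tie-breaks; null-mass
  conservation holds to 1e−9·L (it is exact up to rounding).
* Diagonals: layers, complements and empirical nulls are zero-diagonal by
  construction; only the configuration null carries diagonal terms (see
  above).
* Binary complements require exactly 0/1 weights and direct the caller to
  the weighted complement otherwise; weighted complements of all-zero
  layers, empty nulls, and `observed = null` in exclusion/inclusion mode are
  errors, as is γ < 0.
* Louvain gain uses community weight sums only; `L` rescales `Q` but never
  changes the argmax.
* File outputs use fixed 6-decimal formatting, `NA` for undefined values,
  and canonical sorted orderings, so identical runs are byte-identical.

## Problem sizes

Unit and property tests run on 4–30-node fixtures (exhaustive oracles up to
N = 10, Louvain-vs-exhaustive on 100 seeded instances at N ≤ 8); generator
and recovery tests use the 67-node default spec; the examples use the toy
network, the 67-node default, and a noisier 67-node three-layer variant.
The full suite completes in a few seconds on one CPU.

## Known limitations

* The optimizer is greedy; different visit orders can return different
  near-optimal partitions, so exact module memberships on real data are not
  reproducible across implementations — only `Q`-level and statistical
  behaviour are. Leiden-style refinement and multiresolution (RB/AFG)
  variants of the random null are out of scope.
* Plain modularity's resolution limit applies to the `ng` mode; empirical
  nulls change, but do not remove, scale effects.
* No interlayer edges, temporal layers, overlapping communities, or
  significance testing of `Q`; NMI is unadjusted for chance.
* Dense-matrix storage: intended for networks up to a few thousand nodes.
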