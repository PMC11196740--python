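# multifacet

Community detection in **multiplex networks** with **empirical null
networks**: find groups of nodes that share — or deliberately avoid —
*multiple facets* of connectivity at once.

## The problem

Real social and organizational systems are multiplex: the same actors are
linked by several kinds of directed ties (cooperation, friendship, advice,
esteem, …), one network layer per tie type. Classical modularity-based
community detection looks at one layer at a time and compares it against a
*random* null model, so it is blind to whether the edges inside a community
overlap across layers. But overlap is often exactly what matters: a working
group whose members are also friends behaves differently from one whose
members merely cooperate.

`multifacet` is for network scientists and organizational analysts who want
community structure defined *relative to another layer* of the same
multiplex, not relative to chance.

## The model

Modularity of a partition `c(·)` of a directed network with adjacency `A`,
total weight `L = Σᵢⱼ Aᵢⱼ` and null network `P` is

    Q = (1/L) Σᵢⱼ (Aᵢⱼ − Pᵢⱼ) δ(cᵢ, cⱼ),

maximized over partitions via a generalized Louvain procedure that accepts
any real modularity matrix `B = A − P`. The package provides four nulls:

| mode        | observed `A`        | null `P`                                  | communities …                         |
|-------------|---------------------|-------------------------------------------|---------------------------------------|
| `ng`        | one layer (or merge)| configuration model `kᵢkⱼ`-product        | are density-based (classical)         |
| `exclusion` | layer `l_k`         | γ · layer `l_m` (another empirical layer) | avoid `l_m`-overlap on their edges    |
| `inclusion` | layer `l_k`         | γ · complement graph of `l_m`             | favour `l_m`-overlapping edges        |
| `multi`     | weighted layer merge| γ · weighted complement of a sub-merge    | promote the chosen layers' edges      |

Every empirical null is rescaled so `Σ Pᵢⱼ = γ·L`: at `γ = 1` the observed
and null networks carry equal weight, and `γ` tunes how strongly the null is
taken into account. Binary complements flip edges and non-edges; the
weighted complement is `max(A) − A` off the diagonal, so pairs connected in
every promoted dimension incur no penalty.

Detected structures are characterized by local modularity `Q_c` (each
community's additive share of `Q`), the within-module edge-overlap
probability `P(l_m | l_k)` (fraction of `l_k` edges inside a module that
co-occur with an `l_m` edge on the same ordered pair), and normalized mutual
information (NMI) between partitions.

## Worked example

The packaged 12-node toy network has two dense blocks in its `black` layer;
`red` edges overlap black edges only across the two halves of the first
block (`python examples/toy_exclusion_inclusion.py`):

```
toy network: N=12, layers=('black', 'red')
global P(red|black) = 0.2903

configuration (NG)         Q=0.4677 K=2   within-module P(red|black)={1: 0.600, 2: 0.000}
exclusion  (null = red)    Q=0.7097 K=2   within-module P(red|black)={1: 0.000, 2: 0.000}
inclusion  (null = ~red)   Q=0.5993 K=2   within-module P(red|black)={1: 0.600, 2: 0.000}
```

The configuration model returns the two blocks, with 60% red overlap inside
the first. Exclusion mode treats overlapping edges as weak ties and splits
that block along them (`v04–v06` separate; within-module overlap drops to
zero), while inclusion mode treats them as strong multidimensional ties and
keeps the block intact. The same machinery scales up: the synthetic
generator (`examples/synthetic_recovery.py`) produces a 67-node two-layer
multiplex (≈300/≈400 directed edges, overlap concentrated within six planted
blocks) whose blocks NG detection recovers with NMI 1.000, and
`examples/layer_contribution_scan.py` ranks promoted layer subsets of a
three-layer merge by the NMI of their communities against the NG baseline
(0.78–0.92 on its fixture).

There is also a thin CLI over the same functions:

```bash
multifacet detect --input net.csv --mode exclusion \
    --observed cooperation --null friendship --gamma 1.0 --out-prefix run
multifacet scan-layers --input net.csv --observed l1,l2,l3 --out scan.csv
multifacet compare run_partition.csv other_partition.csv
```

Input is a layered edge list (`source,target,layer[,weight]` CSV); all
outputs are plain delimited text, byte-identical across reruns of the same
seed and configuration.

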