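# coevonet

Do interacting proteins have more similar evolutionary histories than chance
would predict? `coevonet` answers this question the way it must be asked on
a network: it compares the phylogenetic tree topologies (and presence/absence
orthologue profiles) of interacting protein pairs against **structured
random-graph null models** that preserve successively more of the empirical
network — because "expected by chance" means something different once degree
heterogeneity and biological annotations are taken into account.

It is aimed at molecular evolution and systems-biology researchers with a
protein interaction network, one rooted tree topology per protein (over a
small species panel), and optional presence/absence profiles and categorical
annotations.

## The statistic

For two rooted, multifurcating, leaf-labelled topologies restricted to their
`n ≥ 3` shared species, the edit distance `η` is the minimum number of
*neighbour moves* — single-species rearrangements across one internal node
(detach a leaf to its grandparent, push it into a sibling clade, or bracket
a sibling pair) — transforming one into the other. It is normalized to the
similarity

```
Γ = 1 − η / M_n,      M_n = 1 + (n−1)(n−2)/2
```

so trees sharing different numbers of species become comparable
(`M_3..M_10 = 2, 4, 7, 11, 16, 22, 29, 37`). Profiles are compared by
Hamming difference and Jaccard index/distance on presence and absence sets.

Edge-level statistics (proportion of matching topologies, mean `η`, mean
`Γ`, mean profile difference) are then recomputed over graphs sampled from
five ensembles — uniform random graph, node shuffle (traits permuted,
adjacency fixed), network shuffle (degree-preserving rewiring), and their
annotation-constrained variants — and the empirical value is located in the
null distribution with an add-one permutation p-value.

A synthetic-data generator produces complete datasets (panel, profiles,
trees, sparse network, annotations) with a tunable planted co-evolution
signal (`coupling_rho`: complex-like modules share a perturbed intermediate
tree), so the whole pipeline is testable without any downloads.

## Worked example

```python
from coevonet import (SimConfig, simulate_dataset, run_ensemble, EnsembleSpec)

cfg = SimConfig(n_proteins=200, coupling_rho=0.8, seed=11)  # planted signal
ds = simulate_dataset(cfg)
rep = run_ensemble(ds.graph, EnsembleSpec(model="node_shuffle",
                                          samples=500, seed=3))
print(rep.statistics["mean_similarity"])
```

prints (reformatted)

```
empirical           0.8740
null_mean           0.8405
null_sd             0.0120
empirical_quantile  0.998
p_greater           0.0040
```

The mean tree similarity over interacting pairs (Γ = 0.874, from 325
comparable tree pairs; 38 edges lacked a tree, 37 shared fewer than 3
species) sits above every null quantile but 0.2% of the 500 trait-permuted
graphs: the planted co-evolution of interacting modules is detected at
p ≈ 0.004. With `coupling_rho=0` the same pipeline returns uniform
p-values (type-I control is part of the test suite).

The same analysis runs from the shell on tab-separated files:

```sh
coevonet simulate --seed 11 --out data/
coevonet summary --network data/edges.tsv --trees data/trees.nwk \
    --profiles data/profiles.tsv --panel data/panel.tsv
coevonet ensemble --network data/edges.tsv --trees data/trees.nwk \
    --profiles data/profiles.tsv --classes data/classes.tsv \
    --panel data/panel.tsv --model network_shuffle --samples 1000 \
    --seed 7 --out report.json
coevonet compare-trees "((1,3),(2,4,5))" "((1,2),(5,(3,4)))"   # eta = 5
coevonet count --max-n 10
```

Real data are ingested in the same formats: an edge-list TSV, a
`protein<TAB>newick` topology file (branch lengths ignored), a 0/1 profile
matrix, a panel definition, and a per-protein annotation table.

## Layout

```
src/coevonet/
  topology.py    canonical topologies, neighbour moves, eta, Gamma
  counts.py      counting + exhaustive enumeration (the test oracle)
  profiles.py    phylogenetic profiles and pair measures
  graphio.py     ProteinGraph (networkx) + TSV/Newick readers and writers
  ensembles.py   the five null-model samplers
  pipeline.py    edge statistics, exclusion accounting, permutation tests
  simulate.py    synthetic datasets with planted co-evolution
  cli.py         command-line interface
docs/methods.md  models, numerical choices, limitations
```
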