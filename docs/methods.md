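# Methods

`coevonet` tests whether the phylogenetic trees (and presence/absence
profiles) of interacting proteins are more similar than expected under
structured random-graph null models. This note documents the models, the
numerical choices, and what the synthetic data can and cannot show.

## Tree topologies and the neighbour-move metric

A topology is a rooted, leaf-labelled, multifurcating tree without branch
lengths; every internal node has at least two children. Topologies are held
in a canonical form (children sorted by smallest leaf label, then canonical
text), so equality is string equality of the canonical text and all
algorithms operate on hashable nested tuples.

Two topologies on the same leaf set are **neighbours** when one elementary
rearrangement of a single species converts one into the other:

* **PROMOTE** — detach a leaf from its parent `P` and re-attach it to `P`'s
  parent, splicing `P` out if it is left with one child;
* **DEMOTE** — detach a leaf and re-attach it as an extra child of a sibling
  internal node (only when the parent keeps at least two children — the
  spliced variant has no inverse single-leaf move, and its resulting
  topology is reachable by PROMOTE anyway);
* **GROUP** — bracket a sibling pair, at least one of which is a leaf, under
  a new internal node, when the parent has at least three children.

Every move is invertible (PROMOTE-with-splice ↔ GROUP, PROMOTE-without-splice
↔ DEMOTE), so the relation is symmetric and the shortest-path length `η`
in the neighbour graph is a metric. `η` between two trees with different
leaf sets is defined after restricting both to their shared species; at
least 3 shared species are required, otherwise the pair is *incomparable*.

The normalized similarity is

    Γ = 1 − η / M_n ,   M_n = 1 + (n−1)(n−2)/2 ,

with `n` the number of shared species. `M_n` is the published maximum-score
sequence (2, 4, 7, 11, 16, 22, 29, 37 for n = 3..10), anchored at `M_3 = 2`
with increments `n − 1`. The exhaustively computed diameter of the
neighbour graph equals `M_n` for n = 3 and n = 4. For n ≥ 5 the true
diameter under this move set is smaller (6 at n = 5, 10 at n = 6, vs the
printed 7 and 11): an extensive search over symmetric variants of the move
vocabulary found no relation that reproduces both the published worked
examples (the three-neighbour list and the distance-5 example) and the
printed maxima at n ≥ 5, so the printed column is treated as an analytic
upper bound used for normalization. Since `η ≤ diameter ≤ M_n`, `Γ` always
stays in [0, 1]; the normalizer is simply slightly conservative for n ≥ 5.

Distances are computed by bidirectional breadth-first search over canonical
texts, expanding the smaller frontier layer by layer and returning the
minimum meeting length at the first layer with a meeting (this is exact for
layer-synchronized bidirectional BFS). A state budget (default 2·10⁶
generated states) guards the worst case on 8–10 species; an exhausted
budget classifies the pair as *unresolved*, which the pipeline counts and
excludes rather than hanging. Neighbour sets are memoized (LRU, 2¹⁷
entries) because ensemble runs revisit the same region of topology space.

## Counting and enumeration

Rooted bifurcating topologies are counted by the double factorial
`(2n−3)!!`. Multifurcating topologies with `m` internal nodes satisfy

    T(n, m) = (n + m − 2)·T(n−1, m−1) + m·T(n−1, m),  T(1, 0) = 1:

the n-th leaf either subdivides one of the `n + m − 2` edges or attaches to
one of the `m` internal nodes. `enumerate_topologies(n ≤ 7)` realizes the
same insertion argument explicitly with canonical deduplication and is the
brute-force oracle: enumerated totals and per-`m` censuses match the
recursion for all n ≤ 6 (4, 26, 236, 2,752 trees for n = 3..6), and the
neighbour-graph diameters reported above are all-pairs BFS over these
spaces (scipy.sparse.csgraph on the sparse adjacency).

## Profiles

A phylogenetic profile is a 0/1 vector over the non-focal panel species
(the focal species trivially contains its own proteins). All-zero profiles
are non-informative and excluded from pairwise statistics. Pair measures:
Hamming difference (0..panel−1), and Jaccard index/distance on the presence
sets and on the absence sets (both index and distance are reported; an
empty union leaves the measure undefined and it is skipped with
accounting).

## Null models

Five ensembles preserve the node set and edge count of the empirical graph
`G` and never mutate it:

| model | preserved | randomized |
|---|---|---|
| `random_graph` | n, m, traits on nodes | all edges (uniform G(n, m)) |
| `node_shuffle` | adjacency matrix | trait bundles (uniform permutation) |
| `network_shuffle` | degree of every node, traits | edges (double-edge swaps) |
| `bio_node_shuffle` | adjacency, class labels per position | trait bundles within classes |
| `bio_network_shuffle` | degrees, multiset of edge classes | edges (class-constrained swaps) |

The edge class is the unordered pair of endpoint labels for the chosen
characteristic; missing labels form the class `"unknown"`. Swap chains run
for `swaps_per_edge × m` accepted swaps (default 10×m) plus a random parity
bit — without the parity bit a fixed accepted count fixes the reachable
half of tiny two-state constrained spaces; rejected proposals (self-loop,
duplicate, or class-breaking) are resampled, and a sample is emitted with a
warning if the quota is not met within 100× the quota in attempts. Swap
chains are the standard mixing heuristic, not an exactly-uniform sampler of
the constrained space; tests assert exact constraint preservation and full
support on enumerable toys, not exact uniformity. Connectivity is not
preserved (empirical interactomes are themselves fragmented).

## Resampling pipeline

`edge_trait_summary` walks each edge once: profile statistics over edges
with two informative profiles, tree statistics over edges whose trees share
≥ 3 species. Every edge is accounted for exactly once in the tree
statistics or in one of three exclusion counters (no tree / fewer than 3
shared species / distance unresolved); the accounting identity is asserted
on construction. Tree-pair comparisons are memoized across a run keyed by
the unordered pair of canonical texts; the cache provably cannot change
results and tests verify this.

`run_ensemble` computes the statistic per sampled graph and then locates
the empirical value in that per-graph distribution (matching box-plot-style
per-graph averages; samples are never pooled). Significance uses the
add-one permutation p-value `p = (1 + #{null ≥ observed}) / (N + 1)`
(never exactly zero; two-sided by tail doubling, capped at 1). Reports
serialize deterministically under a fixed seed; wall-clock time is logged,
not serialized, so repeated runs are byte-identical.

## Synthetic data

The generator emulates a small-panel comparative study: a 10-species panel
with one focal species; per-protein orthologue retention `r ~ Beta(5, 2)`
(mean presence 9·5/7 ≈ 6.4 species — most proteins keep orthologues in
most species, a minority in few); a sparse network (uniform G(n, m) at mean
degree 4 by default, or a heavy-tailed configuration model); one random
bifurcating reference tree per dataset; and protein trees obtained by
restricting the reference to each protein's present species and applying a
Poisson(2) number of random neighbour moves. Proteins with fewer than
three present species get no tree, reproducing both real-data exclusion
sources (missing trees, too few shared species) without a separate knob.

Planted co-evolution (`coupling_rho`): each edge is flagged with
probability ρ, and flagged edges agglomerate their endpoints into
complex-like modules of at most 12 proteins (modules merge while under the
cap). Each module has one intermediate tree perturbed from the reference;
members derive their trees from it (restricted to their species, plus
Poisson(0.5) extra moves each), so edges inside a module carry a pairwise
tree-similarity signal in exactly the metric the pipeline measures. The
intermediate's divergence counts only moves visible at the species coverage
of a typical (median) member, because restriction erases moves among absent
species and a plain full-panel walk would under-express the declared
divergence. The module cap sits where the fraction of intra-module edges
saturates (≈ 0.43 at ρ = 0.8) while modules remain small relative to the
proteome; at ρ = 0.8 roughly 40–45% of edges are intra-module, which is
what the power properties below are calibrated against.

All randomness flows through named SeedSequence sub-streams (reference,
profiles, network, classes, coupling flags, tree noise), so datasets are
bit-reproducible and the coupled-edge sets are nested across ρ at a fixed
seed.

What the generator does *not* emulate: orthology-call errors, correlated
retention across interacting proteins, realistic complex size
distributions, expression-level confounding, or non-uniform annotation
classes. Passing tests therefore demonstrate that the pipeline measures and
calibrates correctly under its stated model — not that real interactomes
carry (or lack) a co-evolution signal.

## Statistical properties checked

* Type-I error: under ρ = 0 the dataset is exchangeable under trait
  permutation, so the add-one p-value at a nominal 0.05 rejects with
  probability exactly 10/201 per replicate; the suite checks 200 replicate
  datasets (24 proteins each, 200-sample ensembles) against the binomial
  99% band.
* Power: under ρ = 0.8 at 200 proteins, the empirical mean Γ exceeds the
  null 95th percentile in ≥ 90% of 50 replicates (node-shuffle null,
  200 samples). The study size was fixed by a pilot power analysis on
  seeds disjoint from the test seeds.
* Monotonicity: mean edge Γ is non-decreasing in ρ (up to a small
  Monte-Carlo allowance; the effect saturates once most eligible proteins
  are in modules).

## Problem sizes and runtime

Exhaustive spaces are used through n = 6 (2,752 topologies; the all-pairs
BFS diameter takes a few seconds via scipy). Enumeration refuses n > 7.
The statistical studies run at 24–200 proteins with 200-sample ensembles;
these sizes resolve the planted effect while keeping the full suite in the
minutes range on one CPU.

## Known limitations

* `M_n` for n ≥ 5 exceeds the true neighbour-graph diameter (see above), so
  Γ compresses slightly toward 1 for large shared-species counts.
* Swap-based rewiring is not exactly uniform over the degree-constrained
  graph space (known bias of naive swap chains).
* Distances on 8–10 shared species between very distant trees can hit the
  search budget; such pairs are counted as unresolved and excluded.
* Multi-label annotations must be reduced upstream to one label per
  characteristic per protein.
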