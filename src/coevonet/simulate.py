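"""Synthetic datasets: panel, profiles, protein trees, network, annotations.

The generator emulates the statistical shape of a small-panel comparative
study: a 10-species panel with one focal species, per-protein orthologue
retention drawn from a Beta law (so most proteins keep orthologues in most
species, some in few), protein trees that are neighbour-move perturbations of
a single reference species tree restricted to each protein's present species,
a sparse interaction network (uniform or heavy-tailed configuration model),
and uniform categorical annotations.

The planted co-evolution signal is controlled by ``coupling_rho``: each edge
is independently flagged co-evolving with that probability, and flagged
edges agglomerate their endpoint proteins into small co-evolving modules
(complex-like clusters of at most ``coupling_cluster_max`` members).  Every
member of a module derives its tree from the module's shared perturbed
intermediate (plus a few extra moves each) instead of an independent
perturbation of the reference, so edges internal to a module carry a
pairwise tree-similarity signal.  Because the perturbation kernel is exactly
the neighbour-move relation the pipeline measures with, the planted signal
lives in the metric being tested.  Missing trees arise organically from
profiles with fewer than three present species, reproducing both real-data
exclusion sources without a separate knob.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np

from . import graphio
from .graphio import ProteinGraph
from .profiles import PhyloProfile, SpeciesPanel, default_panel
from .topology import TreeTopology, _canonicalize, _raw_neighbours, restrict

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_reference_tree",
    "simulate_profiles",
    "simulate_protein_tree",
    "apply_random_moves",
    "simulate_network",
    "simulate_dataset",
    "write_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset.

    Defaults describe a small comparative panel: 10 species (one focal),
    Beta(5, 2) orthologue retention (mean presence 9 * 5/7 ~ 6.4 species),
    a sparse network of mean degree 4, protein trees a Poisson(2) number of
    neighbour moves away from the restricted reference, and no planted
    coupling (``coupling_rho = 0``).
    """

    n_proteins: int = 100
    n_species: int = 10
    network_model: str = "er"
    target_mean_degree: float = 4.0
    retention_alpha: float = 5.0
    retention_beta: float = 2.0
    divergence_moves_mean: float = 2.0
    coupling_rho: float = 0.0
    coupling_extra_moves_mean: float = 0.5
    coupling_cluster_max: int = 12
    n_classes: int = 4
    characteristics: tuple[str, ...] = ("process", "complex")
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if self.n_species < 4:
            raise ValueError("need at least 4 panel species (3 non-focal)")
        if self.network_model not in ("er", "configuration"):
            raise ValueError("network_model must be 'er' or 'configuration'")
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must be in [0, 1]")
        for name, value in (
            ("target_mean_degree", self.target_mean_degree),
            ("retention_alpha", self.retention_alpha),
            ("retention_beta", self.retention_beta),
            ("n_classes", self.n_classes),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.divergence_moves_mean < 0 or self.coupling_extra_moves_mean < 0:
            raise ValueError("move means must be non-negative")
        if self.coupling_cluster_max < 2:
            raise ValueError("coupling_cluster_max must be >= 2")

    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(1, self.n_proteins + 1)]


def _bifurcating_insertions(node, label: str) -> list:
    """All raw trees from bracketing ``label`` with one existing subtree."""
    out = [(node, label)]
    if isinstance(node, tuple):
        for i, child in enumerate(node):
            for sub in _bifurcating_insertions(child, label):
                out.append(node[:i] + (sub,) + node[i + 1 :])
    return out


def simulate_reference_tree(
    panel: SpeciesPanel, rng: np.random.Generator
) -> TreeTopology:
    """A random rooted bifurcating topology on the non-focal panel species,
    grown by uniform random leaf attachment (the dataset's species tree)."""
    labels = panel.non_focal
    if len(labels) < 3:
        raise ValueError("panel too small for a reference tree")
    node = labels[0]
    for label in labels[1:]:
        options = _bifurcating_insertions(node, label)
        node = options[int(rng.integers(len(options)))]
    return TreeTopology(node)


def simulate_profiles(
    config: SimConfig, rng: np.random.Generator, panel: Optional[SpeciesPanel] = None
) -> dict[str, PhyloProfile]:
    """Per-protein presence vectors: retention probability r ~ Beta(alpha,
    beta), presence ~ Bernoulli(r) per non-focal species.  All-zero profiles
    are kept (and flagged non-informative downstream)."""
    if panel is None:
        panel = default_panel(config.n_species)
    out: dict[str, PhyloProfile] = {}
    width = panel.profile_length
    for pid in config.protein_ids():
        r = rng.beta(config.retention_alpha, config.retention_beta)
        presence = tuple(int(x) for x in (rng.random(width) < r))
        out[pid] = PhyloProfile(protein_id=pid, presence=presence, panel=panel)
    return out


def apply_random_moves(
    t: TreeTopology, k: int, rng: np.random.Generator
) -> TreeTopology:
    """Apply ``k`` uniformly random neighbour moves to ``t``."""
    node, text = t.root, t.canonical_text
    for _ in range(k):
        options = sorted(_raw_neighbours(node))
        text, node = options[int(rng.integers(len(options)))]
    return TreeTopology._from_canonical(node, text)


def _perturb_visible(
    t: TreeTopology,
    visibility_set: frozenset,
    k: int,
    rng: np.random.Generator,
    max_extra_steps: int = 4,
) -> TreeTopology:
    """Random neighbour walk on ``t`` until ``k`` moves have visibly changed
    the restriction to ``visibility_set`` (at most ``k + max_extra_steps``
    steps in total).

    Restriction erases moves among absent species, so a plain ``k``-move
    walk on the full tree under-expresses the declared divergence on the
    species subsets where trees are actually compared.  Counting visible
    moves (at the coverage scale of a typical profile) keeps the divergence
    parameter meaningful while the step cap bounds the total drift.  Falls
    back to a plain walk when the visibility set is too small to restrict to.
    """
    if k == 0:
        return t
    if len(visibility_set & t.leaf_set) < 3:
        return apply_random_moves(t, k, rng)
    current = t
    current_vis = restrict(current, visibility_set)
    visible = 0
    for _ in range(k + max_extra_steps):
        nxt = apply_random_moves(current, 1, rng)
        nxt_vis = restrict(nxt, visibility_set)
        if nxt_vis != current_vis:
            visible += 1
        current, current_vis = nxt, nxt_vis
        if visible >= k:
            break
    return current


def simulate_protein_tree(
    reference: TreeTopology,
    profile: PhyloProfile,
    k_moves: int,
    rng: np.random.Generator,
) -> Optional[TreeTopology]:
    """Restrict the reference tree to the profile's present species and apply
    ``k_moves`` random neighbour moves; ``None`` (no tree) when fewer than
    three species are present."""
    present = profile.present_species & reference.leaf_set
    if len(present) < 3:
        return None
    return apply_random_moves(restrict(reference, present), k_moves, rng)


def _heavy_tailed_degrees(
    n: int, target_mean: float, rng: np.random.Generator
) -> list[int]:
    """Zipf(2.5) degrees clipped to [1, n-1], nudged to an even total of
    about n * target_mean while keeping the heavy tail."""
    deg = np.minimum(rng.zipf(2.5, size=n), n - 1).astype(int)
    target_sum = int(round(n * target_mean / 2.0)) * 2
    total = int(deg.sum())
    while total != target_sum:
        i = int(rng.integers(n))
        if total < target_sum and deg[i] < n - 1:
            deg[i] += 1
            total += 1
        elif total > target_sum and deg[i] > 1:
            deg[i] -= 1
            total -= 1
    return deg.tolist()


def simulate_network(
    config: SimConfig, rng: np.random.Generator
) -> ProteinGraph:
    """A simple undirected network on the configured protein ids.

    ``er``: exactly ``round(n * mean_degree / 2)`` edges placed uniformly.
    ``configuration``: heavy-tailed degree sequence realized by the
    configuration model, then simplified (loops and multi-edges dropped), so
    the realized size falls slightly short of the target.
    """
    ids = config.protein_ids()
    n = len(ids)
    g = nx.Graph()
    g.add_nodes_from(ids)
    if config.network_model == "er":
        m = int(round(config.target_mean_degree * n / 2.0))
        m = min(m, n * (n - 1) // 2)
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < m:
            i = int(rng.integers(n))
            j = int(rng.integers(n))
            if i != j:
                chosen.add((i, j) if i < j else (j, i))
        g.add_edges_from((ids[i], ids[j]) for i, j in chosen)
    else:
        deg = _heavy_tailed_degrees(n, config.target_mean_degree, rng)
        multi = nx.configuration_model(deg, seed=int(rng.integers(2**31 - 1)))
        simple = nx.Graph(multi)
        simple.remove_edges_from(nx.selfloop_edges(simple))
        g.add_edges_from((ids[u], ids[v]) for u, v in simple.edges())
    return g


@dataclass(frozen=True)
class SyntheticDataset:
    """A complete simulated study: network, profiles, trees, annotations."""

    config: SimConfig
    panel: SpeciesPanel
    reference_tree: TreeTopology
    graph: ProteinGraph
    profiles: dict[str, PhyloProfile]
    trees: dict[str, TreeTopology]
    classes: dict[str, dict[str, str]]


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a full dataset bundle, deterministic under ``config.seed``.

    Independent sub-streams drive the reference tree, profiles, network,
    annotations, coupling decisions and tree noise, so nested coupled-edge
    sets are obtained across ``coupling_rho`` values at a fixed seed.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_ref, s_prof, s_net, s_cls, s_coup, s_tree) = ss.spawn(6)
    rng_ref = np.random.default_rng(s_ref)
    rng_prof = np.random.default_rng(s_prof)
    rng_net = np.random.default_rng(s_net)
    rng_cls = np.random.default_rng(s_cls)
    rng_coup = np.random.default_rng(s_coup)
    rng_tree = np.random.default_rng(s_tree)

    panel = default_panel(config.n_species)
    reference = simulate_reference_tree(panel, rng_ref)
    profiles = simulate_profiles(config, rng_prof, panel)
    graph = simulate_network(config, rng_net)

    classes: dict[str, dict[str, str]] = {}
    for pid in config.protein_ids():
        classes[pid] = {
            char: f"{char}_c{int(rng_cls.integers(config.n_classes)) + 1}"
            for char in config.characteristics
        }

    # Planted co-evolution: edges flagged with probability rho agglomerate
    # their endpoints into small co-evolving modules; each module shares one
    # perturbed intermediate tree from which all member trees derive.
    trees: dict[str, TreeTopology] = {}
    cluster_of: dict[str, int] = {}
    clusters: list[list[str]] = []
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    cap = config.coupling_cluster_max
    for u, v in edges:
        if rng_coup.random() >= config.coupling_rho:
            continue
        cu, cv = cluster_of.get(u), cluster_of.get(v)
        if cu is None and cv is None:
            cluster_of[u] = cluster_of[v] = len(clusters)
            clusters.append([u, v])
        elif cu is not None and cv is None and len(clusters[cu]) < cap:
            cluster_of[v] = cu
            clusters[cu].append(v)
        elif cv is not None and cu is None and len(clusters[cv]) < cap:
            cluster_of[u] = cv
            clusters[cv].append(u)
        elif (
            cu is not None
            and cv is not None
            and cu != cv
            and len(clusters[cu]) + len(clusters[cv]) <= cap
        ):
            # merge the two modules the edge bridges
            for w in clusters[cv]:
                cluster_of[w] = cu
            clusters[cu].extend(clusters[cv])
            clusters[cv] = []
        # else both endpoints already placed (or the module is full): the
        # edge stays co-evolving only if both ended up in the same module.
    for members in clusters:
        if not members:  # emptied by a merge
            continue
        k = int(rng_tree.poisson(config.divergence_moves_mean))
        # visibility at the coverage scale of a typical (median) member
        member_sets = sorted(
            (profiles[w].present_species for w in members),
            key=lambda s: (len(s), sorted(s)),
        )
        vis = member_sets[len(member_sets) // 2]
        intermediate = _perturb_visible(reference, vis, k, rng_tree)
        for w in members:
            present = profiles[w].present_species & intermediate.leaf_set
            if len(present) < 3:
                continue
            t = restrict(intermediate, present)
            extra = int(rng_tree.poisson(config.coupling_extra_moves_mean))
            trees[w] = apply_random_moves(t, extra, rng_tree)
    for pid in config.protein_ids():
        if pid in cluster_of:
            continue
        k = int(rng_tree.poisson(config.divergence_moves_mean))
        t = simulate_protein_tree(reference, profiles[pid], k, rng_tree)
        if t is not None:
            trees[pid] = t

    for pid in graph.nodes:
        graph.nodes[pid]["profile"] = profiles[pid]
        graph.nodes[pid]["classes"] = classes[pid]
        if pid in trees:
            graph.nodes[pid]["tree"] = trees[pid]

    return SyntheticDataset(
        config=config,
        panel=panel,
        reference_tree=reference,
        graph=graph,
        profiles=profiles,
        trees=trees,
        classes=classes,
    )


def write_dataset(ds: SyntheticDataset, outdir: Union[str, PathLike]) -> None:
    """Write the bundle as edges.tsv, trees.nwk, profiles.tsv, classes.tsv,
    panel.tsv and manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graphio.write_edge_list(ds.graph, outdir / "edges.tsv")
    graphio.write_trees(ds.trees, outdir / "trees.nwk")
    graphio.write_profiles(ds.profiles, outdir / "profiles.tsv")
    graphio.write_classes(ds.classes, outdir / "classes.tsv")
    graphio.write_panel(ds.panel, outdir / "panel.tsv")
    manifest = {
        "config": dataclasses.asdict(ds.config),
        "reference_tree": ds.reference_tree.canonical_text + ";",
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def load_dataset(indir: Union[str, PathLike]) -> ProteinGraph:
    """Re-read a written bundle into an attribute-laden graph."""
    indir = Path(indir)
    panel = graphio.read_panel(indir / "panel.tsv")
    g = graphio.read_edge_list(indir / "edges.tsv")
    graphio.attach_attributes(
        g,
        trees_path=indir / "trees.nwk",
        profiles_path=indir / "profiles.tsv",
        classes_path=indir / "classes.tsv",
        panel=panel,
    )
    return g
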