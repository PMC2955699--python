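"""Protein-graph data model and tab-delimited readers/writers.

The in-memory container is a :class:`networkx.Graph` whose nodes are protein
ids (opaque, case-sensitive strings) and whose node attributes hold the
biological traits used downstream:

* ``tree`` - a :class:`~coevonet.topology.TreeTopology` (optional),
* ``profile`` - a :class:`~coevonet.profiles.PhyloProfile` (optional),
* ``classes`` - ``dict`` mapping characteristic name -> categorical label.

Graphs are simple: self-interactions and duplicate edges are dropped on read
(with a logged count).  All files are UTF-8, tab-delimited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from os import PathLike
from typing import Optional, Union

import networkx as nx
import pandas as pd

from .profiles import PhyloProfile, SpeciesPanel
from .topology import TreeTopology, parse_topology

__all__ = [
    "ProteinGraph",
    "GraphSummary",
    "read_edge_list",
    "write_edge_list",
    "read_panel",
    "write_panel",
    "read_profiles",
    "write_profiles",
    "read_trees",
    "write_trees",
    "read_classes",
    "write_classes",
    "attach_attributes",
    "graph_summary",
]

logger = logging.getLogger(__name__)

PathArg = Union[str, PathLike]

#: A protein interaction network: a simple undirected networkx graph with
#: per-node ``tree`` / ``profile`` / ``classes`` attributes.
ProteinGraph = nx.Graph


def read_edge_list(path: PathArg) -> ProteinGraph:
    """Read a two-column (protein_a, protein_b) TSV into a simple graph.

    No header row; extra columns are ignored; duplicate edges and self-loops
    are dropped and counted in the log.  An empty file yields an empty graph.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment="#", skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        return nx.Graph()
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs at least 2 columns")
    g = nx.Graph()
    self_loops = 0
    duplicates = 0
    for a, b in df.iloc[:, :2].itertuples(index=False):
        if a == b:
            self_loops += 1
            continue
        if g.has_edge(a, b):
            duplicates += 1
            continue
        g.add_edge(a, b)
    if self_loops or duplicates:
        logger.info(
            "read_edge_list(%s): dropped %d self-loops and %d duplicate edges",
            path,
            self_loops,
            duplicates,
        )
    return g


def write_edge_list(g: ProteinGraph, path: PathArg) -> None:
    """Write the graph's edges as a headerless two-column TSV (sorted)."""
    rows = sorted(tuple(sorted(e)) for e in g.edges())
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_panel(path: PathArg) -> SpeciesPanel:
    """Read a species-panel TSV with columns ``species`` and ``is_focal``."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    if "species" not in df.columns or "is_focal" not in df.columns:
        raise ValueError(f"{path}: panel file needs 'species' and 'is_focal' columns")
    focal = df.loc[df["is_focal"].astype(int) == 1, "species"]
    if len(focal) != 1:
        raise ValueError(f"{path}: exactly one focal species required")
    return SpeciesPanel(species=tuple(df["species"]), focal=focal.iloc[0])


def write_panel(panel: SpeciesPanel, path: PathArg) -> None:
    pd.DataFrame(
        {
            "species": list(panel.species),
            "is_focal": [int(s == panel.focal) for s in panel.species],
        }
    ).to_csv(path, sep="\t", index=False)


def read_profiles(
    path: PathArg, panel: Optional[SpeciesPanel] = None
) -> dict[str, PhyloProfile]:
    """Read a 0/1 profile matrix TSV: first column protein id, one column per
    non-focal species.

    If ``panel`` is given, the columns must match its non-focal species (any
    order); otherwise a panel is synthesized from the columns with an implicit
    focal species named ``_focal``.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    id_col = df.columns[0]
    species_cols = list(df.columns[1:])
    if panel is None:
        panel = SpeciesPanel(species=("_focal", *species_cols), focal="_focal")
    else:
        if set(species_cols) != set(panel.non_focal):
            raise ValueError(f"{path}: profile columns do not match the panel")
    ordered = list(panel.non_focal)
    out: dict[str, PhyloProfile] = {}
    for _, row in df.iterrows():
        pid = str(row[id_col])
        if pid in out:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        presence = tuple(int(row[s]) for s in ordered)
        out[pid] = PhyloProfile(protein_id=pid, presence=presence, panel=panel)
    return out


def write_profiles(profiles: dict[str, PhyloProfile], path: PathArg) -> None:
    if not profiles:
        raise ValueError("no profiles to write")
    panel = next(iter(profiles.values())).panel
    rows = [
        {"protein_id": pid, **dict(zip(panel.non_focal, p.presence))}
        for pid, p in sorted(profiles.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_trees(path: PathArg) -> dict[str, TreeTopology]:
    """Read a per-line ``protein_id<TAB>newick`` topology file."""
    out: dict[str, TreeTopology] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>newick'")
            pid, newick = parts
            if pid in out:
                raise ValueError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            out[pid] = parse_topology(newick)
    return out


def write_trees(trees: dict[str, TreeTopology], path: PathArg) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, tree in sorted(trees.items()):
            fh.write(f"{pid}\t{tree.canonical_text};\n")


def read_classes(path: PathArg) -> dict[str, dict[str, str]]:
    """Read a classes TSV: protein id column plus one column per
    characteristic.  Empty cells become the label ``"unknown"``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = df.columns[0]
    chars = list(df.columns[1:])
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        pid = str(row[id_col])
        if pid in out:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        out[pid] = {
            c: (row[c] if isinstance(row[c], str) and row[c] != "" else "unknown")
            for c in chars
        }
    return out


def write_classes(classes: dict[str, dict[str, str]], path: PathArg) -> None:
    if not classes:
        raise ValueError("no classes to write")
    chars = sorted({c for labels in classes.values() for c in labels})
    rows = [
        {"protein_id": pid, **{c: labels.get(c, "unknown") for c in chars}}
        for pid, labels in sorted(classes.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def attach_attributes(
    g: ProteinGraph,
    trees_path: Optional[PathArg] = None,
    profiles_path: Optional[PathArg] = None,
    classes_path: Optional[PathArg] = None,
    panel: Optional[SpeciesPanel] = None,
) -> ProteinGraph:
    """Attach tree/profile/class attributes to graph nodes by protein id.

    Ids present in an attribute file but absent from the graph are logged and
    ignored; graph nodes without a tree remain valid (their edge comparisons
    are excluded later, with accounting).  Returns ``g`` (modified in place).
    """
    if trees_path is not None:
        trees = read_trees(trees_path)
        _attach(g, trees, "tree")
    if profiles_path is not None:
        profiles = read_profiles(profiles_path, panel=panel)
        _attach(g, profiles, "profile")
    if classes_path is not None:
        classes = read_classes(classes_path)
        _attach(g, classes, "classes")
    return g


def _attach(g: ProteinGraph, mapping: dict, attr: str) -> None:
    unmatched = [pid for pid in mapping if pid not in g]
    if unmatched:
        logger.info(
            "attach_attributes: %d %s ids not in graph (e.g. %s)",
            len(unmatched),
            attr,
            unmatched[:3],
        )
    for pid, value in mapping.items():
        if pid in g:
            g.nodes[pid][attr] = value


@dataclass(frozen=True)
class GraphSummary:
    """Whole-graph statistics: order, size, components, degrees, clustering.

    The clustering coefficient is the average local clustering over nodes of
    degree >= 2 (nodes that cannot close a triangle are excluded; 0.0 if no
    such node exists).
    """

    proteins: int
    interactions: int
    components: int
    maximum_degree: int
    mean_degree: float
    clustering_coefficient: float

    def as_dict(self) -> dict:
        return asdict(self)


def graph_summary(g: ProteinGraph) -> GraphSummary:
    n = g.number_of_nodes()
    m = g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    eligible = [v for v, d in g.degree() if d >= 2]
    clustering = (
        float(sum(nx.clustering(g, eligible).values()) / len(eligible))
        if eligible
        else 0.0
    )
    return GraphSummary(
        proteins=n,
        interactions=m,
        components=nx.number_connected_components(g) if n else 0,
        maximum_degree=max(degrees, default=0),
        mean_degree=(2.0 * m / n) if n else 0.0,
        clustering_coefficient=clustering,
    )
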