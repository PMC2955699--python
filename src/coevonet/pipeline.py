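"""Edge-level trait statistics and ensemble-based significance testing.

For one graph, :func:`edge_trait_summary` walks every edge once and records
profile statistics (Hamming difference, Jaccard on presence and absence) over
edges where both endpoints carry informative profiles, and tree statistics
(match proportion, edit distance ``eta``, similarity ``Gamma``) over edges
whose endpoint trees share at least three species.  Edges excluded from the
tree statistics are accounted for exactly: either an endpoint has no tree,
the trees share fewer than three species, or (rare, budget-capped searches)
the distance was left unresolved.

:func:`run_ensemble` repeats the summary over graphs drawn from a null model
and locates the empirical value within the sampled null distribution using
add-one permutation p-values: ``p = (1 + #{null >= observed}) / (N + 1)``
(never exactly zero, two-sided by tail doubling).  Statistics are computed
per sampled graph and then summarized, mirroring per-graph-average boxplots,
not pooled across samples.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import profiles as _profiles
from .ensembles import EnsembleSpec, sample_ensemble
from .graphio import ProteinGraph
from .topology import (
    ComparisonResult,
    UnresolvedDistanceError,
    compare,
    DEFAULT_NODE_BUDGET,
)

__all__ = [
    "TraitSummary",
    "EnsembleReport",
    "DistanceCache",
    "edge_trait_summary",
    "run_ensemble",
    "empirical_p_value",
]

logger = logging.getLogger(__name__)

#: Statistics compared against the null distribution in an EnsembleReport.
REPORT_STATISTICS = (
    "mean_profile_difference",
    "mean_jaccard_presence",
    "mean_jaccard_absence",
    "proportion_matching",
    "mean_eta",
    "mean_similarity",
)


class DistanceCache:
    """Memoizes tree-pair comparisons across a run, keyed by the unordered
    pair of canonical texts.  Purely an optimization: results are identical
    with or without it."""

    def __init__(self, node_budget: int = DEFAULT_NODE_BUDGET):
        self.node_budget = node_budget
        self._store: dict[tuple[str, str], Optional[ComparisonResult]] = {}

    def compare(self, a, b) -> Optional[ComparisonResult]:
        """Comparison result, or ``None`` if the search budget was exhausted."""
        ka, kb = a.canonical_text, b.canonical_text
        key = (ka, kb) if ka <= kb else (kb, ka)
        if key not in self._store:
            try:
                result = compare(a, b, node_budget=self.node_budget)
            except UnresolvedDistanceError:
                logger.warning("distance unresolved for pair %s | %s", ka, kb)
                result = None
            self._store[key] = result
        return self._store[key]


@dataclass(frozen=True)
class TraitSummary:
    """Per-graph edge-level statistics with full exclusion accounting.

    The accounting identity ``n_tree_pairs_compared + n_excluded_no_tree +
    n_excluded_shared_lt3 + n_excluded_unresolved == n_edges`` always holds.
    Mean statistics are ``None`` when no eligible pair exists.
    """

    n_edges: int
    n_profile_pairs_compared: int
    mean_profile_difference: Optional[float]
    profile_difference_histogram: tuple[int, ...]
    mean_jaccard_presence: Optional[float]
    mean_jaccard_absence: Optional[float]
    n_tree_pairs_compared: int
    n_excluded_no_tree: int
    n_excluded_shared_lt3: int
    n_excluded_unresolved: int
    proportion_matching: Optional[float]
    mean_eta: Optional[float]
    mean_similarity: Optional[float]
    shared_species_histogram: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        total = (
            self.n_tree_pairs_compared
            + self.n_excluded_no_tree
            + self.n_excluded_shared_lt3
            + self.n_excluded_unresolved
        )
        if total != self.n_edges:
            raise ValueError(
                f"exclusion accounting broken: {total} != {self.n_edges} edges"
            )
        if sum(self.shared_species_histogram.values()) != self.n_tree_pairs_compared:
            raise ValueError("shared-species histogram does not sum to comparisons")
        if sum(self.profile_difference_histogram) != self.n_profile_pairs_compared:
            raise ValueError("profile histogram does not sum to comparisons")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["profile_difference_histogram"] = list(self.profile_difference_histogram)
        d["shared_species_histogram"] = {
            str(k): v for k, v in sorted(self.shared_species_histogram.items())
        }
        return d


def _mean(values: list) -> Optional[float]:
    return float(np.mean(values)) if values else None


def edge_trait_summary(
    g: ProteinGraph,
    cache: Optional[DistanceCache] = None,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> TraitSummary:
    """Summarize profile and tree similarity over the edges of ``g``.

    Profile and tree eligibility are assessed independently per edge; a
    shared :class:`DistanceCache` may be passed to reuse tree comparisons
    across the many graphs of an ensemble run.
    """
    if cache is None:
        cache = DistanceCache(node_budget=node_budget)
    n_edges = 0
    diffs: list[int] = []
    jacc_p: list[float] = []
    jacc_a: list[float] = []
    hist_len = 0
    etas: list[int] = []
    gammas: list[float] = []
    matches = 0
    no_tree = 0
    lt3 = 0
    unresolved = 0
    shared_hist: dict[int, int] = {}

    for u, v in g.edges():
        n_edges += 1
        pu = g.nodes[u].get("profile")
        pv = g.nodes[v].get("profile")
        if (
            pu is not None
            and pv is not None
            and _profiles.is_informative(pu)
            and _profiles.is_informative(pv)
            and pu.panel == pv.panel
        ):
            hist_len = max(hist_len, pu.panel.profile_length + 1)
            diffs.append(_profiles.profile_difference(pu, pv))
            jp = _profiles.jaccard_presence(pu, pv)
            if jp is not None:
                jacc_p.append(jp.index)
            ja = _profiles.jaccard_absence(pu, pv)
            if ja is not None:
                jacc_a.append(ja.index)

        tu = g.nodes[u].get("tree")
        tv = g.nodes[v].get("tree")
        if tu is None or tv is None:
            no_tree += 1
            continue
        result = cache.compare(tu, tv)
        if result is None:
            unresolved += 1
            continue
        if result.status == "incomparable":
            lt3 += 1
            continue
        shared_hist[result.shared_species_count] = (
            shared_hist.get(result.shared_species_count, 0) + 1
        )
        etas.append(result.eta)
        gammas.append(result.similarity)
        if result.status == "match":
            matches += 1

    hist = [0] * hist_len
    for d in diffs:
        hist[d] += 1
    n_tree = len(etas)
    return TraitSummary(
        n_edges=n_edges,
        n_profile_pairs_compared=len(diffs),
        mean_profile_difference=_mean(diffs),
        profile_difference_histogram=tuple(hist),
        mean_jaccard_presence=_mean(jacc_p),
        mean_jaccard_absence=_mean(jacc_a),
        n_tree_pairs_compared=n_tree,
        n_excluded_no_tree=no_tree,
        n_excluded_shared_lt3=lt3,
        n_excluded_unresolved=unresolved,
        proportion_matching=(matches / n_tree) if n_tree else None,
        mean_eta=_mean(etas),
        mean_similarity=_mean(gammas),
        shared_species_histogram=shared_hist,
    )


def empirical_p_value(
    empirical_value: float, null_values: Sequence[float], side: str = "greater"
) -> float:
    """Add-one permutation p-value of the empirical value under the null.

    ``p = (1 + #{null at least as extreme}) / (N + 1)``; ``side`` is one of
    ``greater``, ``less`` or ``two_sided`` (tail doubling, capped at 1).
    """
    nulls = np.asarray(null_values, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null sample")
    n = nulls.size
    p_greater = (1 + int(np.sum(nulls >= empirical_value))) / (n + 1)
    p_less = (1 + int(np.sum(nulls <= empirical_value))) / (n + 1)
    if side == "greater":
        return p_greater
    if side == "less":
        return p_less
    if side == "two_sided":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValueError(f"unknown side {side!r}")


@dataclass(frozen=True)
class EnsembleReport:
    """Empirical trait summary located within a sampled null distribution."""

    empirical: TraitSummary
    samples: tuple[TraitSummary, ...]
    statistics: dict[str, dict]
    metadata: dict

    def to_json(self, include_samples: bool = True, indent: int = 2) -> str:
        payload = {
            "metadata": self.metadata,
            "empirical": self.empirical.as_dict(),
            "statistics": self.statistics,
        }
        if include_samples:
            payload["samples"] = [s.as_dict() for s in self.samples]
        return json.dumps(payload, indent=indent, sort_keys=True)

    def samples_table(self) -> list[dict]:
        """One row of per-graph statistics per null sample (for TSV export)."""
        rows = []
        for i, s in enumerate(self.samples):
            row = {"sample": i}
            for stat in REPORT_STATISTICS:
                row[stat] = getattr(s, stat)
            rows.append(row)
        return rows


def run_ensemble(
    g: ProteinGraph,
    spec: EnsembleSpec,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> EnsembleReport:
    """Draw ``spec.samples`` null graphs, summarize each, and compare the
    empirical summary with the null distribution of every statistic."""
    start = time.perf_counter()
    cache = DistanceCache(node_budget=node_budget)
    empirical = edge_trait_summary(g, cache=cache)
    summaries = [
        edge_trait_summary(h, cache=cache) for h in sample_ensemble(g, spec)
    ]

    statistics: dict[str, dict] = {}
    for stat in REPORT_STATISTICS:
        emp = getattr(empirical, stat)
        nulls = [x for s in summaries if (x := getattr(s, stat)) is not None]
        if emp is None or not nulls:
            continue
        arr = np.asarray(nulls, dtype=float)
        statistics[stat] = {
            "empirical": float(emp),
            "null_mean": float(arr.mean()),
            "null_sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "null_n": int(arr.size),
            "empirical_quantile": float(np.mean(arr <= emp)),
            "p_greater": empirical_p_value(emp, arr, "greater"),
            "p_less": empirical_p_value(emp, arr, "less"),
            "p_two_sided": empirical_p_value(emp, arr, "two_sided"),
        }

    metadata = {
        "model": spec.model,
        "characteristic": spec.characteristic,
        "samples": spec.samples,
        "seed": spec.seed,
        "swaps_per_edge": spec.swaps_per_edge,
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
    logger.info(
        "run_ensemble(%s, samples=%d, seed=%s) finished in %.2fs",
        spec.model,
        spec.samples,
        spec.seed,
        time.perf_counter() - start,
    )
    return EnsembleReport(
        empirical=empirical,
        samples=tuple(summaries),
        statistics=statistics,
        metadata=metadata,
    )
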