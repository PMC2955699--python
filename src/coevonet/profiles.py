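"""Phylogenetic profiles: presence/absence of orthologues over a species panel.

A profile records, for one focal-species protein, in which of the other panel
species an orthologue was identified.  Profiles of all zeros carry no signal
(the protein would have been excluded upstream) and are flagged
non-informative; pairwise statistics require both profiles informative and on
the same panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "SpeciesPanel",
    "PhyloProfile",
    "Jaccard",
    "profile_difference",
    "jaccard_presence",
    "jaccard_absence",
    "is_informative",
]


@dataclass(frozen=True)
class SpeciesPanel:
    """An ordered panel of species with one focal species.

    Profiles are defined over the non-focal species only: the focal species
    trivially contains every one of its own proteins.
    """

    species: tuple[str, ...]
    focal: str

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names in panel")
        if len(self.species) < 2:
            raise ValueError("panel needs at least 2 species")
        if self.focal not in self.species:
            raise ValueError(f"focal species {self.focal!r} not in panel")

    @property
    def non_focal(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s != self.focal)

    @property
    def profile_length(self) -> int:
        return len(self.species) - 1


def default_panel(n_species: int = 10) -> SpeciesPanel:
    """A generic panel of ``n_species`` named sp01.. with sp01 focal."""
    names = tuple(f"sp{i:02d}" for i in range(1, n_species + 1))
    return SpeciesPanel(species=names, focal=names[0])


@dataclass(frozen=True)
class PhyloProfile:
    """Presence/absence vector of one protein's orthologues over a panel."""

    protein_id: str
    presence: tuple[int, ...]
    panel: SpeciesPanel = field(compare=False)

    def __post_init__(self):
        if len(self.presence) != self.panel.profile_length:
            raise ValueError(
                f"profile length {len(self.presence)} != panel size - 1 "
                f"({self.panel.profile_length})"
            )
        if any(v not in (0, 1) for v in self.presence):
            raise ValueError("profile values must be 0 or 1")

    @property
    def present_species(self) -> frozenset[str]:
        nf = self.panel.non_focal
        return frozenset(nf[i] for i, v in enumerate(self.presence) if v)

    @property
    def n_present(self) -> int:
        return int(sum(self.presence))


def is_informative(p: PhyloProfile) -> bool:
    """False iff the profile is all zeros (no orthologue anywhere)."""
    return any(p.presence)


def _check_pair(p: PhyloProfile, q: PhyloProfile) -> None:
    if p.panel != q.panel:
        raise ValueError("profiles are on different panels")
    if not (is_informative(p) and is_informative(q)):
        raise ValueError("non-informative (all-zero) profile in comparison")


def profile_difference(p: PhyloProfile, q: PhyloProfile) -> int:
    """Hamming distance: species where exactly one protein has an orthologue.

    Ranges from 0 (orthologues in exactly the same species) to panel-1 (every
    species covered by exactly one of the two proteins).
    """
    _check_pair(p, q)
    a = np.asarray(p.presence, dtype=np.int8)
    b = np.asarray(q.presence, dtype=np.int8)
    return int(np.sum(a != b))


class Jaccard(NamedTuple):
    """Jaccard index |X&Y|/|X|Y| and its complement distance 1 - index."""

    index: float
    distance: float


def _jaccard(x: frozenset, y: frozenset) -> Optional[Jaccard]:
    union = x | y
    if not union:
        return None
    idx = len(x & y) / len(union)
    return Jaccard(index=idx, distance=1.0 - idx)


def jaccard_presence(p: PhyloProfile, q: PhyloProfile) -> Optional[Jaccard]:
    """Jaccard index/distance of the species sets where orthologues are present.

    Returns ``None`` when both presence sets are empty (undefined).
    """
    if p.panel != q.panel:
        raise ValueError("profiles are on different panels")
    return _jaccard(p.present_species, q.present_species)


def jaccard_absence(p: PhyloProfile, q: PhyloProfile) -> Optional[Jaccard]:
    """Jaccard index/distance of the species sets where orthologues are absent."""
    if p.panel != q.panel:
        raise ValueError("profiles are on different panels")
    nf = frozenset(p.panel.non_focal)
    return _jaccard(nf - p.present_species, nf - q.present_species)
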