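"""Ortholog-group categorisation and representative selection.

Ortholog groups (InParanoid-style clusters of yeast/human proteins,
optionally joined to worm, fly and fish members) are categorised by
mRNA-binding status: a group counts as mRNA binding in a species when
at least one of its members of that species is in the species'
complete interactome list.  Groups binding in both yeast and human
form the conserved core interactome.  For sequence-level analyses each
group is represented per organism by its longest member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

__all__ = [
    "Member",
    "OrthologGroupSet",
    "categorize_groups",
    "core_interactome",
    "select_representative",
    "select_cross_species_ortholog",
]

logger = logging.getLogger(__name__)

DEFAULT_SPECIES = ("yeast", "worm", "fly", "fish", "human")

CATEGORIES = ("both", "human_only", "yeast_only", "neither")


class Member(NamedTuple):
    species: str
    protein_id: str
    length: int


@dataclass
class OrthologGroupSet:
    """Clusters of species-tagged proteins keyed by group id."""

    groups: dict[str, list[Member]]
    species: tuple[str, ...] = DEFAULT_SPECIES

    def __post_init__(self) -> None:
        for gid, members in self.groups.items():
            if not members:
                raise ValueError(f"ortholog group {gid!r} has no members")
            for m in members:
                if m.species not in self.species:
                    raise ValueError(
                        f"group {gid!r}: unknown species tag {m.species!r}"
                    )

    def members_of(self, group_id: str, species: str) -> list[Member]:
        return [m for m in self.groups[group_id] if m.species == species]


def categorize_groups(
    groups: OrthologGroupSet,
    yeast_rbps: set,
    human_rbps: set,
    yeast: str = "yeast",
    human: str = "human",
) -> pd.DataFrame:
    """Categorise every group by mRNA binding in yeast and human.

    Returns a frame with columns ``group_id`` and ``category`` in
    {both, human_only, yeast_only, neither}.  A group is mRNA binding
    in a species iff any member of that species is in the species'
    RBP set.  Yeast-only binding groups are biologically unexpected
    (human coverage is deeper) and trigger a warning but are reported
    faithfully.
    """
    for sp in (yeast, human):
        if sp not in groups.species:
            raise ValueError(f"species {sp!r} not declared in the group set")
    rows = []
    for gid, members in groups.groups.items():
        y_hit = any(m.species == yeast and m.protein_id in yeast_rbps for m in members)
        h_hit = any(m.species == human and m.protein_id in human_rbps for m in members)
        if y_hit and h_hit:
            cat = "both"
        elif h_hit:
            cat = "human_only"
        elif y_hit:
            cat = "yeast_only"
        else:
            cat = "neither"
        rows.append((gid, cat))
    out = pd.DataFrame(rows, columns=["group_id", "category"])
    n_yeast_only = int((out["category"] == "yeast_only").sum())
    if n_yeast_only:
        logger.warning("%d groups bind mRNA in yeast but not human", n_yeast_only)
    return out


def core_interactome(
    categories: pd.DataFrame,
    groups: OrthologGroupSet,
    yeast_rbps: set,
    human_rbps: set,
    yeast: str = "yeast",
    human: str = "human",
) -> dict:
    """Extract the conserved core interactome.

    Returns the group ids categorised ``both`` together with the union
    of their RBP members per species.
    """
    core_groups = set(categories.loc[categories["category"] == "both", "group_id"])
    yeast_core: set = set()
    human_core: set = set()
    for gid in core_groups:
        for m in groups.groups[gid]:
            if m.species == yeast and m.protein_id in yeast_rbps:
                yeast_core.add(m.protein_id)
            elif m.species == human and m.protein_id in human_rbps:
                human_core.add(m.protein_id)
    return {
        "core_groups": core_groups,
        "yeast_core": yeast_core,
        "human_core": human_core,
    }


def select_representative(members: Iterable[Member], species: str) -> str:
    """Longest member of ``species``; ties broken by smallest protein id.

    Members with unknown sequence length should be encoded with
    length 0 (they then lose against any sequenced member).
    """
    candidates = [m for m in members if m.species == species]
    if not candidates:
        raise ValueError(f"no member of species {species!r} in group")
    best = min(candidates, key=lambda m: (-m.length, m.protein_id))
    return best.protein_id


def select_cross_species_ortholog(
    yeast_rep: str,
    human_rep: str,
    candidates: Sequence[tuple[str, int, set]],
) -> Optional[str]:
    """Pick the third-species ortholog tied to both anchor representatives.

    Each candidate is (protein_id, length, linked_to) where
    ``linked_to`` is the set of yeast/human proteins the candidate is
    orthologous to.  Among candidates linked to both representatives
    the longest wins (ties by smallest id); None when no candidate
    qualifies.
    """
    qualifying = [
        (pid, length)
        for pid, length, links in candidates
        if yeast_rep in links and human_rep in links
    ]
    if not qualifying:
        return None
    return min(qualifying, key=lambda c: (-c[1], c[0]))[0]
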