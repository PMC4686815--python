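"""Set algebra over interactome gene lists.

Merges per-study RBP lists into "complete" interactome data sets,
computes Venn region counts for two- or three-way comparisons, and
reports the intersection of all lists (the housekeeping interactome).
All identifiers are normalised (whitespace stripped, version suffix
removed, uppercased) before set operations.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["InteractomeList", "normalize_id", "merge_lists", "overlap_counts"]

_VERSION_RE = re.compile(r"\.\d+$")


def normalize_id(gene_id: str) -> str:
    """Strip whitespace and trailing version suffix, uppercase."""
    return _VERSION_RE.sub("", str(gene_id).strip()).upper()


@dataclass
class InteractomeList:
    """A labelled set of gene ids in one declared namespace."""

    label: str
    genes: set
    namespace: str = "gene"

    def __post_init__(self) -> None:
        self.genes = {normalize_id(g) for g in self.genes}


@dataclass
class MergedInteractome:
    label: str
    genes: set
    namespace: str
    membership: pd.DataFrame  # genes x source labels, boolean


def merge_lists(lists: list[InteractomeList], label: str = "merged") -> MergedInteractome:
    """De-duplicated union of interactome lists with per-source membership."""
    if not lists:
        raise ValueError("no lists to merge")
    namespaces = {l.namespace for l in lists}
    if len(namespaces) > 1:
        raise ValueError(f"mixed identifier namespaces: {sorted(namespaces)}")
    union = sorted(set().union(*(l.genes for l in lists)))
    membership = pd.DataFrame(
        {l.label: [g in l.genes for g in union] for l in lists},
        index=pd.Index(union, name="gene"),
    )
    return MergedInteractome(
        label=label, genes=set(union), namespace=lists[0].namespace, membership=membership
    )


def overlap_counts(lists: list[InteractomeList]) -> dict:
    """Exact Venn region counts for 2-3 lists.

    Regions are keyed by the tuple of member labels, e.g.
    ('A',), ('A', 'B'), ('A', 'B', 'C'); each gene is counted in
    exactly one region (the set of lists containing it).  The
    intersection of all lists is additionally reported under
    'housekeeping'.  Region counts sum to the size of the union
    (checked on every call).
    """
    if not 2 <= len(lists) <= 3:
        raise ValueError("overlap_counts supports 2 or 3 lists; use pairwise calls")
    labels = [l.label for l in lists]
    if len(set(labels)) != len(labels):
        raise ValueError("list labels must be unique")
    if len({l.namespace for l in lists}) > 1:
        raise ValueError("mixed identifier namespaces")

    by_label = {l.label: l.genes for l in lists}
    regions: dict[tuple, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(by_label[c] for c in combo))
            outside = set().union(
                *(by_label[c] for c in labels if c not in combo), set()
            )
            regions[combo] = len(inside - outside)
    union = set().union(*by_label.values())
    total = sum(regions.values())
    if total != len(union):
        raise AssertionError(
            f"Venn regions sum to {total}, union has {len(union)} genes"
        )
    housekeeping = set.intersection(*by_label.values())
    return {"regions": regions, "housekeeping": housekeeping, "union_size": len(union)}
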