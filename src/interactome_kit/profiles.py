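"""Crosslink-site aggregation over structured-RNA regions.

iCLIP crosslink-site count tracks are summed per named sub-region of
structured RNAs (e.g. the stems and loops of mitochondrial tRNAs),
normalised against a control library, and pooled across genes into a
generic region profile: mean control-normalised fold enrichment per
region, divided by the region length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CrosslinkTrack",
    "RegionModel",
    "aggregate_by_region",
    "region_enrichment",
    "generic_profile",
]


@dataclass
class CrosslinkTrack:
    """Per-position strand-aware crosslink read counts.

    ``counts`` has columns (reference, pos, strand, count); positions
    are 0-based.  ``library_size`` is the total count over the track.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"reference", "pos", "strand", "count"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"track missing columns: {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise ValueError("crosslink counts must be nonnegative")

    @property
    def library_size(self) -> int:
        return int(self.counts["count"].sum())


@dataclass
class RegionModel:
    """Ordered named sub-regions of structured RNA genes.

    ``regions`` has columns (reference, gene, region, start, end,
    strand) with 0-based half-open intervals; regions of one gene must
    not overlap.  ``region_order`` fixes the generic-profile layout
    (e.g. acceptor stem 5' .. acceptor stem 3' for tRNAs).
    """

    regions: pd.DataFrame
    region_order: tuple = ()

    def __post_init__(self) -> None:
        required = {"reference", "gene", "region", "start", "end", "strand"}
        missing = required - set(self.regions.columns)
        if missing:
            raise ValueError(f"region model missing columns: {sorted(missing)}")
        if (self.regions["end"] <= self.regions["start"]).any():
            raise ValueError("regions must have length >= 1")
        for gene, sub in self.regions.groupby("gene"):
            iv = sub.sort_values("start")[["start", "end"]].to_numpy()
            if (iv[1:, 0] < iv[:-1, 1]).any():
                raise ValueError(f"overlapping regions within gene {gene!r}")
        if not self.region_order:
            self.region_order = tuple(dict.fromkeys(self.regions["region"]))

    def region_lengths(self) -> pd.Series:
        """Generic region lengths: mean interval length per region name."""
        lengths = self.regions["end"] - self.regions["start"]
        return lengths.groupby(self.regions["region"]).mean()


def aggregate_by_region(track: CrosslinkTrack, model: RegionModel) -> dict:
    """Strand-aware per-(gene, region) count sums.

    Returns {'sums': DataFrame(gene, region, count), 'outside': int}
    where 'outside' tallies reads not falling in any region.  Region
    sums plus the outside tally equal the track total.
    """
    tc = track.counts
    model_refs = set(model.regions["reference"])
    track_refs = set(tc["reference"])
    unknown = track_refs - model_refs
    rows = []
    assigned = np.zeros(len(tc), dtype=bool)
    ref_pos = tc["pos"].to_numpy()
    for _, reg in model.regions.iterrows():
        in_reg = (
            (tc["reference"] == reg["reference"]).to_numpy()
            & (tc["strand"] == reg["strand"]).to_numpy()
            & (ref_pos >= reg["start"])
            & (ref_pos < reg["end"])
        )
        if np.any(assigned & in_reg):
            raise ValueError("position assigned to two regions")
        assigned |= in_reg
        rows.append(
            (reg["gene"], reg["region"], int(tc.loc[in_reg, "count"].sum()))
        )
    sums = pd.DataFrame(rows, columns=["gene", "region", "count"])
    outside = int(tc.loc[~assigned, "count"].sum())
    return {"sums": sums, "outside": outside, "unmatched_references": unknown}


def region_enrichment(
    signal: CrosslinkTrack,
    control: CrosslinkTrack,
    model: RegionModel,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Library-size-normalised fold enrichment per (gene, region).

    enrichment = ((signal + pc) / signal_library) /
                 ((control + pc) / control_library).
    A single all-zero track is handled through the pseudocount (its
    library size is clamped to 1); two empty tracks leave the ratio
    undefined and raise.
    """
    sig_n = signal.library_size
    ctl_n = control.library_size
    if sig_n == 0 and ctl_n == 0:
        raise ValueError("both tracks are empty; enrichment undefined")
    # pseudo-library of 1 keeps the ratio finite for an all-zero track
    sig_n = max(sig_n, 1)
    ctl_n = max(ctl_n, 1)
    sig = aggregate_by_region(signal, model)["sums"].rename(columns={"count": "signal"})
    ctl = aggregate_by_region(control, model)["sums"].rename(columns={"count": "control"})
    merged = sig.merge(ctl, on=["gene", "region"], validate="one_to_one")
    merged["enrichment"] = ((merged["signal"] + pseudocount) / sig_n) / (
        (merged["control"] + pseudocount) / ctl_n
    )
    return merged


def generic_profile(
    enrichments: pd.DataFrame,
    model: RegionModel,
    min_signal: int = 1,
) -> dict:
    """Pool per-gene enrichments into a length-normalised generic profile.

    A gene enters the profile when its summed signal over all regions
    reaches ``min_signal`` (the binding filter).  Per generic region
    the profile is the mean over included genes of
    enrichment / region length.  Returns the profile Series (ordered
    by the model's region order) and the gene inclusion list.
    """
    per_gene_signal = enrichments.groupby("gene")["signal"].sum()
    included = sorted(per_gene_signal.index[per_gene_signal >= min_signal])
    if not included:
        raise ValueError("no gene passes the binding filter")
    sub = enrichments[enrichments["gene"].isin(included)].copy()
    lengths = model.region_lengths()
    sub["normalized"] = sub["enrichment"] / sub["region"].map(lengths)
    profile = sub.groupby("region")["normalized"].mean()
    profile = profile.reindex([r for r in model.region_order if r in profile.index])
    return {"profile": profile, "genes": included}
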