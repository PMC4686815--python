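"""Readers and writers for the plain-text formats the pipeline consumes.

Quantification tables, ortholog-group tables (InParanoid-style
sqltable), annotation tables and gene lists are TSV; sequences are
FASTA (via Biopython); region models are BED6 with the name field
encoding ``gene|region``; crosslink tracks are 4-column TSV
(reference, pos, strand, count).  Result writers prepend ``#``
comment headers carrying tool version, config hash and seed so every
output is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import QuantTable
from .classify import AnnotationBundle
from .orthology import Member, OrthologGroupSet
from .profiles import CrosslinkTrack, RegionModel

__all__ = [
    "read_quant_table",
    "write_quant_table",
    "read_mapping",
    "read_gene_list",
    "write_gene_list",
    "read_fasta",
    "write_fasta",
    "read_sqltable",
    "write_sqltable",
    "read_annotations",
    "write_annotations",
    "read_region_model",
    "write_region_model",
    "read_track",
    "write_track",
    "read_score_track",
    "write_tsv_with_header",
    "write_truth_json",
]

SQLTABLE_COLUMNS = ("group_id", "bitscore", "species", "inparalog_score", "protein_id")


def read_quant_table(path, organism: str = "") -> QuantTable:
    """Read a TSV quant table (group_id, accessions, [gene], CL_*_logratio)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"group_id": str})
    if df.empty:
        raise ValueError(f"empty quantification table: {path}")
    df = df.set_index("group_id")
    ratio_cols = [c for c in df.columns if c.endswith("_logratio")]
    if not ratio_cols:
        raise ValueError(f"no *_logratio columns in {path}")
    accessions = df["accessions"].map(lambda s: str(s).split(";"))
    gene = df["gene"] if "gene" in df.columns else pd.Series(None, index=df.index, dtype=object)
    return QuantTable(
        ratios=df[ratio_cols].astype(float),
        accessions=accessions,
        gene=gene,
        organism=organism,
    )


def write_quant_table(table: QuantTable, path) -> None:
    out = table.ratios.copy()
    out.insert(0, "accessions", table.accessions.map(";".join))
    out.insert(1, "gene", table.gene)
    out.to_csv(path, sep="\t", index_label="group_id")


def read_mapping(path) -> pd.Series:
    """Accession -> gene mapping from a 2-column TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"mapping table needs two columns: {path}")
    bad = df[df.iloc[:, 0].isna() | df.iloc[:, 1].isna()]
    if len(bad):
        raise ValueError(f"malformed mapping row {bad.index[0] + 2} in {path}")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def read_gene_list(path) -> set:
    lines = Path(path).read_text().splitlines()
    return {l.strip() for l in lines if l.strip() and not l.startswith("#")}


def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_sqltable(
    path,
    lengths: Optional[Mapping[str, int]] = None,
    species: Optional[tuple] = None,
    columns: tuple = SQLTABLE_COLUMNS,
) -> OrthologGroupSet:
    """Read an InParanoid-style sqltable into an ortholog group set.

    The file is headerless TSV whose column layout defaults to
    (group_id, bitscore, species, inparalog_score, protein_id); pass
    ``columns`` to override dialects.  Sequence lengths are taken from
    the ``lengths`` map (e.g. built from FASTA); proteins without a
    known length get length 0.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=list(columns), dtype=str)
    lengths = lengths or {}
    groups: dict[str, list[Member]] = {}
    for _, row in df.iterrows():
        pid = row["protein_id"]
        groups.setdefault(row["group_id"], []).append(
            Member(row["species"], pid, int(lengths.get(pid, 0)))
        )
    if species is None:
        species = tuple(sorted(df["species"].unique()))
    return OrthologGroupSet(groups=groups, species=species)


def write_sqltable(groups: OrthologGroupSet, path) -> None:
    rows = []
    for gid in sorted(groups.groups):
        for m in groups.groups[gid]:
            rows.append((gid, "100", m.species, "1.000", m.protein_id))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_annotations(go_path, domain_path, ec_path) -> AnnotationBundle:
    """Assemble an annotation bundle from three gene-keyed TSV tables."""
    go = pd.read_csv(go_path, sep="\t", comment="#", dtype=str)
    dom = pd.read_csv(domain_path, sep="\t", comment="#", dtype=str)
    ec = pd.read_csv(ec_path, sep="\t", comment="#", dtype=str)
    go_names: dict[str, set] = {}
    for _, r in go.iterrows():
        go_names.setdefault(r["gene"], set()).add(r["go_name"])
    domain_class: dict[str, list] = {}
    for _, r in dom.iterrows():
        domain_class.setdefault(r["gene"], []).append((r["domain_id"], r["class"]))
    ec_records: dict[str, list] = {}
    for _, r in ec.iterrows():
        ec_records.setdefault(r["gene"], []).append((r["ec_number"], r["descriptor"]))
    return AnnotationBundle(go_names=go_names, domain_class=domain_class, ec_records=ec_records)


def write_annotations(bundle: AnnotationBundle, go_path, domain_path, ec_path) -> None:
    go_rows = [
        (g, name) for g in sorted(bundle.go_names) for name in sorted(bundle.go_names[g])
    ]
    pd.DataFrame(go_rows, columns=["gene", "go_name"]).to_csv(go_path, sep="\t", index=False)
    dom_rows = [
        (g, d, c) for g in sorted(bundle.domain_class) for d, c in bundle.domain_class[g]
    ]
    pd.DataFrame(dom_rows, columns=["gene", "domain_id", "class"]).to_csv(
        domain_path, sep="\t", index=False
    )
    ec_rows = [
        (g, e, desc) for g in sorted(bundle.ec_records) for e, desc in bundle.ec_records[g]
    ]
    pd.DataFrame(ec_rows, columns=["gene", "ec_number", "descriptor"]).to_csv(
        ec_path, sep="\t", index=False
    )


def read_region_model(path, region_order: tuple = ()) -> RegionModel:
    """BED6 region model; the name field encodes ``gene|region``."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["reference", "start", "end", "name", "score", "strand"],
    )
    gene_region = df["name"].str.split("|", n=1, expand=True)
    if gene_region.shape[1] < 2 or gene_region[1].isna().any():
        raise ValueError(f"BED name field must be 'gene|region': {path}")
    regions = pd.DataFrame(
        {
            "reference": df["reference"],
            "gene": gene_region[0],
            "region": gene_region[1],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "strand": df["strand"],
        }
    )
    return RegionModel(regions=regions, region_order=region_order)


def write_region_model(model: RegionModel, path) -> None:
    df = model.regions
    bed = pd.DataFrame(
        {
            "reference": df["reference"],
            "start": df["start"],
            "end": df["end"],
            "name": df["gene"] + "|" + df["region"],
            "score": 0,
            "strand": df["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_track(path) -> CrosslinkTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["reference", "pos", "strand", "count"],
        dtype={"reference": str, "pos": int, "strand": str, "count": int},
    )
    return CrosslinkTrack(counts=df)


def write_track(track: CrosslinkTrack, path) -> None:
    track.counts.to_csv(path, sep="\t", index=False, header=False)


def read_score_track(path) -> np.ndarray:
    """Per-residue disorder scores from 2-column (position, score) text."""
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, usecols=[0, 1], names=["pos", "score"]
    )
    df = df.sort_values("pos")
    return df["score"].to_numpy(dtype=float)


def write_tsv_with_header(df: pd.DataFrame, path, meta: Mapping[str, object], index=False) -> None:
    """Write a TSV prefixed with ``# key=value`` provenance comments."""
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_truth_json(truth: Mapping[str, object], path) -> None:
    def default(o):
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o).__name__)

    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True, default=default))
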