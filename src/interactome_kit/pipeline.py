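"""End-to-end orchestration of the synthetic demonstration pipeline.

Runs simulate -> interactome calling -> classification -> orthology ->
motif expansion -> sequence features -> crosslink profiles into a run
directory, with every output TSV carrying provenance headers (tool
version, config hash, seed) and a machine-readable ``summary.json``.
Re-running with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io
from .calling import call_interactome, fit_moderated_ttest
from .classify import classify_rbps
from .features import ResidueScoreTrack, disorder_fraction, low_complexity_fraction
from .motifs import average_copy_trajectory, build_count_array, test_motif_expansion
from .orthology import categorize_groups, core_interactome, select_representative
from .profiles import generic_profile, region_enrichment
from .synthetic_data import (
    ORGANISMS,
    PlantedMotifSpec,
    SimulationConfig,
    default_trna_region_model,
    simulate_annotations,
    simulate_crosslink_tracks,
    simulate_proteomes,
    simulate_quant_experiment,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Thresholds default to the analysis constants: interactome tiers at
    FDR 0.01 / 0.05, tripeptide motifs (k=3) expanded by >= 2 copies
    tested at FDR 0.2, disorder above score 0.4, low complexity below
    3 bits in a +/-10 residue window.
    """

    seed: int = 0
    # quantification stage
    n_proteins: int = 2000
    n_true_rbps: int = 200
    n_replicates: int = 3
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    prior_df: float = 4.0
    prior_var: float = 0.05
    missing_rate: float = 0.05
    fdr: float = 0.01
    candidate_fdr: float = 0.05
    # proteome / motif stage
    n_groups: int = 100
    rbp_fraction: float = 0.2
    planted_motif: str = "KKR"
    planted_extra: tuple = (0, 0, 1, 2, 3)
    background_motifs: int = 5
    k: int = 3
    delta: int = 2
    motif_fdr: float = 0.2
    # annotation stage
    fraction_rna_linked: float = 0.4
    fraction_with_rbd: float = 0.3
    fraction_enzyme: float = 0.2
    # feature stage
    disorder_threshold: float = 0.4
    entropy_halfwidth: int = 10
    entropy_bits: float = 3.0
    # crosslink stage
    enrich_region: str = "D-loop"
    crosslink_fold: float = 5.0
    crosslink_depth: float = 2.0
    pseudocount: float = 1.0
    min_signal: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.planted_extra, list):
            cfg.planted_extra = tuple(cfg.planted_extra)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _meta(cfg: RunConfig) -> dict:
    return {
        "tool": f"interactome-kit {__version__}",
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages into ``outdir`` and return the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = _meta(config)
    rng = np.random.default_rng(config.seed)
    stage_seeds = rng.integers(0, 2**31 - 1, size=8)
    summary: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    # --- stage 1: quantification and interactome calling
    sim_cfg = SimulationConfig(
        seed=int(stage_seeds[0]),
        n_proteins=config.n_proteins,
        n_true_rbps=config.n_true_rbps,
        n_replicates=config.n_replicates,
        effect_mean=config.effect_mean,
        effect_sd=config.effect_sd,
        prior_df=config.prior_df,
        prior_var=config.prior_var,
        missing_rate=config.missing_rate,
    )
    table, truth = simulate_quant_experiment(sim_cfg)
    io.write_quant_table(table, out / "quant_table.tsv")
    io.write_truth_json({"true_rbps": truth}, out / "quant_truth.json")
    fit = fit_moderated_ttest(table)
    calls = call_interactome(fit, fdr=config.fdr, candidate_fdr=config.candidate_fdr)
    res = fit.table.copy()
    res["tier"] = "ns"
    res.loc[res.index.isin(calls["candidate"]), "tier"] = "FDR05"
    res.loc[res.index.isin(calls["high_confidence"]), "tier"] = "FDR01"
    io.write_tsv_with_header(res, out / "interactome.tsv", meta, index=True)
    summary["interactome"] = {
        "tested_genes": int(len(res)),
        "excluded_genes": len(fit.excluded),
        "high_confidence": len(calls["high_confidence"]),
        "candidate": len(calls["candidate"]),
        "true_positive_high_conf": len(calls["high_confidence"] & truth),
        "d0_hat": float(fit.d0),
        "s0_sq_hat": float(fit.s0_sq),
    }

    # --- stage 2: classification of the called interactome
    called = sorted(calls["high_confidence"])
    bundle = simulate_annotations(
        called,
        fraction_rna_linked=config.fraction_rna_linked,
        fraction_with_rbd=config.fraction_with_rbd,
        fraction_enzyme=config.fraction_enzyme,
        seed=int(stage_seeds[1]),
    )
    io.write_annotations(
        bundle, out / "go.tsv", out / "domains.tsv", out / "ec.tsv"
    )
    classifications = classify_rbps(set(called), bundle)
    cls_df = pd.DataFrame([dataclasses.asdict(c) for c in classifications])
    io.write_tsv_with_header(cls_df, out / "classification.tsv", meta)
    summary["classification"] = {
        "n_rbps": int(len(cls_df)),
        "enigm": int(cls_df["enigm"].sum()) if len(cls_df) else 0,
        "classic_enzymes": int(cls_df["classic_enzyme"].sum()) if len(cls_df) else 0,
    }

    # --- stage 3: proteomes, orthology and motif expansion
    planted = [
        PlantedMotifSpec(
            motif=config.planted_motif, extra_copies_in_rbps=config.planted_extra
        )
    ]
    sequences, groups, rbp_groups = simulate_proteomes(
        config.n_groups,
        planted,
        background_motifs=config.background_motifs,
        seed=int(stage_seeds[2]),
        rbp_fraction=config.rbp_fraction,
    )
    for org in ORGANISMS:
        io.write_fasta(sequences[org], out / f"proteome_{org}.fa")
    io.write_sqltable(groups, out / "ortholog_groups.tsv")
    io.write_truth_json({"rbp_groups": rbp_groups}, out / "proteome_truth.json")

    yeast_rbps = {
        m.protein_id
        for gid in rbp_groups
        for m in groups.groups[gid]
        if m.species == "yeast"
    }
    human_rbps = {
        m.protein_id
        for gid in rbp_groups
        for m in groups.groups[gid]
        if m.species == "human"
    }
    categories = categorize_groups(groups, yeast_rbps, human_rbps)
    core = core_interactome(categories, groups, yeast_rbps, human_rbps)
    io.write_tsv_with_header(categories, out / "ortholog_categories.tsv", meta)
    summary["orthology"] = {
        "n_groups": int(len(categories)),
        "core_groups": len(core["core_groups"]),
        "yeast_core": len(core["yeast_core"]),
        "human_core": len(core["human_core"]),
    }

    representatives = {
        org: {gid: select_representative(m, org) for gid, m in groups.groups.items()}
        for org in ORGANISMS
    }
    array = build_count_array(representatives, sequences, rbp_groups, k=config.k)
    results = test_motif_expansion(array, delta=config.delta, fdr=config.motif_fdr)
    io.write_tsv_with_header(results, out / "motif_expansion.tsv", meta)
    selected = set(results.loc[results["selected"], "motif"])
    summary["motifs"] = {
        "tested": int(len(results)),
        "selected": sorted(selected),
        "planted_selected": config.planted_motif in selected,
    }
    if selected:
        traj = average_copy_trajectory(array, selected)
        io.write_tsv_with_header(traj, out / "motif_trajectory.tsv", meta, index=True)

    # --- stage 4: sequence features of human representatives
    feat_rng = np.random.default_rng(int(stage_seeds[3]))
    rows = []
    for gid in sorted(groups.groups):
        pid = representatives["human"][gid]
        seq = sequences["human"][pid]
        # synthetic stand-in for an external disorder predictor track
        scores = feat_rng.random(len(seq))
        rows.append(
            (
                pid,
                disorder_fraction(
                    ResidueScoreTrack(pid, scores), threshold=config.disorder_threshold
                ),
                low_complexity_fraction(
                    seq,
                    halfwidth=config.entropy_halfwidth,
                    bits_threshold=config.entropy_bits,
                ),
            )
        )
    feat_df = pd.DataFrame(
        rows, columns=["protein_id", "fraction_disordered", "fraction_low_complexity"]
    )
    io.write_tsv_with_header(feat_df, out / "features.tsv", meta)
    summary["features"] = {"n_proteins": int(len(feat_df))}

    # --- stage 5: crosslink profile on the generic tRNA model
    model = default_trna_region_model()
    signal, control = simulate_crosslink_tracks(
        model,
        enrich_region=config.enrich_region,
        fold=config.crosslink_fold,
        depth=config.crosslink_depth,
        seed=int(stage_seeds[4]),
    )
    io.write_track(signal, out / "signal_track.tsv")
    io.write_track(control, out / "control_track.tsv")
    io.write_region_model(model, out / "trna_regions.bed")
    enr = region_enrichment(signal, control, model, pseudocount=config.pseudocount)
    prof = generic_profile(enr, model, min_signal=config.min_signal)
    prof_df = prof["profile"].rename("mean_enrichment_per_nt").reset_index()
    io.write_tsv_with_header(prof_df, out / "crosslink_profile.tsv", meta)
    summary["crosslink"] = {
        "n_genes_profiled": len(prof["genes"]),
        "top_region": str(prof["profile"].idxmax()),
    }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return summary
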