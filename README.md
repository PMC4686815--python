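# interactome-kit

Statistical analysis of **mRNA interactome capture** experiments: calling
RNA-binding proteomes from crosslink/no-crosslink quantitative proteomics,
and comparative downstream analysis of the resulting RBP lists.

In interactome capture, living cells are UV-crosslinked, polyadenylated RNA
is purified by oligo(dT) and the covalently attached proteins are quantified
by mass spectrometry against non-crosslinked controls. `interactome-kit`
takes the per-replicate log2(CL/noCL) ratio table from such an experiment
and provides:

- **Interactome calling** — one-sample empirical-Bayes moderated t-test of
  the mean log-ratio against zero. Per-gene variances are shrunk toward a
  scaled inverse-chi-square prior (d₀, s₀²) estimated by closed-form moment
  matching; s̃²_g = (d₀s₀² + df·s²_g)/(d₀ + df),
  t_g = β̂_g/√(s̃²_g/n), p from t(d₀ + df). BH-adjusted and tiered at
  FDR 0.01 (high confidence) / 0.05 (candidates), requiring positive
  enrichment.
- **Orthology** — categorisation of InParanoid-style ortholog groups by
  yeast/human mRNA-binding status, extraction of the conserved core
  interactome, longest-isoform representative selection.
- **Motif evolution** — overlapping tripeptide repeat counts per
  representative across five organisms (yeast, worm, fly, fish, human) and a
  one-sided Fisher's exact screen for motifs whose copy number expands by
  ≥ 2 from yeast to human preferentially in RBPs (BH, FDR 0.2).
- **Sequence features** — disorder fraction from external per-residue score
  tracks (score > 0.4) and low-complexity fraction from ±10-residue
  windowed Shannon entropy (< 3 bits).
- **Classification** — RNA-linked GO annotation, recognised RNA-binding
  domains, **enigmRBPs** (RBPs with neither), classic metabolic enzymes with
  an RNA/DNA-enzyme exclusion list and EC top-class breakdown.
- **Set algebra** — merged "complete" interactomes, 2–3-way Venn region
  counts, the housekeeping intersection.
- **Crosslink profiles** — iCLIP count aggregation over structured-RNA
  sub-regions (generic tRNA cloverleaf model), control-normalised,
  length-normalised enrichment profiles.
- **Synthetic data** — generators for every input with known ground truth,
  so the full pipeline runs and validates offline.

## Worked example

Run the complete synthetic demonstration pipeline:

```bash
interactome-kit run --seed 1 --outdir demo_run
```

This simulates a 3-replicate capture of 2000 protein groups (200 true RBPs),
calls the interactome, classifies the called RBPs, simulates five-organism
proteomes with a planted KKR repeat expansion, runs the ortholog and motif
analyses, computes sequence features, and profiles a simulated crosslink
experiment on a 22-gene generic tRNA model. The summary it prints (and
writes to `demo_run/summary.json`) looks like:

```json
{
  "interactome": {
    "tested_genes": 1986,
    "high_confidence": 194,
    "candidate": 5,
    "true_positive_high_conf": 194,
    "d0_hat": 5.345,
    "s0_sq_hat": 0.0561
  },
  "classification": {"n_rbps": 194, "enigm": 78, "classic_enzymes": 39},
  "orthology": {"n_groups": 100, "core_groups": 20, "yeast_core": 25, "human_core": 27},
  "motifs": {"tested": 7997, "selected": ["KKR"], "planted_selected": true},
  "crosslink": {"n_genes_profiled": 22, "top_region": "D-loop"}
}
```

Reading the numbers: 194 of 1986 testable genes are called at FDR 0.01, all
of them true planted RBPs (no false discoveries in this run); the estimated
variance prior (d̂₀ = 5.3, ŝ₀² = 0.056) is close to the generating values
(4, 0.05); the motif screen tests ~8000 tripeptides and selects exactly the
planted KKR expansion; and the 5×-enriched D-loop is recovered as the top
region of the crosslink profile.

Individual stages are available as subcommands operating on plain-text
files, e.g.:

```bash
interactome-kit call-interactome --quant quant.tsv --mapping map.tsv --fdr 0.01 --out calls.tsv
interactome-kit motif-scan --groups sqltable.tsv --rbp-groups rbps.txt \
    --fasta yeast=yeast.fa --fasta human=human.fa --out motifs.tsv
interactome-kit clip-profile --signal s.tsv --control c.tsv --regions trna.bed --out profile.tsv
```

See `docs/methods.md` for the statistical model, parameter defaults and the
limits of what the synthetic validation shows.

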