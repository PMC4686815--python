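"""Synthetic inputs for every pipeline stage.

Generates quantitative proteomics ratio tables under the hierarchical
variance model assumed by the moderated t-test, five-organism
proteomes with ortholog structure and planted tripeptide-repeat
expansions, annotation bundles for the classification rules, and
Poisson crosslink-count tracks with region-localised enrichment.
Every generator is a pure function of its configuration including the
seed, so reruns are byte-identical and ground truth is available for
power and error-control studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import QuantTable
from .classify import AnnotationBundle
from .orthology import Member, OrthologGroupSet
from .profiles import CrosslinkTrack, RegionModel

__all__ = [
    "SimulationConfig",
    "PlantedMotifSpec",
    "simulate_quant_experiment",
    "simulate_proteomes",
    "simulate_annotations",
    "simulate_crosslink_tracks",
    "default_trna_region_model",
    "AMINO_ACIDS",
    "ORGANISMS",
]

ORGANISMS = ("yeast", "worm", "fly", "fish", "human")

#: the 20 standard amino acids; the background model draws uniformly
#: from these so no k-mer contains the excluded letters X or U
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for a simulated interactome-capture experiment.

    Defaults mirror a three-replicate capture of ~2000 quantified
    protein groups of which ~10% are genuine RBPs enriched by about
    two log2 units, with per-protein variances drawn from a scaled
    inverse-chi-square prior (d0=4, s0^2=0.05) and 5% of
    quantifications missing completely at random.
    """

    seed: int = 0
    n_proteins: int = 2000
    n_true_rbps: int = 200
    n_replicates: int = 3
    effect_mean: float = 2.0
    effect_sd: float = 0.5
    prior_df: float = 4.0
    prior_var: float = 0.05
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_true_rbps > self.n_proteins:
            raise ValueError("n_true_rbps cannot exceed n_proteins")
        if self.prior_df <= 0 or self.prior_var <= 0:
            raise ValueError("prior_df and prior_var must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_replicates < 1 or self.n_proteins < 1:
            raise ValueError("counts must be positive")


@dataclass
class PlantedMotifSpec:
    """A tripeptide planted into ortholog-group members.

    ``baseline_copies`` (one integer per organism, yeast..human) go
    into every group; ``extra_copies_in_rbps`` are added on top in
    RBP-labelled groups, creating a true copy-number expansion.
    """

    motif: str
    baseline_copies: tuple = (0, 0, 0, 0, 0)
    extra_copies_in_rbps: tuple = (0, 0, 0, 0, 0)

    def __post_init__(self) -> None:
        if any(ch in "XU" for ch in self.motif.upper()):
            raise ValueError("planted motifs must not contain X or U")
        if len(self.baseline_copies) != len(ORGANISMS) or len(
            self.extra_copies_in_rbps
        ) != len(ORGANISMS):
            raise ValueError("copy vectors need one entry per organism")
        if any(c < 0 for c in self.baseline_copies) or any(
            c < 0 for c in self.extra_copies_in_rbps
        ):
            raise ValueError("copy numbers must be nonnegative")


def simulate_quant_experiment(cfg: SimulationConfig) -> tuple[QuantTable, set]:
    """Simulate a CL vs noCL log-ratio table with known RBP truth.

    Per-protein variances are s0^2 * d0 / chi2(d0); replicate
    log-ratios are Normal(effect, sigma_g) where the effect is
    Normal(effect_mean, effect_sd) for true RBPs and 0 otherwise.
    Missing values are injected completely at random.  Returns the
    table and the set of true RBP gene ids (exactly ``n_true_rbps``).
    """
    rng = np.random.default_rng(cfg.seed)
    n, r = cfg.n_proteins, cfg.n_replicates
    genes = np.array([f"G{i:05d}" for i in range(n)])
    rbp_idx = rng.choice(n, size=cfg.n_true_rbps, replace=False)
    is_rbp = np.zeros(n, dtype=bool)
    is_rbp[rbp_idx] = True

    sigma_sq = cfg.prior_var * cfg.prior_df / rng.chisquare(cfg.prior_df, size=n)
    effect = np.where(is_rbp, rng.normal(cfg.effect_mean, cfg.effect_sd, size=n), 0.0)
    ratios = rng.normal(effect[:, None], np.sqrt(sigma_sq)[:, None], size=(n, r))
    if cfg.missing_rate > 0:
        ratios[rng.random(size=(n, r)) < cfg.missing_rate] = np.nan

    index = pd.Index([f"PG{i:05d}" for i in range(n)], name="group_id")
    table = QuantTable(
        ratios=pd.DataFrame(
            ratios, index=index, columns=[f"CL_rep{j + 1}_logratio" for j in range(r)]
        ),
        accessions=pd.Series([[f"P{i:05d}"] for i in range(n)], index=index),
        gene=pd.Series(genes, index=index),
        organism="synthetic",
    )
    return table, set(genes[is_rbp])


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _AA_BYTES[rng.integers(0, len(_AA_BYTES), size=length)]


def _plant(seq: np.ndarray, motif: str, copies: int, rng: np.random.Generator) -> None:
    """Overwrite ``copies`` disjoint slots of ``seq`` with ``motif`` in place."""
    if copies == 0:
        return
    k = len(motif)
    n_slots = len(seq) // k
    if copies > n_slots:
        raise ValueError(f"sequence too short to plant {copies} copies of {motif!r}")
    slots = rng.choice(n_slots, size=copies, replace=False)
    mb = np.frombuffer(motif.encode(), dtype=np.uint8)
    for s in slots:
        seq[s * k : s * k + k] = mb


def simulate_proteomes(
    groups: int,
    planted: list[PlantedMotifSpec],
    background_motifs: int = 0,
    seed: int = 0,
    rbp_fraction: float = 0.2,
    length_range: tuple[int, int] = (150, 450),
    extra_member_rate: float = 0.3,
) -> tuple[dict, OrthologGroupSet, set]:
    """Five-organism proteomes with ortholog structure and planted repeats.

    Every ortholog group receives at least one member per organism
    (occasionally more, to exercise representative selection) with
    uniform-random amino-acid sequences.  Planted motif copies are
    written into every member: baseline copies everywhere, plus the
    extra copies in RBP-labelled groups.  ``background_motifs``
    additional random tripeptides are planted once per member in a
    random half of the groups irrespective of RBP status (decoys with
    no expansion signal).

    Returns (sequences, group set, rbp group ids) where sequences maps
    organism -> {protein_id -> sequence}.
    """
    rng = np.random.default_rng(seed)
    for spec in planted:
        _ = spec  # validated in __post_init__
    n_rbp = int(round(groups * rbp_fraction))
    rbp_groups = {f"OG{i:04d}" for i in rng.choice(groups, size=n_rbp, replace=False)}

    decoys = []
    for _ in range(background_motifs):
        motif = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=3))
        decoys.append((motif, set(rng.choice(groups, size=groups // 2, replace=False))))

    sequences: dict[str, dict[str, str]] = {org: {} for org in ORGANISMS}
    members: dict[str, list[Member]] = {}
    for g in range(groups):
        gid = f"OG{g:04d}"
        is_rbp = gid in rbp_groups
        members[gid] = []
        for oi, org in enumerate(ORGANISMS):
            n_members = 1 + int(rng.random() < extra_member_rate)
            for mi in range(n_members):
                length = int(rng.integers(length_range[0], length_range[1] + 1))
                seq = _random_sequence(rng, length)
                for spec in planted:
                    copies = spec.baseline_copies[oi]
                    if is_rbp:
                        copies += spec.extra_copies_in_rbps[oi]
                    _plant(seq, spec.motif.upper(), copies, rng)
                for motif, in_groups in decoys:
                    if g in in_groups:
                        _plant(seq, motif, 1, rng)
                pid = f"{org}_{gid}_p{mi}"
                sequences[org][pid] = seq.tobytes().decode()
                members[gid].append(Member(org, pid, length))
    group_set = OrthologGroupSet(groups=members, species=ORGANISMS)
    return sequences, group_set, rbp_groups


# GO term names with and without a link to RNA biology; the non-RNA
# names deliberately avoid every substring of the RNA-linked rule list
_RNA_GO_NAMES = (
    "RNA binding",
    "mRNA processing",
    "spliceosomal complex",
    "translation initiation",
    "ribosome biogenesis",
    "exosome (RNase complex)",
)
_OTHER_GO_NAMES = (
    "actin binding",
    "gluconeogenesis",
    "protein folding",
    "glycolytic process",
    "cell adhesion",
    "lipid metabolic process",
)
_CLASSIC_ECS = (
    ("1.1.1.1", "alcohol dehydrogenase"),
    ("1.1.1.51", "3-hydroxysteroid dehydrogenase"),
    ("2.7.1.1", "hexokinase"),
    ("2.6.1.1", "aspartate transaminase"),
    ("5.3.1.9", "glucose-6-phosphate isomerase"),
    ("4.1.2.13", "fructose-bisphosphate aldolase"),
    ("6.3.1.2", "glutamine synthetase"),
    ("3.1.3.11", "fructose-bisphosphatase"),
)


def simulate_annotations(
    genes: list,
    fraction_rna_linked: float = 0.4,
    fraction_with_rbd: float = 0.3,
    fraction_enzyme: float = 0.2,
    seed: int = 0,
) -> AnnotationBundle:
    """Random GO / domain / EC annotations realising the given fractions.

    The three properties are assigned independently; realised counts
    match ``round(fraction * n)`` exactly.  Every gene receives one GO
    name (RNA-linked or not), RBD genes carry one classical-list
    domain while the rest carry an 'other' domain, and enzyme genes
    receive one classic metabolic EC record.
    """
    for f in (fraction_rna_linked, fraction_with_rbd, fraction_enzyme):
        if not 0 <= f <= 1:
            raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n = len(genes)
    if n == 0:
        return AnnotationBundle()

    def pick(fraction: float) -> set:
        k = int(round(fraction * n))
        return {genes[i] for i in rng.choice(n, size=k, replace=False)}

    rna_genes = pick(fraction_rna_linked)
    rbd_genes = pick(fraction_with_rbd)
    enzyme_genes = pick(fraction_enzyme)

    go_names, domain_class, ec_records = {}, {}, {}
    for g in genes:
        pool = _RNA_GO_NAMES if g in rna_genes else _OTHER_GO_NAMES
        go_names[g] = {pool[int(rng.integers(0, len(pool)))]}
        if g in rbd_genes:
            domain_class[g] = [("PF00076", "classical")]
        else:
            domain_class[g] = [("PF00012", "other")]
        if g in enzyme_genes:
            ec, desc = _CLASSIC_ECS[int(rng.integers(0, len(_CLASSIC_ECS)))]
            ec_records[g] = [(ec, desc)]
    return AnnotationBundle(
        go_names=go_names, domain_class=domain_class, ec_records=ec_records
    )


#: canonical cloverleaf sub-regions of a generic tRNA with lengths
_TRNA_REGIONS = (
    ("acceptor stem 5p", 7),
    ("D-stem 5p", 4),
    ("D-loop", 8),
    ("D-stem 3p", 4),
    ("anticodon stem 5p", 5),
    ("anticodon loop", 7),
    ("anticodon stem 3p", 5),
    ("variable loop", 4),
    ("T-stem 5p", 5),
    ("T-loop", 7),
    ("T-stem 3p", 5),
    ("acceptor stem 3p", 7),
)


def default_trna_region_model(n_genes: int = 22, spacing: int = 20) -> RegionModel:
    """A generic mitochondrial-style tRNA region model.

    ``n_genes`` tRNA genes laid out on one reference with alternating
    strands, each split into the canonical cloverleaf sub-regions
    (acceptor stem, D-arm, anticodon arm, variable loop, T-arm).
    """
    rows = []
    offset = 0
    for g in range(n_genes):
        gene = f"tRNA-{g + 1:02d}"
        strand = "+" if g % 2 == 0 else "-"
        pos = offset
        for region, length in _TRNA_REGIONS:
            rows.append(("chrM", gene, region, pos, pos + length, strand))
            pos += length
        offset = pos + spacing
    regions = pd.DataFrame(
        rows, columns=["reference", "gene", "region", "start", "end", "strand"]
    )
    return RegionModel(regions=regions, region_order=tuple(r for r, _ in _TRNA_REGIONS))


def simulate_crosslink_tracks(
    region_model: RegionModel,
    enrich_region: str,
    fold: float = 5.0,
    depth: float = 2.0,
    seed: int = 0,
) -> tuple[CrosslinkTrack, CrosslinkTrack]:
    """Poisson signal and control tracks with one enriched region class.

    Control counts are Poisson(depth) at every modelled position; the
    signal track uses rate depth * fold inside every interval named
    ``enrich_region`` and depth elsewhere.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    rng = np.random.default_rng(seed)
    sig_rows, ctl_rows = [], []
    for _, reg in region_model.regions.iterrows():
        positions = np.arange(reg["start"], reg["end"])
        rate = depth * (fold if reg["region"] == enrich_region else 1.0)
        sig_counts = rng.poisson(rate, size=len(positions))
        ctl_counts = rng.poisson(depth, size=len(positions))
        for p, s, c in zip(positions, sig_counts, ctl_counts):
            sig_rows.append((reg["reference"], int(p), reg["strand"], int(s)))
            ctl_rows.append((reg["reference"], int(p), reg["strand"], int(c)))
    cols = ["reference", "pos", "strand", "count"]
    return (
        CrosslinkTrack(counts=pd.DataFrame(sig_rows, columns=cols)),
        CrosslinkTrack(counts=pd.DataFrame(ctl_rows, columns=cols)),
    )
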