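"""Empirical-Bayes moderated t-test for calling mRNA interactomes.

A protein is declared part of the mRNA interactome when its mean
log2(CL/noCL) ratio across biological replicates is significantly above
zero.  Per-protein sample variances are shrunk toward an empirical-Bayes
prior (d0, s0^2) estimated from all proteins by moment matching of the
log sample variances, and the resulting moderated t-statistics gain
d0 extra degrees of freedom.  P-values are corrected with the
Benjamini-Hochberg step-up procedure and proteins are tiered at
FDR 0.01 (high confidence) and FDR 0.05 (candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "QuantTable",
    "EbayesFit",
    "map_protein_groups",
    "estimate_variance_prior",
    "fit_moderated_ttest",
    "adjust_bh",
    "call_interactome",
    "trigamma_inverse",
]

logger = logging.getLogger(__name__)

#: sample variances below this are floored before log-variance moment matching
VARIANCE_FLOOR = 1e-8


@dataclass
class QuantTable:
    """Protein-group x replicate log2(CL/noCL) ratio matrix.

    Parameters
    ----------
    ratios
        Float frame indexed by group id with one column per replicate;
        missing quantifications are NaN.
    accessions
        Series indexed like ``ratios`` holding the list of protein
        accessions of each group.
    gene
        Series indexed like ``ratios`` with the resolved gene id, or
        None where unresolved.
    organism
        Free-text organism tag.
    """

    ratios: pd.DataFrame
    accessions: pd.Series
    gene: pd.Series
    organism: str = ""

    def __post_init__(self) -> None:
        if self.ratios.shape[1] < 1:
            raise ValueError("QuantTable needs at least one replicate column")
        vals = self.ratios.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("log-ratios must be finite where present")

    @property
    def n_replicates(self) -> int:
        return self.ratios.shape[1]


@dataclass
class EbayesFit:
    """Result of the moderated t-test.

    ``table`` is indexed by gene and carries per-gene columns
    beta_hat (mean log-ratio), s_sq (sample variance), df (residual
    degrees of freedom), s_tilde_sq (posterior variance), t_mod,
    p_raw and p_adj.  ``d0`` may be ``inf`` when the log sample
    variances show no excess spread, in which case every posterior
    variance equals ``s0_sq``.
    """

    d0: float
    s0_sq: float
    table: pd.DataFrame
    excluded: list = field(default_factory=list)


def map_protein_groups(table: QuantTable, mapping: pd.Series) -> QuantTable:
    """Resolve protein groups to single gene ids.

    ``mapping`` maps accession -> gene id.  A group is retained only if
    its accessions resolve to exactly one distinct gene id; groups
    hitting two or more genes are ambiguous and dropped, as are groups
    whose accessions are entirely unmapped.  When two retained groups
    resolve to the same gene, the one quantified in more replicates
    wins (ties broken by group id).
    """
    if len(table.ratios) == 0:
        raise ValueError("empty quantification table")
    if mapping.index.has_duplicates:
        dup = mapping.index[mapping.index.duplicated()][0]
        raise ValueError(f"accession mapped more than once: {dup!r}")

    resolved: dict[str, str] = {}
    n_ambiguous = n_unmapped = 0
    for gid, accs in table.accessions.items():
        genes = {mapping[a] for a in accs if a in mapping.index and pd.notna(mapping[a])}
        if len(genes) == 1:
            resolved[gid] = genes.pop()
        elif len(genes) == 0:
            n_unmapped += 1
        else:
            n_ambiguous += 1
    if n_ambiguous or n_unmapped:
        logger.info(
            "dropped %d ambiguous and %d unmapped protein groups",
            n_ambiguous,
            n_unmapped,
        )

    keep = table.ratios.index[table.ratios.index.isin(resolved)]
    ratios = table.ratios.loc[keep]
    gene = pd.Series({g: resolved[g] for g in keep}, dtype=object)

    # one row per gene: the best-quantified group represents the gene
    n_obs = ratios.notna().sum(axis=1)
    order = pd.DataFrame({"gene": gene, "n_obs": n_obs}).sort_values(
        ["gene", "n_obs"], ascending=[True, False], kind="mergesort"
    )
    chosen = order[~order["gene"].duplicated()].index
    n_dup = len(keep) - len(chosen)
    if n_dup:
        logger.info("collapsed %d groups mapping to already-seen genes", n_dup)

    return QuantTable(
        ratios=table.ratios.loc[chosen],
        accessions=table.accessions.loc[chosen],
        gene=gene.loc[chosen],
        organism=table.organism,
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def estimate_variance_prior(
    s_sq: np.ndarray, df: np.ndarray
) -> tuple[float, float]:
    """Moment-matching estimate of the scaled inverse-chi-square prior.

    Under the hierarchical model s_sq | sigma_g^2 ~ sigma_g^2 chi2(df)/df
    and sigma_g^2 ~ s0_sq * d0 / chi2(d0), the corrected log sample
    variances e_g = log s_g^2 - digamma(df/2) + log(df/2) have mean
    log s0_sq + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond the sampling term trigamma(df/2).  Matching
    the first two moments yields closed forms in the digamma and
    trigamma functions.

    When the observed spread of e_g does not exceed its expected
    sampling spread, the prior is degenerate (d0 = inf) and s0_sq is
    set to the geometric mean of the sample variances so that the
    moderated statistic reduces exactly to the ordinary t-statistic
    for homoscedastic data.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    if s_sq.size < 2:
        raise ValueError("need at least two genes to estimate the variance prior")
    z = np.log(np.maximum(s_sq, VARIANCE_FLOOR))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (e.size - 1)
    evar -= np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(z.mean()))
        logger.info("no excess variance in log sample variances; prior df set to inf")
    return float(d0), s0_sq


def fit_moderated_ttest(table: QuantTable, min_replicates: int = 2) -> EbayesFit:
    """One-sample moderated t-test of mean log-ratio against zero.

    Genes quantified in fewer than ``min_replicates`` replicates are
    excluded from testing (their sample variance is undefined) and
    listed in ``EbayesFit.excluded``.  Posterior variances are the
    precision-weighted compromise (d0*s0_sq + df*s_sq) / (d0 + df) and
    p-values come from a t distribution with d0 + df degrees of
    freedom (normal when d0 is infinite).
    """
    min_replicates = max(2, int(min_replicates))
    X = table.ratios.to_numpy(dtype=float)
    genes = table.gene.fillna(pd.Series(table.ratios.index, index=table.ratios.index))
    n_obs = np.sum(~np.isnan(X), axis=1)
    tested = n_obs >= min_replicates
    excluded = [str(g) for g in genes[~tested]]
    if excluded:
        logger.info("excluded %d genes with < %d observations", len(excluded), min_replicates)
    if tested.sum() < 2:
        raise ValueError("fewer than two testable genes; cannot estimate prior")

    Xt = X[tested]
    n = n_obs[tested].astype(float)
    beta = np.nanmean(Xt, axis=1)
    s_sq = np.nanvar(Xt, axis=1, ddof=1)
    if np.all(s_sq <= VARIANCE_FLOOR):
        logger.warning("all sample variances at floor; moderation is degenerate")
    s_sq = np.maximum(s_sq, VARIANCE_FLOOR)
    df = n - 1.0

    d0, s0_sq = estimate_variance_prior(s_sq, df)
    if np.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0_sq)
        t_mod = beta / np.sqrt(s_tilde_sq / n)
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        s_tilde_sq = (d0 * s0_sq + df * s_sq) / (d0 + df)
        t_mod = beta / np.sqrt(s_tilde_sq / n)
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df + d0)
    p_adj = adjust_bh(p_raw)

    out = pd.DataFrame(
        {
            "beta_hat": beta,
            "s_sq": s_sq,
            "df": df,
            "s_tilde_sq": s_tilde_sq,
            "t_mod": t_mod,
            "p_raw": p_raw,
            "p_adj": p_adj,
        },
        index=pd.Index(genes[tested], name="gene"),
    )
    return EbayesFit(d0=d0, s0_sq=s0_sq, table=out, excluded=excluded)


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_raw, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_raw must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def call_interactome(
    fit: EbayesFit, fdr: float = 0.01, candidate_fdr: float = 0.05
) -> dict[str, set]:
    """Tier genes into a high-confidence interactome and a candidate set.

    A gene is high confidence iff p_adj <= ``fdr`` and its mean
    log-ratio is positive (CL-over-noCL enrichment); it is a candidate
    iff ``fdr`` < p_adj <= ``candidate_fdr`` with positive enrichment.
    """
    t = fit.table
    up = t["beta_hat"] > 0
    high = set(t.index[(t["p_adj"] <= fdr) & up])
    cand = set(t.index[(t["p_adj"] > fdr) & (t["p_adj"] <= candidate_fdr) & up])
    return {"high_confidence": high, "candidate": cand}
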