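# Methods

## Scope and model overview

`interactome-kit` implements the downstream statistical analysis of mRNA
interactome capture: experiments in which UV-crosslinked, oligo(dT)-purified
protein–RNA complexes are quantified by mass spectrometry against
non-crosslinked controls, and a proteome-wide list of RNA-binding proteins
(RBPs) is derived from the replicate crosslink/no-crosslink (CL/noCL)
enrichment ratios. The toolkit covers interactome calling, cross-species
ortholog analysis, tripeptide repeat-expansion testing, sequence-feature
summaries, functional classification, interactome set algebra, and
crosslink-site (iCLIP) region profiles. A synthetic-data module generates
every input with known ground truth so the complete pipeline is testable
offline.

## Interactome calling

Input is a protein-group × replicate matrix of log2(CL/noCL) ratios. Protein
groups are first resolved to gene identifiers; a group whose accessions map
to two or more distinct genes is ambiguous and dropped, as are wholly
unmapped groups. When two groups resolve to the same gene the
better-quantified group represents it.

The test is a one-sample empirical-Bayes moderated t-test of the mean
log-ratio against zero. For gene *g* with *n_g* observed replicates,
mean β̂_g, sample variance s²_g and residual df_g = n_g − 1, the
per-gene variances are assumed exchangeable under a scaled
inverse-chi-square prior σ²_g ~ s₀²·d₀/χ²(d₀). The posterior variance is the
precision-weighted compromise

    s̃²_g = (d₀·s₀² + df_g·s²_g) / (d₀ + df_g),

the moderated statistic is t_g = β̂_g / √(s̃²_g / n_g), and p-values use a t
distribution with d₀ + df_g degrees of freedom. Two-sided p-values are
BH-adjusted and a gene enters the high-confidence interactome iff
p_adj ≤ 0.01 **and** β̂_g > 0 (candidates at 0.01 < p_adj ≤ 0.05). The
positive-direction requirement encodes that an RBP must be enriched in the
crosslinked capture; the test itself is kept two-sided.

Hyperparameters (d₀, s₀²) are estimated by moment matching of the corrected
log sample variances e_g = log s²_g − ψ(df_g/2) + log(df_g/2), whose excess
variance beyond the sampling term ψ′(df_g/2) identifies d₀ through
ψ′(d₀/2) (trigamma inverse by Newton iteration) and whose mean identifies
s₀². **Degenerate branch:** when the observed spread of e_g does not exceed
its sampling expectation, the prior is taken as infinitely informative
(d₀ = ∞) and s₀² is set to the geometric mean of the sample variances. This
choice makes the method exactly consistent in the homoscedastic limit — when
every gene shows the same sample variance, the moderated t equals the
ordinary one-sample t — at the cost of dropping the log-scale bias
correction in a branch that only arises for (near-)homoscedastic data.
Sample variances are floored at 1e-8 before taking logs; genes observed in
fewer than two replicates have no variance estimate and are excluded and
reported.

## Orthology

Ortholog groups are consumed as InParanoid-style sqltable rows
(group, bitscore, species, inparalog score, protein). A group is "mRNA
binding" in a species when at least one member of that species is in the
species' complete interactome list; the cross-product of yeast/human status
yields the categories both / human_only / yeast_only / neither, and the
"both" groups form the conserved core interactome. Yeast-only binding groups
are reported with a warning rather than an error: the underlying data sets
make them unexpected, not impossible. Per organism, a group is represented
by its longest member (sequence lengths from FASTA; unknown length counts as
0), ties broken by lexicographically smallest protein id so that member
order never matters. Third-species orthologs are chosen among candidates
linked to both the yeast and the human representative, again longest-first.

## Tripeptide repeat expansion

For each organism's representative sequence, overlapping occurrences of
every k-mer (k = 3 by default) are counted; windows containing X or U are
skipped and a terminal stop (`*`) is stripped. Counting is overlapping
because the "repeat number" of e.g. KKK inside a poly-lysine run is
naturally the number of sliding-window matches; the choice is a parameter
of nothing — it is fixed and documented here because alternatives exist.
The motif axis of the groups × motifs × organisms array is the union of
k-mers occurring in the yeast and human representatives of the tested
groups (the conserved proteins); organisms in which a group lacks an
ortholog carry an absent (NaN) slice and are excluded pairwise.

Per motif, a group is *expanded* when its human copy number exceeds its
yeast copy number by at least δ = 2. The 2×2 table of
{RBP, non-RBP} × {expanded, not} over all groups with both yeast and human
representatives is tested with a one-sided Fisher's exact test
(alternative: expansion enriched among RBPs), BH-corrected, and motifs with
p_adj ≤ 0.2 are selected. The deliberately liberal FDR reflects the
screening character of the test. Average copy-number trajectories across
the five organisms are arithmetic means over (group, motif) pairs,
separately for RBP and non-RBP groups.

## Sequence features

Disorder is an input track of per-residue scores from an external predictor
(IUPred-style output); a residue is disordered when its score is strictly
greater than 0.4, and the per-protein summary is the disordered fraction.
Complexity is the Shannon entropy, in bits, of the residue composition in a
±10-residue window around each position; windows are truncated at the
sequence ends (no padding symbols are invented) and the focal residue is
included. Positions strictly below 3 bits are low complexity. Any letters
present (including B, Z, J, X, U) count as ordinary symbols, since the
measure is purely compositional.

## Classification

An RBP is *linked to mRNA biology* when any of its GO term **names**
contains one of the substrings mRNA, splic, RNA binding, RNA, RNP,
translation, ribosom, nuclease, exosome. The fragments are deliberately
truncated to catch morphological variants; matching is case-sensitive so
that the uppercase acronyms never match inside ordinary lowercase words
(e.g. 'internal'). An RBP carries a *recognised* RNA-binding domain when
any of its domains appears on the classical or non-classical RBD lists
supplied as configuration (small Pfam-based defaults ship with the package;
real analyses should pass curated lists matching their domain annotation).
RBPs with neither property are **enigmRBPs** — the invariant
enigm ⇒ ¬rna_linked ∧ ¬rbd_recognised is enforced in the result type.

A gene is a *classic metabolic enzyme* when it has at least one well-formed
EC record and no descriptor matches the exclusion patterns covering
RNA/DNA helicases, tRNA/rRNA modification enzymes, nucleases,
aminoacyl-tRNA synthetases, RNA/DNA polymerases, topoisomerases, proteasome
subunits and regulatory subunits of any enzyme. "Regulatory subunit" has no
structural encoding in EC numbers, so it is implemented as a descriptor
pattern. Enzymes are tallied by the first EC digit (oxidoreductases …
ligases); a gene with EC numbers in several top classes counts once per
distinct class.

## Interactome set algebra

Gene identifiers are normalised (whitespace stripped, trailing `.N` version
removed, uppercased) before any set operation, since mixed identifier
dialects are the dominant practical failure mode when combining published
lists. Merging produces the de-duplicated union with a per-source
membership matrix; overlaps of two or three lists produce exact Venn region
counts whose sum is asserted to equal the union size on every call, and the
intersection of all lists is reported as the housekeeping interactome.

## Crosslink profiles

Crosslink tracks are per-position, strand-aware read counts; region models
are 0-based half-open intervals (BED convention) naming ordered sub-regions
per gene, e.g. the cloverleaf arms of mitochondrial tRNAs. Counts are
summed per (gene, region) with minus-strand regions aggregated on
minus-strand counts; reads outside every region are tallied so totals are
conserved. Enrichment is computed after library-size normalisation with a
pseudocount:

    E = ((signal + pc)/N_signal) / ((control + pc)/N_control),  pc = 1,

which makes a track against itself exactly 1 in every region for any
pseudocount. The generic profile averages, over genes passing a minimum
total-signal binding filter (default ≥ 1 read; the filter is configurable
because the appropriate stringency depends on library depth), the per-gene
enrichment divided by the region length. Differential crosslink testing
between conditions is out of scope; the aggregation exports count matrices
suitable for any count-based differential tool.

## Synthetic data — what it emulates and what it does not

The quantification generator draws per-protein variances from the scaled
inverse-chi-square prior and replicate ratios as Normal(effect, σ_g), with
effects Normal(2.0, 0.5) log2 units in true RBPs and zero otherwise; 2000
proteins, 200 true RBPs, 3 replicates, (d₀, s₀²) = (4, 0.05) and 5% MCAR
missingness are the default conditions. Because the generator matches the
inference model exactly, hyperparameter recovery and FDR calibration are
meaningful checks of the implementation — not of the model's adequacy for
real spectra, which show intensity-dependent variance trends,
non-ignorable missingness and shared-peptide effects the generator does
not emulate.

Proteome simulation produces uniform-composition random sequences
(150–450 aa) in five organisms with at least one member per group
(sometimes more, to exercise representative selection) and plants motif
copies by overwriting disjoint k-length slots: baseline copies everywhere,
extra copies in RBP groups, plus optional decoy motifs planted without
RBP bias. Real proteomes have strongly non-uniform composition, so
absolute motif frequencies are unrealistic; the expansion *contrast*
(RBP vs non-RBP, human vs yeast) is what the screen's power and
error-control results speak to. Crosslink tracks are independent Poisson
counts with a single fold-enriched region class — no overdispersion, no
crosslinking sequence bias.

Annotation simulation realises requested fractions of RNA-linked,
RBD-carrying and enzyme genes exactly (after rounding) using GO names and
EC records chosen to sit unambiguously on one side of each classification
rule.

## Numerical choices

- Trigamma inverse by damped Newton iteration (50 iterations max,
  relative tolerance 1e-12); closed-form asymptotes for very large/small
  arguments.
- Variance floor 1e-8 before log-variance moment matching.
- BH step-up via stable sort + reverse cumulative minimum; ties preserved.
- Fisher upper tail via the hypergeometric survival function
  (`P(X ≥ a)` given the margins); validated exhaustively against exact
  rational enumeration for all tables with total ≤ 30.
- Entropy via cumulative one-hot counts, O(L·|alphabet|); agrees with the
  naive window recount to ~1e-15.
- All generators take integer seeds into `numpy.random.default_rng`;
  pipeline stages derive child seeds from the run seed so one integer
  reproduces a full run byte-identically.

## Problem sizes used in validation

The validation suite and the acceptance script use: 500-protein tables for
exact-arithmetic agreement, 20 × 5000 proteins for hyperparameter recovery,
200 × 400-protein null datasets for call-rate calibration, 50 × 2000 for
realized false-discovery proportions, 100 planted + 200 null motif screens
at 200 ortholog groups (40 RBP / 160 non-RBP), and 100 crosslink
simulations on a 22-gene generic tRNA model. These sizes were chosen as the
smallest at which the Monte-Carlo error of each property is comfortably
below its acceptance margin.

## Known limitations

- The moderated test has no robust or intensity-trend variants; ratios are
  assumed pre-normalised.
- GO matching operates on term names only (no synonyms, no ontology
  traversal), exactly as the rule list is defined.
- Ortholog groups are consumed, never computed; identifier mapping between
  namespaces must be supplied.
- The expansion test contrasts only yeast vs human; the other organisms
  enter descriptively through trajectories.
- Crosslink profiling assumes non-overlapping region intervals per gene and
  single-nucleotide site resolution.
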