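# Methods

This note documents the models the package implements, the defaults it
ships with, and the design decisions taken where the procedures were
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Proteogenomic specificity scoring

**Protein normalization.** Raw protein abundances are first divided by the
total abundance of their sample (missing values excluded from the totals)
and then each protein row is divided by its maximum, mapping retained
values into [0, 1]. Missing values are never imputed — they are excluded
from totals and propagate as missing. Rows that are entirely missing or
all zero carry no information and are excluded with a warning; a sample
whose non-missing total is zero is an error because the sample-wise step
is undefined. The row-scaling step is idempotent, which the tests exploit
as an invariant.

**Concordance prefilter.** Before scoring, RNA–protein pairs can be
filtered for concordant differential evidence: |log2 fold change| > 1 at
BH q < 0.05 on RNA and |LFC| > 0.5 at q < 0.1 on protein, with matching
sign, in the same contrast. The differential engine behind this filter is
a plain Welch two-sample t-test per gene on log2-scale values with BH
correction — a deliberately simple stand-in labelled as such in run
manifests; the scorer accepts any externally produced gene list in its
place (`--skip-prefilter` bypasses it entirely). A protein is testable
only if detected in at least two biological replicates per condition;
untestable genes are reported as excluded, never as non-significant.
Zero-variance groups are handled explicitly (equal means give p = 1,
distinct means p = 0) so that degenerate but unambiguous inputs do not
produce NaNs.

**Specificity.** With replicate-averaged, non-negative expression `X[i, j]`
of gene *i* in condition *j* over *n* conditions,

    S_RNA[i, j] = X[i, j] / sqrt(sum_j X[i, j]^2)

and identically for protein abundance. Per gene the squared scores sum to
1, scores are invariant to any common positive rescaling of a gene's row,
and raising a gene in one condition can only raise its score there. The
combined score is `S = W_RNA * S_RNA + W_prot * S_prot` with both weights
0.5 by default; genes scored in only one layer are excluded, since the
combined score requires the matched pair. All-zero rows have no defined
direction and are flagged and excluded. Unstimulated ("resting") samples
are excluded before scoring, so *n* counts stimulated conditions only.

**Permutation null.** Significance is assessed by shuffling the
sample-to-condition assignment, re-averaging replicates, and recomputing
the combined score, 10,000 rounds by default. A sample's RNA and protein
measurements move together under the shuffle: the combined score relies on
the cross-layer dependence of the paired design, and permuting layers
independently would test a different null. Empirical p-values use the
add-one convention, `p = (1 + #{S_perm >= S_obs}) / (1 + n_valid)`, so
they are valid (never zero) under finite permutations. A permutation can
leave a gene with a permuted group that has no detected protein value;
such rounds are uninformative for that gene and are excluded from its
count (`n_valid`), rather than being counted as exceedances (which would
bias p upward by the missingness rate) or as non-exceedances (which would
bias it downward). BH correction is applied across genes within each
condition by default, since the correction is "for the number of genes
tested" and signatures are reported per condition; a `bh_scope="global"`
switch pools all gene x condition pairs instead. A gene enters a
condition's signature when S > 0.7 and q < 0.1 (both strict). Signatures
are computed separately for each cell type present in the sample
annotations. A gene may belong to several condition signatures; an
optional winner-takes-all mode assigns it to its argmax-S condition, ties
going to the lexicographically smallest condition label.

## Effectorness and the interaction model

**Effectorness** is trajectory pseudotime min–max scaled to [0, 1] within
each stimulation condition; the per-condition columns are then
concatenated unchanged into a single statistic, so each condition attains
0 and 1 and within-condition rank order is exactly preserved. Constant
pseudotime within a condition is an error — there is no gradient to
scale. Pseudotime itself is an input (trajectory inference is out of
scope).

**Model.** For each gene, log2 expression across cells is fit by OLS as

    X = alpha + beta*E + gamma_c + delta_c*E + eps

with dummy coding against the Th0 reference (Th0 is the
activation-without-cytokines control, so `gamma_Th0 = delta_Th0 = 0`).
Cells with zero expression for a gene are omitted from that gene's fit;
log2 of normalized expression therefore needs no pseudocount. Coefficient
p-values come from the OLS t-statistics and are BH-adjusted across genes
separately per coefficient family (beta, each gamma_c, each delta_c),
matching the reporting of separate per-family gene counts; significance is
q < 0.05. "Some gamma/delta significant" means at least one non-reference
condition passes.

Degenerate genes are reported, not dropped: a gene with non-zero cells in
fewer than two conditions, or none in the reference, or a rank-deficient
post-omission design is flagged `unfit` with a reason. A non-reference
condition with fewer than two non-zero cells is removed from that gene's
design and its gamma/delta reported as NaN.

**Classification.** Significance patterns map to mechanism classes:
cytokine-only (some gamma, no beta/delta), effectorness-only (beta only),
independent (beta and gamma, no delta), and interaction — split into
ubiquitous (beta and delta significant: effectorness-dependent everywhere,
with cytokines modulating the strength) and cytokine-specific (delta
without beta: effectorness dependency only under that cytokine). Strong
subsets flag significant |beta| > 0.5 and, per condition, significant
|delta_c| > 0.5. The generative truth classes of the simulator use the
same rules with "non-zero" in place of "significant", so fitted and true
classes share one vocabulary.

One modelling note: with ~2,000 cells split over four conditions and
residual sd 0.5, the OLS standard error of an interaction slope is on the
order of 0.09; per-coefficient RMSE against truth of about that size is
the attainable precision at this design, and is what the acceptance checks
measure.

## TCR clonal diversity

Cells are sorted by increasing effectorness (ties broken by cell id, a
stable sort, so windows are deterministic and the profile is invariant to
input row order) and three metrics are computed per sliding window of 100
cells, advancing one rank at a time: the fraction of unique clones
(distinct clonotypes / window size), the Shannon entropy of clonotype
frequencies, and the expansion index = 1 − entropy. The entropy is
normalized by ln(window size): the raw natural-log entropy of a 100-cell
window can reach ln 100 ≈ 4.6, which would make "1 − entropy" leave
[0, 1] and the expansion index incoherent; normalization puts a
monoclonal window at 0 and an all-singleton window at 1 with the base
cancelling out. The raw value remains available via the
`entropy="raw"` switch. The fixed window size removes any need for
cell-number normalization across windows. The high-effectorness subset
(E strictly > 0.7) is exported with clone sizes as input for external
TCR specificity grouping, which is out of scope.

## Synthetic data

The generators define the study conditions the tests and acceptance runs
use; all are deterministic given their seed.

**Paired bulk omics.** Six stimulation conditions (Th0, Th1, Th2, Th17,
iTreg, IFNB) x 3 replicates by default. RNA is simulated directly on the
log2 scale (the downstream computations consume normalized log
expression; count-level simulation would add machinery the in-scope
analyses never see), clipped at zero because the specificity score
requires non-negative input. Each condition receives 50 designated
signature genes by default, shifted up by 3 log2 units on RNA and 1.5 on
protein in that condition only, with additive Gaussian log-scale noise of
sd 0.5 on both layers. The off-state baseline is U(0.5, 2.5): genes that
can carry a state-specific signature are, by the arithmetic of the
Euclidean-norm score, genes with a low expression floor outside their
state (a gene with baseline b and a +3 spike scores above 0.7 only for
b below roughly 2.5), so the generator models that gene universe rather
than the bulk of uniformly expressed genes. Protein abundances are
linear-scale (baseline 2^U(8,12)) with each value independently missing
at rate 0.1, emulating detection dropout across mass-spectrometry
batches.

**Single cells.** Each cell draws a latent effectorness E and a condition
(Th0, Th2, Th17, iTreg, uniform and independent of E by default; a
documented switch induces dependence for confounding studies). Latent
log2 expression follows the interaction model exactly, with per-gene
coefficients either supplied or drawn from {0, ±0.8} with known mechanism
classes, intercepts U(2, 4) and residual sd 0.5. E defaults to the
U-shaped beta(0.5, 0.5): pooled naive + memory datasets are bimodal along
the gradient — dense lobes of naive-like cells near 0 and
effector-memory-like cells near 1 — which a symmetric U-shaped density
emulates better than a flat one. Zero inflation is expression-dependent
dropout, `p_zero(X) = expit(-(X - 0) / 0.5)`, a monotone decreasing
function of latent expression, so the zero-omission rule of the fitting
code is genuinely exercised. Cells also carry an unscaled pseudotime (a
per-condition positive affine transform of E) so the scaling pipeline has
realistic input. The generator does not attempt library-size effects, UMI
saturation or batch structure; passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to those artefacts.

**Clonotypes.** A cell joins an expanded clone with probability
`p0 + p1 * E` (defaults 0.05 + 0.6 E), otherwise it is a singleton
clonotype. Expanded clone sizes are geometric (p = 0.3, mean ≈ 3.3), and
clone mates are adjacent in effectorness: clonal expansion is an event in
a cell's activation history, so sister cells sit at similar points of the
gradient — this is also what makes windowed diversity sensitive to
expansion. The last clone may be truncated by availability. Configs
enforce `p0 + p1 <= 1` so the probability stays in [0, 1] for all E.

## Numerical and interface choices

* Dense TSV is the canonical interchange format; MatrixMarket triplets
  (1-based coordinates, with `.rows.tsv` / `.cols.tsv` id sidecars) are
  accepted for cell x gene matrices. Dense TSV round-trips float64
  bit-exactly (shortest-repr writing, round-trip parsing). Missing protein
  values are empty cells.
* Signature output ordering is deterministic: condition ascending, then
  descending S, then gene id.
* The estimator surface follows the fit/attribute convention
  (`SpecificityScorer`, `EffectornessScaler`, `EffectornessCytokineModel`,
  `ClonalDiversityProfiler`; fitted results in trailing-underscore
  attributes, parameters via `get_params`/`set_params`), with the
  module-level functions as the underlying primitives.
* Problem sizes in the test suite and acceptance script (500–1,000 genes,
  999 permutations, 2,000–5,000 cells, 3 seeds where averaging is needed)
  were chosen as the smallest designs at which the measured quantities
  stabilise; all measured behaviour is reproduced from scratch at run
  time.

## Known limitations

* The Welch-t stand-in does not shrink variances; with 3 replicates it is
  noticeably less powerful than moderated tests, which is why the
  prefilter is optional and the thresholds are applied to it rather than
  to a reimplementation of the original two-layer divergence filter,
  whose parameters are not published.
* Permutation p-values with n_perm rounds cannot fall below
  1/(n_perm + 1); with per-condition BH this sets a floor on the number of
  genes required before any call can pass q < 0.1 at small n_perm.
* The interaction model assumes Gaussian residuals on log2 expression
  after zero-omission; expression-dependent dropout induces a mild
  selection on low-expressed cells that is not corrected for.
* Window-level diversity metrics are strongly autocorrelated across
  overlapping windows; correlations across windows are therefore assessed
  against relabelling nulls, never against parametric p-values.
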