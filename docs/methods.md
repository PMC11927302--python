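# Methods

## Problem setting and model

Bulk RNA measured from a body fluid (urine supernatant cfRNA, urine
sediment RNA, plasma cfRNA) is modeled as a non-negative mixture of
cell-type-specific expression programs. Given a labeled reference atlas,
the basis matrix `B` has one column per cell type, built by *pseudobulk*:
counts are summed over the cells of a type and scaled to CPM. Summing
before scaling weights cells by their sequencing depth, the standard
construction for deconvolution bases; per-cell CPM averaging would
up-weight shallow cells.

Each bulk sample is CPM-normalized over all of its genes (so the solve
is invariant to global rescaling of the bulk vector), restricted to the
genes shared with the basis, and decomposed by non-negative least
squares. Reported fractions are the normalized weights `w/Σw` and are
fractions of **cell-type-specific RNA**, not of cells: no per-cell-type
RNA-content correction is applied. A nu-SVR solver (linear kernel,
coefficients clipped to ≥0) is available behind `method="nu-svr"` for
fidelity with support-vector deconvolution designs; NNLS is the default
because it is deterministic and recovers the same simplex on
well-conditioned bases.

By default the basis is restricted to the union of cell-type profile
genes before solving (configurable). This mirrors signature-gene-
restricted deconvolution designs and improves conditioning; the
`basis_collinearity` table (Pearson over log2(CPM+1)) exposes how
correlated the remaining columns are, which is the main caveat when
interpreting small fractions of transcriptionally similar cell types.

### Post-processing rules

- Fractions strictly below 0.1% are set to zero. Rows are **not**
  renormalized afterwards: the rule removes noise-level coefficients,
  and renormalizing would silently inflate the surviving fractions
  (a flag restores renormalization if a caller wants rows back on the
  simplex).
- A cell type enters the two-group comparison only if its proportion of
  nonzero fractions across the pooled cohort is at least
  `q = min(n_A, n_B)/(n_A + n_B)`, evaluated **after** zeroing (zeroed
  entries are the operational definition of absent signal). The
  denominator pools both groups of the comparison at hand.
- Tested cell types get a two-sided Mann–Whitney U test and BH
  correction across the tested family only; untested cell types carry no
  p-values rather than p = 1, so they cannot dilute the family.

### Mann–Whitney implementation

For `min(n₁, n₂) ≤ 8` the p-value is exact: the permutation distribution
of the rank sum is computed by a dynamic program over doubled midranks
(doubling keeps tied .5 ranks integral), which handles ties exactly and
stays cheap for unbalanced groups where literal enumeration would not.
Two-sided exact p doubles the smaller tail, capped at 1. Above that
size, the normal approximation with midranks, tie correction and
continuity correction is used. The crossover at 8 keeps every cohort
shape of interest (6 vs 12 and smaller) on the exact path.

### Confidence intervals

Per-cell-type 95% CIs come from a gene-resampling bootstrap: gene rows of
the shared-gene system are resampled with replacement and the sample
re-deconvolved; percentile 2.5/97.5 bounds are taken with the point
estimate appended to the bootstrap set, so the interval always contains
it. This treats genes as the sampling unit, which captures basis-model
misfit; it does not capture biological replicate variation.

## Normalization

CPM, TMM scaling factors and log2(CPM + pseudocount) with TMM-adjusted
effective library sizes. TMM follows the canonical estimator: reference
sample = the one whose 0.75 expression quantile is closest to the mean
upper quartile; M and A values over genes positive in both samples;
rank-based double-sided trims (defaults 0.30 on M, 0.05 on A); factor =
2^(inverse-variance weighted mean of surviving M values); factors
rescaled to geometric mean 1. An unweighted trimmed mean is available by
flag. The pseudocount defaults to 1 on the CPM scale; neither it nor the
trims are claims about any published analysis — they are this package's
defaults, configurable.

TMM is the natural choice for fluids with strong solute/volume
variability: library size and composition both vary with hydration and
voided volume, and a pure depth normalization would skew between-sample
comparisons.

## Cell-type gene profiles and signature scores

A gene joins the profile of cell type *c* iff its basis value is at
least `min_cpm` (default 10 CPM) **and** at least `fold_threshold`
(default 10×) times the largest other column. Columns are renormalized
to CPM internally, so the rule is invariant to global rescaling of the
basis. With a fold threshold above 1 a gene can satisfy the rule for at
most one column, so profiles are disjoint by construction. This rule is
a transparent, testable design choice of this package, with both knobs
in config.

The signature score of sample *j* is the arithmetic mean of the
log2(CPM·TMM+1) values of the N profile genes present in the filtered
matrix. Profile genes filtered out of the matrix are dropped and N
adjusted (and recorded), never imputed as zero — treating missingness as
zero would conflate count filtering with biology. The default count
filter keeps genes with ≥1 count in ≥25% of samples.

## Differential expression

Per gene, ordinary least squares of log2-CPM(+TMM, pseudocount 1) on
[intercept, class, covariates]; the class coefficient is the log2 fold
change and its t statistic (df = n − p) gives the p-value. BH at 0.05
with a minimum |log2FC| of 0, i.e. no fold-change floor beyond sign.
Collinear designs are rejected with the offending columns named. 95%
log2FC CIs: samples resampled with replacement within class, model
refit, percentile bounds with the point estimate appended; degenerate
(collinear) resamples are redrawn.

This is deliberately a plain linear model, not an empirical-Bayes
moderated fit: per-gene variances are not shrunk, so in very small
cohorts moderated pipelines will rank low-variance genes differently.
The default gene filter keeps genes with CPM ≥ 1 in at least
`min(n_A, n_B)` samples.

Spot creatinine (mg/dL) and RNA-isolation volume (mL) are the canonical
covariates: urine solute concentration varies with hydration and voided
volume, confounding class comparisons if ignored.

## Enrichment and integration

Over-representation is the upper-tail hypergeometric probability
`P(X ≥ k)` (observed overlap included) with universe M, set size K after
universe intersection, query size n. BH runs across all sets tested in
one invocation; sets empty after universe intersection are untestable
and excluded from the family (they would only inflate m), while sets
with zero *overlap* remain in it. Default universes: genes surviving the
DE filter for pathway enrichment; the union of profile genes for
cell-type enrichment. The joint table keeps pathways with adjusted
p below alpha in both omics.

Subsystem integration joins measured profile genes and annotated
metabolites through a reaction table (reaction id, subsystem, gene or
metabolite participant). Co-membership requires only a shared subsystem
by default — matching the subsystem-level resolution of the output — with
a stricter shared-reaction mode behind a flag. A subsystem is retained
iff it has ≥2 genes OR ≥3 metabolites (inclusive disjunction; the
alternative and-like reading is available by raising both minima).
Currency metabolites (water, protons, ATP, ...) are excluded from
metabolite counts via a configurable stop-list since they connect
essentially every subsystem.

## Metabolite annotation

Candidates must match precursor m/z within 0.01 Da in the same
ionization mode (positive and negative injections are never
cross-matched). If the library entry has a method-specific retention
time, |ΔRT| ≤ 0.4 min is required; entries without a known RT skip the
RT test. When both feature and candidate carry MS2 spectra, the
similarity gate is mandatory: cosine of square-root intensities over
greedily paired peaks (closest mass first, each peak used once, 0.015 Da
pairing tolerance) must reach `min_ms2_similarity` (default 0.7), and a
failing spectrum rejects the candidate even when mass and RT agree.
Match levels are `ms1_rt_ms2` > `ms1_rt` > `ms1_only`; the best
candidate is chosen by level, then similarity, then smallest mass error,
then compound id, making annotation deterministic and independent of
library row order. All features matching a compound are reported;
deduplication of adducts/in-source fragments is left to the caller.
Manual curation of annotations has no computable form and is not
modeled.

## Sample QC

Each metric is rounded to the nearest tenth (half away from zero — the
spreadsheet convention; half-even available by flag) before an inclusive
comparison against its bound. The ribosomal read fraction threshold
ships at ≤ 0.5; 3' bias and intron/exon ratio have no universal pass
direction, so their thresholds are user-supplied configuration.
Computing the metrics themselves (from alignments) is upstream of this
package.

## Synthetic data: what it emulates and what it does not

The generator produces every input with known truth from one seed:

- **Atlas**: negative-binomial counts (var = μ + φμ², φ default 0.3)
  around per-type gene means; each cell type gets planted marker genes
  whose mean exceeds every other type by at least the requested fold
  (default 10×; construction places them at 2× that so the guarantee
  survives sampling noise at small cell counts).
- **Bulk cohort**: per sample, cell-type fractions ~ Dirichlet; group B
  adds a constant to selected concentration parameters, which keeps
  fractions on the simplex by construction. Expected gene proportions
  are the basis-weighted mixture; planted DE genes multiply their
  expected proportion by 2^lfc in group B. Counts are one multinomial
  draw at a depth sampled uniformly from a range — so column totals
  equal the drawn depth exactly and depth variability (the synthetic
  stand-in for solute/volume variability) is exactly testable.
- **Metabolome**: a spectral library with minimum precursor spacing of
  3× the MS1 window (so a decoy offset from one entry can never fall in
  another's window), true-match features inside all tolerances with
  noisy MS2 copies, and decoys offset in exactly one dimension (mass,
  RT, or every MS2 fragment) by tolerance + margin, isolating each rule.
- **QC metrics**: passing baselines with designated planted violations.

Frozen end-to-end study conditions (the pipeline's simulate defaults):
5 cell types × 400 genes, 30 cells/type, 6 vs 12 samples, concentration
30 with +15 on one cell type in group B, depths U(1e5, 4e5), 25 planted
DE genes at log2FC 2 forming the planted pathway, 120 LC-MS features
with 12 decoys. The depth range is a desk-scale stand-in for ~30M-read
libraries; at these depths counting noise keeps composition-driven
background DE from flooding the enrichment universe, which is what makes
pathway enrichment a meaningful readout at this problem size.

Deliberately not emulated: read-level artifacts (the pipeline consumes
count tables), isoform structure, batch effects beyond library depth,
adduct networks, chromatographic drift, and biological covariance
between the planted covariates and expression. Passing tests therefore
demonstrate correctness of the estimators and rules under the stated
generative model, not robustness to real-data artifacts upstream of it.

## Numerical choices and degenerate inputs

- All randomness flows from one integer seed through numpy Generators;
  the pipeline fans one global seed out to per-step seeds by fixed
  offsets so steps rerun in isolation reproduce byte-identical outputs.
- Zero-total bulk samples, empty libraries/universes and collinear
  designs raise typed errors naming the offender; unresolvable samples
  (all-zero NNLS solution) are dropped with a warning rather than
  fabricating a row.
- Bootstrap percentile intervals always append the point estimate;
  degenerate resamples are redrawn with an attempt cap.
- BH uses a stable mergesort so tied p-values adjust identically across
  platforms; annotation ties break by mass error then lexicographic id.

## Known limitations

- OLS-on-log2-CPM differential expression has no variance moderation;
  with n per class below ~5 its p-values are noticeably noisier than
  moderated alternatives.
- The gene-resampling CI understates uncertainty when the basis itself
  is estimated from few cells.
- The profile-derivation rule and the count filters are declared
  package defaults, not reconstructions of any particular published
  supplementary procedure.
- Deconvolution quality degrades with basis collinearity; the
  collinearity table is diagnostic, not corrective.
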