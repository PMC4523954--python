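# Methods

This note documents the statistical models in `hlagrs`, the choices made
where the design was open, and what the synthetic data can and cannot
establish.

## Liability-threshold cohort simulator (`hlagrs.simdata`)

Each individual draws two HLA haplotypes i.i.d. from a four-label pool
with default frequencies DQ2.5 0.11, DQ2.2 0.05, DQ8 0.08, neutral 0.76
(giving ~42% of the population carrying at least one risk heterodimer,
within the range reported for European-ancestry populations).  The
haplotypes determine DQA1/DQB1 alleles and hence a heterodimer state
with precedence DQ2.5-hom > DQ2.5-het+DQ2.2 > DQ2.5-het > DQ2.2 > DQ8 >
none.  Liability is

    L = mu_state + sum_j beta_j z_j + e,     e ~ N(0, 1),

where `z_j` is the standardized dosage of causal SNP `j` (allele
frequencies Uniform(0.05, 0.5), effects `beta_j ~ N(0, sd^2)`, default
sd 0.15 over 20 causal SNPs).  An individual is a case when `L` exceeds
a threshold solved analytically (Brent's method on the normal survival
function) so that prevalence within the carrier stratum equals
`prevalence_target` (default 10%, the at-risk stratum).

The state shifts are not measurable quantities; they were solved once
against the composition targets — carrier-stratum prevalence 10%, case
composition ~88% DQ2.5 / ~4% DQ2.2 / ~6% DQ8 with <1% non-carrier
cases, and a homozygote:heterozygote risk ratio of ~2.5 — and frozen at
(2.74, 2.50, 1.83, 0.66, 0.66, −2.50) for
(hom, het+DQ2.2, het, DQ2.2, DQ8, none).  The het+DQ2.2 compound state
carries extra risk so that the 3-level haplotype code is genuinely more
informative than zygosity alone, mirroring the real gene-dose
architecture.  The `none` shift is low enough that non-carrier disease
probability stays below 1% for any polygenic liability within ±3.

`disease_probability(state, g, params)` is the exact closed form of the
same model (`Phi_c(threshold − mu_state − g)`), so its cohort average
matches the realized case fraction up to Monte-Carlo error — this
identity is tested.

Contaminants for QC testing: exact duplicates (genotypes copied before
missingness), parent-offspring pairs (child alleles transmitted
Bernoulli(d/2) from the parent's dosages and a random mate), and
ancestry outliers drawn from Balding–Nichols-style Beta-drifted allele
frequencies at Fst 0.05.  An optional HLA-region channel emits binary
present/absent markers tagging the risk haplotypes with a 5% flip rate,
emulating imputed non-SNP markers.  Missingness is injected last,
uniformly at rate 1% by default.  All randomness flows from one master
seed through named child streams, so cohorts are bit-reproducible.

What the simulator does **not** emulate: linkage disequilibrium between
SNPs (variants are independent given ancestry), chromosome-scale
coordinates, genotyping batch effects, and imputation-quality
gradients.  Tests passing on these cohorts show the machinery is
correct under the stated architecture, not that real-data predictive
performance would match.

## Quality control (`hlagrs.qc`)

Variant filters (conjunctive, order-free): non-autosomal (chromosome
outside 1–22), MAF < 1%, missingness > 10%, Hardy–Weinberg exact test
in controls P < 5e-6, case/control differential missingness (Fisher
exact) P < 1e-3.  The HWE test is the classic two-sided exact tail — the
sum of conditional heterozygote-count probabilities no larger than the
observed one, computed by the standard ratio recurrence in log space;
mid-p is deliberately not used.  Individuals with > 10% missingness are
removed.

Relatedness: method-of-moments IBD.  Pairwise IBS0/1/2 counts are
compared with their expectations under IBD states 0/1/2 given sample
allele frequencies; the state equations are solved sequentially and
pi-hat = P(IBD=2) + P(IBD=1)/2.  The per-state estimates are left
unclipped before combining (clipping each at zero biases pi-hat upward
by ~0.02–0.03 for unrelated pairs at a few thousand SNPs); only the
final pi-hat is clamped to [0, 1].  Pairs with pi-hat > 0.1 are
flagged and the member with higher missingness (ties: lexicographically
larger ID) removed.  All pairwise quantities are computed as one-hot
matrix products, so cohorts of a few thousand are handled in seconds.

PCA outliers: on LD-thinned (greedy windowed r² pruning, defaults
r² 0.2 / window 50 / step 5), standardized, mean-imputed dosages,
individuals more than 3 SD from the per-PC median on any of the top k
PCs are removed; two passes by default.  k defaults to 50 and is
truncated to min(n−1, m) with a warning.  Note the false-removal rate
grows with k (roughly 1−0.9973^k per pass for null PCs), and the
detectability of a drifted group depends on its share of the cohort:
at Fst 0.05 a group needs to be roughly ≥3% of individuals at ~2000
SNPs to stand out on the top PCs.  The QC recall tests therefore run
with small k and outlier fractions in the detectable regime.

Population differentiation: Weir–Cockerham Fst per variant (components
a, b, c from cluster sizes, allele frequencies and heterozygosity),
with the mean taken as a ratio of sums; variants monomorphic across all
clusters are undefined and excluded.

## Sparse SVM (`hlagrs.sparse_svm`)

The objective is the squared hinge with elastic-net penalties (see
README).  Coordinate updates are proximal majorization steps: along
coordinate j the loss gradient is Lipschitz with constant
(2/n)Σᵢx²ᵢⱼ, so the step with curvature h_j = (2/n)Σᵢx²ᵢⱼ + 2λ₂
followed by soft-thresholding at λ₁/h_j is a true majorizer and the
objective is monotone nonincreasing across sweeps (asserted in tests).
The intercept is unpenalized.  After the first sweep the solver
iterates on the active set and re-checks the full coordinate set before
declaring convergence (max coordinate change < tol; defaults tol 1e-6,
1000 sweeps, fixed cyclic order).  λ₁_max is computed from the loss
gradient at the intercept-only optimum, so the first path point has
exactly zero active weights; the path is warm-started along a
log-spaced decreasing grid (defaults: 100 points to ratio 0.01 for
standalone paths; CV uses shorter grids).  Weights below 1e-12 are
snapped to exact zeros.  The inner kernels are numba-compiled.

Standardization (mean imputation of missing dosages, centering, unit
variance) is estimated on training folds only and frozen for test and
external data — the leakage guard that the permutation-null acceptance
test exercises end to end.

## Cross-validation and consensus (`hlagrs.cv`)

10 repetitions of stratified 10-fold CV; each training fold gets its
own standardizer and its own λ₁ grid (grids are aligned across folds by
index, as in warm-started path solvers).  The AUC-versus-sparsity curve
smooths test AUC against log10(1 + nonzero count) with LOESS (local
linear, tricube weights, span 0.75, no robustness iterations, via
statsmodels lowess); smoothed values are clipped to the raw AUC range
so boundary extrapolation can never leave the data envelope, and with
fewer than 10 points the raw means are used.  Penalty selection
maximizes the smoothed curve, breaking ties toward sparser models.

The consensus keeps variants with selection frequency strictly greater
than 0.6 over the 100 fold-fits.  Weights are averaged over **all**
replications (zeros included) — the literal reading of averaging over
replications — with averaging over selecting replications available as
an option.  Exported weights are de-standardized (divided by the
training-fold SD) so the score file applies to raw dosages; the
intercept is dropped since rank-based evaluation is shift-invariant.
The pipeline falls back to denser grid points when the selected penalty
leaves an empty consensus.

## Scoring (`hlagrs.scoring`)

Scores are weighted **sums** (not per-allele averages) of aligned
dosages.  Effect alleles matching the counted allele use the dosage
as-is; matching the other allele flips to 2−d; matching neither drops
the variant with a warning.  Missing dosages are replaced by twice the
effect-allele frequency observed in the panel.  Palindromic (A/T, C/G)
variants pass through exact matching with a logged flag; no strand
inference is attempted.

## Evaluation (`hlagrs.evaluation`)

AUC is Mann–Whitney concordance with half credit for ties, computed via
midranks; DeLong structural components give the variance for CIs and
the paired covariance for score comparisons.  The paired DeLong test
stands in for Harrell's paired concordance test: for uncensored binary
outcomes both compare paired concordance, and the result object records
which test was used.  ROC convention: positive iff score ≥ threshold,
thresholds at the unique observed scores with a +inf sentinel, ties
sharing a threshold.  `ratio_at_sensitivity` uses the largest
(nearest-attainable) threshold reaching the target sensitivity —
no interpolation.  The stratified bootstrap resamples cases and
controls separately with preserved stratum sizes (default B=10,000;
tests use scaled-down B), reports the mean difference and percentile
2.5/97.5% CI, and redraws replicates with unattainable targets
(warning if >1% of B).

## Pipeline (`hlagrs.pipeline`)

Stage order: simulate/load → QC → HLA typing → restrict to DQ2.5
carriers → CV grid → consensus → external scoring → evaluation.
Training and validation are separate cohorts sharing the causal
architecture with a small allele-frequency drift (Fst 0.01 by default),
emulating training in one population and validating in another; their
ID sets are asserted disjoint.  The JSON report is validated against a
bundled structural schema (required keys and types) and is
byte-identical for identical config and seed (floats rounded to 10
decimals, keys sorted).

## Problem sizes

The test suite runs everything at desk scale by choice: the score-
ordering check simulates ~4800 individuals per cohort (netting ~1000
DQ2.5+ each) over 2000 SNPs with 20 causal effects of SD 0.25 — a
planted-signal strength at which a few hundred training cases can
recover a transferable score — with a single L2 penalty (1.0, the value
at which CV results are reported) and an 8-point L1 path.  The
permutation-null check uses smaller training cohorts and a 4000-
individual validation set so the null AUC band is tight.  Bootstrap
contracts are tested at B=2000.

## Known limitations

* No LD in the simulator, so consensus selection behaves more cleanly
  than on real arrays where tags split selection frequency.
* The IBD estimator omits plink's finite-sample corrections; at a few
  thousand markers its unrelated-pair noise is ~0.01–0.02 SD, adequate
  for the 0.1 flag threshold but not for fine relationship inference.
* Weir–Cockerham Fst assumes biallelic variants and ignores missing
  data beyond per-cluster exclusion.
* The imputed-marker channel models only presence/absence tagging of
  the three risk haplotypes, not amino-acid polymorphisms or
  imputation-quality variation.
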