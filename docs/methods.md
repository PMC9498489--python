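# Methods

This note documents the models and procedures implemented in `translasso`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that matter for
reproducing results.

## Problem setting

Given integer read counts for ~10³–10⁴ genes over a few hundred samples
and per-sample phenotype labels (diagnosis control/UC/CD, age group,
disease-activity grade 0–4), the pipeline searches for transcripts that
discriminate a case group from a control group *stably* — across
cross-validation folds and across a whole range of penalty strengths —
rather than optimally in any single fitted model. The output of interest
is a per-transcript occurrence count, not a classifier.

## Normalization

Size factors use the median-of-ratios estimator: for sample *j*,
*s<sub>j</sub>* = median over reference genes *i* of
counts<sub>ij</sub> / (∏<sub>v</sub> counts<sub>iv</sub>)<sup>1/m</sup>,
where the reference set contains only genes with strictly positive counts
in every sample. Size factors are left unnormalized (no rescaling to unit
geometric mean); they are identified up to a common scale, and only their
ratios matter downstream because each gene is re-standardized before PCA
and before the regression.

The expression value is log₂(count / *s<sub>j</sub>* + 1). The order —
divide, then add the offset, then log — is the only one in which a zero
count maps to exactly 0 for every size factor, which keeps "absent"
unambiguous after normalization. Consequently all normalized values are
≥ 0 and a value is 0 iff the raw count was 0.

Gene filtering removes genes whose **total count across samples** is ≤ 10
(boundary exclusive: a total of exactly 10 is removed). "Expression ≤ 10"
could also be read per-sample or as a mean; the total-count reading is the
loosest common prefilter and is exposed in the configuration
(`filter_threshold`) so stricter variants can be swapped in. Size factors
are computed on the post-filter matrix, matching the filter-then-normalize
stage order.

## PCA preselection

Per contrast, genes are standardized across the contrast's samples (mean
0, sd 1, *n* − 1 denominator) and a PCA is computed by SVD with genes as
variables. For each of the first `n_pcs` = 3 components, genes are ranked
by squared loading (squared loadings on a unit-norm eigenvector sum to 1
and are the standard sign-invariant measure of a variable's contribution);
the shortest prefix reaching `pc_variance_fraction` = 0.95 of the
component's squared-loading mass is kept, and the union over components is
the feature set. Ties in squared loading break by input gene order, and
each component's sign is fixed so its largest-magnitude loading is
positive — both purely for determinism across linear-algebra backends.

Two points were genuinely open and are configuration flags:

* **Which samples enter the PCA.** Default: all samples of the contrast
  (cases + controls). `pca_include_controls = false` restricts the PCA to
  cases only; the selected genes are then used for the same two-class fit.
* **When the PCA runs.** Default: once on the full contrast subset before
  cross-validation. This means the preselection has seen the held-out
  samples (their expression, not their labels), a mild leak that the
  `nested_preselection` flag removes by recomputing the selection inside
  each training fold. The default reproduces the simpler, common ordering;
  the flag exists for leakage-free performance estimates.

## Box-constrained lasso

The classifier solves

min (1/n) Σᵢ [−yᵢηᵢ + log(1 + e^{ηᵢ})] + λ‖β‖₁  s.t. −0.1 ≤ βⱼ ≤ 0.1,

with ηᵢ = β₀ + xᵢᵀβ and an unpenalized, unconstrained intercept. Features
are standardized (1/n variance) on the training data; bounds therefore act
on the standardized scale, where a common magnitude is comparable across
genes. The practical effect of the box is that no single transcript can
dominate: discriminative weight is forced to spread over several genes,
which is what makes occurrence counting informative.

The solver is outer IRLS (weights p(1−p) floored at 10⁻⁵) around cyclic
coordinate descent. Because the one-dimensional coordinate problem —
penalized quadratic plus box — is convex piecewise-quadratic, its exact
minimizer is the soft-threshold solution clipped to the box; no projection
error is introduced. A step-halving safeguard interpolates toward the
previous iterate whenever the IRLS surrogate oversteps, making the true
objective non-increasing across accepted outer iterations. The inner loop
alternates full sweeps with active-set-only sweeps and is JIT-compiled
(numba), which keeps the 400-fit cross-validation grid at
2,000-gene scale in the low seconds.

Numerical settings: coefficient-change tolerance 10⁻⁷, KKT tolerance
10⁻⁶, at most 200 outer iterations and 10,000 coordinate sweeps per fit.
Coefficients with |βⱼ| ≤ 10⁻⁸ are snapped to exact zero at the end of a
fit so the active set (|βⱼ| > 10⁻⁸, the occurrence-count criterion) and
the stored coefficients agree. Convergence is declared only when an
explicit Karush–Kuhn–Tucker residual — including the intercept gradient,
with bound coordinates violated only when the projected subgradient points
back inside the box — is below tolerance; non-convergence returns a
flagged fit rather than raising. λ_max = maxⱼ |xⱼᵀ(y − ȳ)|/n gives the
smallest penalty with an all-zero optimum and is used in tests as a
closed-form anchor.

Fits along the λ grid (0.01 … 0.40, step 0.01) run from the largest λ
down with warm starts. Sweep order is input feature order; all tie-breaks
are deterministic, and two runs with the same seed produce byte-identical
report files.

The coefficient bounds default to ±0.1 (`coef_lower` / `coef_upper`);
tighter bounds such as ±0.05 are a one-line configuration change.

## Cross-validation, λ selection, stability

Folds are stratified (per-class round-robin after a seeded shuffle), so
per-fold class counts deviate from proportionality by at most one sample;
without stratification the small active-disease classes could yield
one-class test folds. Standardization parameters come from the training
fold only and held-out samples are projected onto them.

Held-out performance is the Mann–Whitney AUC (ties ½, computed via
average ranks). An empty model produces constant scores and hence AUC
exactly 0.5.

λ selection: per λ, the median of the fold AUCs above the null cutoff
(0.5) is computed over converged fits; a λ with no qualifying fold is
ineligible. Among eligible λ the **largest** whose median is within
`lambda_tolerance` = 0.01 of the best is selected — an analogue of the
one-standard-error convention operationalizing the precision/shrinkage
tradeoff. Non-converged fits are excluded from selection but still counted
for occurrences (both events are logged).

Occurrence counts tally active-set membership over all
n_folds × |grid| = 400 (fold, λ) models; 400 is the ceiling. The final
model is a warm-started refit on all contrast samples at the selected λ.
The reported AUC is the cross-validated one — the median of the 10
held-out fold AUCs at the selected λ — never the resubstitution AUC of
the refit. The 90 % interval is the 5th–95th percentile of those fold
AUCs; a DeLong interval on the full-data refit's scores is reported
alongside in `summary.json` for reference.

"Active disease" maps to grades 3–4 and "remission" to 0–1; grade 2 is
excluded from the activity contrasts by default (`grade2_policy` can
reassign it to either side). The 0–4 scale itself carries no canonical
cut, so the conservative choice drops the ambiguous middle grade.

## Synthetic data

The generator draws counts NB(μ, φ) with variance μ + φμ² (gamma–Poisson
mixture) and mean μᵢⱼ = sⱼ·2^(mᵢ + Δᵢ·caseⱼ + bᵢⱼ): log-normal size
factors sⱼ, uniform per-gene log₂ baselines mᵢ, planted log₂ fold change
Δ on signal genes in cases, and a per-block shared standard-normal latent
factor scaled by √ρ producing co-expressed gene blocks — the structure the
PCA stage is designed to summarize. Signal genes are drawn outside the
blocks by default (`signal_in_blocks` flips this), so tests can separate
preselection behaviour from regression behaviour.

Defaults describe the reference test cohort: 2,000 genes, 100 cases + 100
controls, 20 signal genes at Δ = 1.5, φ = 0.2 (moderate whole-blood-like
overdispersion), size-factor log-sd 0.2 (~±20 % library-size spread), five
blocks of 20 genes at ρ = 0.3, and half the cases labelled active (grades
3–4). Cases alternate UC/CD and samples alternate adult/child so all 12
contrasts are populated.

Deliberately **not** emulated: empirical mean–dispersion trends, batch
effects, medication covariates, gene-length or GC biases, and any
dependence between disease activity and expression beyond the planted
case effect. Passing the recovery tests therefore shows the pipeline's
machinery is correct and sensitive under its own model assumptions — not
that it would achieve comparable AUCs on a real cohort, where effect
sizes are smaller and structure is messier.

## Scales used in validation

The recovery experiment runs the full default cohort (400 fits on ~1,700
preselected features; a few seconds with the JIT-compiled solver). The
permuted-label null control runs at 500 genes over 20 permutations; the
per-λ medians of the fold AUCs pooled across permutations stay within
[0.35, 0.65] (individual permutation × λ medians of only 10 fold AUCs are
noisier, so the band is asserted on the pooled summary). Solver
correctness is certified against an independent accelerated
proximal-gradient (FISTA) oracle on 200 random small instances, agreeing
to 10⁻⁶ in objective and 10⁻³ per coefficient, and by KKT residuals
< 10⁻⁶ on every converged fit.

## Known limitations

* The default (non-nested) preselection sees held-out expression values;
  use `nested_preselection = true` for strictly leakage-free AUCs.
* The largest-λ-within-tolerance rule can behave erratically when no real
  signal exists: with permuted labels the qualifying-fold median is biased
  upward and an arbitrary λ may be chosen; inspect the null behaviour
  before interpreting small-cohort runs.
* Occurrence counts depend on the grid: a transcript active only at small
  λ is capped by how much of the grid lies below λ_max for that data.
* Only dense, desk-scale matrices are supported; no sparse input path,
  no elastic-net mixing (α is fixed at 1), and no multinomial or survival
  families.
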