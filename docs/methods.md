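# Methods

## Models

### Kinship linear mixed model

For transcript expression y (log2 intensity for mRNA; Ct among detected
samples for miRNA) with fixed-effect design X (intercept, covariates,
trait last):

    y = Xβ + g + e,   g ~ N(0, σ²g A),   e ~ N(0, σ²e I)

A is the additive (numerator) relationship matrix, computed from the
pedigree by the tabular method with missing parents contributing zero
(unrelated-founder convention) and individuals topologically sorted
internally; input order is preserved in all outputs. The kernel choice is
the standard default for pedigree mixed models: A = 2×kinship, diagonal
1 + inbreeding. All families are handled in one matrix regardless of
sub-cohort membership.

Fitting is REML. A is eigendecomposed once per (cohort, sample subset)
and shared across transcripts; in the rotated basis the covariance is
diagonal (σ²g d_i + σ²e), so the profiled REML criterion is optimized
over log λ, λ = σ²g/σ²e, by bounded scalar search on [e⁻¹², e¹²] with the
λ = 0 boundary checked explicitly. The trait test is the Wald χ² =
(β̂/se)² of the last design column against a 1-df χ² (equivalently z²
against the normal); the Wald form was chosen over a likelihood-ratio
test because it is what the two-part combination consumes and avoids a
second REML fit per transcript. With A = I the
variance split is non-identifiable, but β̂/se — and hence every reported
statistic — is invariant to it.

Degenerate inputs are hard errors: singular X (collinear columns
reported), constant response, n ≤ p + 2. p-values are floored at the
smallest subnormal double so BH input stays in (0, 1].

### Adaptive two-part test for Ct data

Detection rate d = fraction of samples with the miRNA detected (Ct below
the limit; the generator encodes non-detection as missing). Branching:

* d ≥ 0.90 — linear branch only: kinship LMM on detected samples, with
  the relationship matrix restricted to those samples and re-decomposed
  (decompositions are cached by detection pattern within a scan).
* d < 0.10 — logistic branch only: ordinary logistic regression of the
  detection indicator on trait + covariates. The logistic model carries
  no family random effect — a deliberate simplification; the detection
  indicator's dependence structure is weaker and a mixed logistic model
  would dominate the runtime of every scan.
* otherwise — both branches; χ² = χ²_linear + χ²_logistic referred to a
  2-df χ², whose upper tail is computed in closed form as exp(−χ²/2).

Both branches use the same covariate set. The two components are computed
on overlapping data and are not exactly independent, so the 2-df
reference is an approximation; the calibration suite measures the
resulting type-I error directly (see below) rather than "fixing" the
rule. Untestable branches (too few detected samples, non-convergent or
separated logistic fits) yield a flagged result with a missing p — never
a silent 0 or 1. Ct-scale effects are reported as fitted; pleiotropy and
concordance layers negate miRNA signs so that "positive" uniformly means
higher expression (higher Ct = lower expression). Trait values enter
untransformed by default; log transformation for skewed traits
(triglycerides, glucose) is the caller's choice.

Panel filters are two distinct knobs: panel inclusion (detected in ≥ 100
samples by default) and the coexpression filter (detected in > 200
samples by default).

### Multiple testing and the family-preserving split

BH step-up within trait × transcript class (mRNA and miRNA scans
corrected separately; coexpression corrected over the full pair list
jointly). Missing p-values pass through as missing. The
discovery/validation split shuffles families by seed and assigns each
greedily to the smaller set, so sets partition the cohort, no family
straddles, and the imbalance is bounded by the largest family size.
Validation FDR is recomputed within the validation set only.

### Surrogate variables

Two-step residual-SVD construction: residualize the mRNA matrix on the
known covariates, take top right-singular vectors (orthonormal in sample
space). Dimension selection, when not fixed, is permutation parallel
analysis: each transcript's residuals are independently permuted across
samples (50 permutations by default) and a component is kept while its
singular value exceeds the 95th percentile of the matching permuted order
statistic. This variant was chosen over iteratively reweighted SVA
because it is deterministic given the seed and directly testable; its
adjustment role is identical. SV selection then keeps an SV iff it
associates with ≥ 1 panel miRNA (two-part test, SV as predictor) below
α/n_miRNA — the 0.05/280 Bonferroni rule at the default panel. The
number of SVs selected is data-dependent by construction; only the rule
is fixed. SVs already spanned by the model matrix are pruned at covariate
assembly, which keeps designs full-rank and makes redundant adjustment a
no-op.

### Cell counts, coexpression, enrichment

Differential cell counts are imputed from mRNA expression by partial
least squares, one model per cell type (a multi-response variant would
share components; per-type models keep accuracies attributable), with
k-fold cross-validated Pearson accuracy reported per type. Measured
counts override imputed ones when both exist. Folds are sample-level and
seed-controlled; family-aware folding is available but off by default.

Coexpression pairs drop samples where the miRNA is undetected (only
detected Ct values are meaningful on the continuous scale; encoding
non-detection at a ceiling value would mix the two data types). Gene-set
over-representation is the one-sided Fisher exact test per GMT term,
computed as the hypergeometric upper tail in log space (survives
p < 10⁻³⁰⁰), significant below α/n_terms (0.05/825 at the default
collection); a two-sided option exists behind the ``alternative`` flag. The universe is the expression panel
restricted to the collection's genes. miRNA identifiers are matched
case-insensitively with the species prefix stripped; arm suffixes must
match exactly when present on both sides.

## Synthetic cohorts: what they emulate, and what they don't

`generate_cohort` draws pedigrees from {trio, nuclear-4,
three-generation-6}; traits are multivariate normal with means/SDs
typical of an untreated middle-aged cohort (BMI 26.9 (5) kg/m²,
HDL 62 (18), TG 104 (67), glucose 95 (13) mg/dL, SBP 117 (15),
DBP 74 (10) mm Hg; age 49 (12), 59% female) and a configurable
correlation matrix (defaults: adiposity positively correlated with
TG/BP/glucose, negatively with HDL; SBP–DBP 0.7). Traits and expression
both carry polygenic components with covariance σ²g·A (trait h² 0.4,
expression h² 0.3 by default), so relatives correlate the way the mixed
models assume. mRNA values add batch shifts, age/sex nuisance on 20% of
genes, latent cell-fraction loadings on a leading gene block (the signal
PLS imputation recovers), and planted trait effects in expression-SD per
trait-SD. miRNA values are generated on the Ct scale with the sign
inverted and censored deterministically at the threshold (27 by
default): no assay dropout noise, matching the binarization rule the
two-part test implements. Planted coexpression injects a miRNA's
standardized latent Ct into chosen mRNAs.

Not emulated: probe-level array artifacts, sequence realism, medication
effects (the generator emits an untreated cohort), non-Gaussian trait
tails, and assay-level stochastic dropout. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model — not robustness to every failure mode of real
expression data.

## Calibration and recovery studies

`pedscan.calibration` holds the seeded simulation drivers the acceptance
script and tests run:

* linear-branch type-I error: 2,000 null replicates on a 500-sample
  nuclear-family cohort, responses drawn in the eigenbasis (exactly
  N(0, h²A + (1−h²)I));
* combined-branch type-I error at 50% detection, same scale — expected
  to be close to but not exactly nominal because of the shared-data
  2-df approximation;
* oracle agreement: eigendecomposition LMM vs explicit-inverse GLS at
  known variance components (n ≤ 50); tabular A vs 200,000 gene-dropping
  meioses on ≤ 12-member pedigrees;
* recovery: 20 planted 0.3-SD effects among 200 transcripts at ~1,000
  samples (power, sign errors at FDR < 0.05); a transcript planted on all
  six traits (simulated uncorrelated for this study — with correlated
  traits the six additive effects partially cancel in marginal scans,
  which would test the trait model rather than the tally); a planted
  miRNA–mRNA pair; 50 confounded null panels scanned with and without
  selected SVs;
* replication: planted effects discovered at FDR < 0.05 in the discovery
  half re-tested in the family-preserving validation half.

Problem sizes (n = 500/1,000 cohorts, 2,000 replicates, 50 seeds) were
chosen to give Monte-Carlo standard errors well inside the tolerance of
each check while keeping a full run to a couple of minutes on one CPU.
Module-level tests run smaller versions of the same designs; the full
sizes live in the acceptance layer.

## Known limitations

* The logistic branch ignores family structure; with strong polygenic
  detection heritability its component can be mildly miscalibrated.
* The combined 2-df reference assumes independence of components that
  share data; measured type-I error at 50% detection stays within
  [0.035, 0.065] in our studies but is not exactly nominal.
* REML Wald tests carry no small-sample df correction; at n below ~100
  the scan is slightly anticonservative.
* Parallel-analysis SV selection assumes exchangeable residuals within
  transcript; heavy-tailed residuals can over-select components.
* The pairwise coexpression scan is O(n_miRNA × n_mRNA) LMM fits; it
  partitions over miRNAs (`n_jobs` in the library, `--threads` at the
  CLI) and results are identical for any partitioning because FDR is
  applied once over the merged pair list.
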