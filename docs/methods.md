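# Methods

`snplasso` implements a complete genome-enabled-prediction analysis for a
quantitative trait: simulate (or read) SNP genotypes, apply marker-level
quality control, construct a covariate-adjusted phenotype, reduce
dimensionality by LD clumping, fit an L1-penalized (LASSO) linear model by
pathwise coordinate descent, and assess prediction honestly with nested
k-fold cross-validation.  This note records the model, the numerical
choices, and the design decisions taken where the design was genuinely
open.

## Model

The trait model is the standard linear one: y = β₀ + Xβ + ε with X the
n × p dosage matrix (0/1/2 copies of the A1 allele) and ε ~ N(0, σ²).
With p ≫ n the OLS estimator is undefined, so coefficients are estimated
by the LASSO:

    (β̂₀, β̂) = argmin  (1/(2n)) Σᵢ (yᵢ − β₀ − Σⱼ βⱼxᵢⱼ)²  +  λ Σⱼ |βⱼ|

The intercept is never penalized.  **Scaling convention.**  We scale the
residual sum of squares by 1/(2n) (the glmnet convention) rather than
leaving it unscaled.  Under the unscaled form a given λ means something
different at every sample size; under 1/(2n) the cross-validated λ values
are commensurable across folds and data sets, which is what makes
"λ decreases as n grows" a meaningful statement.  The unscaled convention
remains available (`rss_scaling="plain"`, where λ_plain = 2n·λ); the two
produce identical solutions under that mapping, which is tested.

## Solver

Cyclic coordinate descent on internally standardized predictors
(population-SD scaling; coefficients are reported on the original dosage
scale).  The coordinate update is soft-thresholding,
β̃ⱼ ← S(gⱼ + vⱼβ̃ⱼ, λ)/vⱼ with gⱼ = (1/n)x̃ⱼᵀr and vⱼ the working-scale
column variance (exactly 1 when standardizing).  The path is fit on a
descending log-spaced grid from λ_max = maxⱼ|x̃ⱼᵀy_c|/n (the smallest
penalty with an all-zero solution) down to `lambda_min_ratio`·λ_max
(default 1e-4 if n > p, else 1e-2), warm-starting each grid point from the
previous solution.  At each λ the solver alternates one full sweep with
active-set iteration until the active set is stable, and declares
convergence when a full sweep changes no standardized coefficient by more
than `tol` (default 1e-7).  Every solution can be certified by the KKT
conditions (|gⱼ| ≤ λ + tol for zero coefficients, gⱼ = λ·sign(β̃ⱼ) ± tol
for active ones); the test suite checks zero violations at 1e-6 on all
converged fits and checks the objective is non-increasing sweep by sweep.

Sequential strong-rule screening (discard j when |gⱼ(λₖ₋₁)| < 2λₖ − λₖ₋₁)
is implemented but **off by default**: correctness first.  When enabled it
is always followed by a full KKT scan that re-admits any violator, so it
cannot change the solution — only the time spent; the equivalence is
tested.  The large cross-validation runs enable it.

Numerical details: cyclic (fixed-order) updates for determinism; missing
dosages are mean-imputed per SNP before fitting (preserves column means;
the standard choice in genotype prediction); constant columns are carried
with a frozen zero coefficient; float32 design matrices are accepted for
the large runs (residual updates accumulate in float64, and the sweep-wise
objective check uses a correspondingly looser slack).

## Nested cross-validation

Folds are uniformly random partitions with sizes differing by at most one
(no stratification or family-aware grouping — relatedness is handled
upstream by PC adjustment).  For each of the k_outer (default 10) outer
folds, a λ grid is computed from that fold's training set and shared by
all k_inner inner splits, so the per-λ mean validation MSE is well
defined; the selected λ minimizes that mean, ties resolving to the larger
(more parsimonious) λ.  The model is then refit on the full outer-training
set at the selection and the held-out fold predicted.  Pooled held-out
predictions yield Pearson r (bounded in expectation by √h² for a trait of
heritability h²), MSE, and the slope of the best-fit line of predicted on
observed (1 = perfect calibration; shrinkage pushes it toward 0).  Fold
bookkeeping asserts each sample is predicted exactly once, by a model that
never saw it, which rules out selection optimism.  A subtlety worth
knowing: under a pure-noise trait (h² = 0) the pooled r is not exactly
centered at zero but sits slightly *below* it (on the order of −√(k/n)),
because near-null models predict approximately the training-fold mean,
which is anti-correlated with the held-out fold — a generic property of
cross-validation, not leakage.  The calibration tests therefore check the
one-sided property (no positive optimism) plus a magnitude bound.

## Quality control

MAF uses the strict inequality (remove when maf < threshold, default
0.01); Hardy-Weinberg uses p ≤ threshold (default 1e-5) with the exact
conditional test (sum over heterozygote counts, given the allele counts,
of configuration probabilities not exceeding the observed one), computed
in log space; an asymptotic chi-square variant is available for
comparison.  The call-rate filter defaults to off.  Rules apply in the
fixed order MAF → HWE → call rate with each SNP attributed to its first
failing rule, so removal counts always reconcile with the input count.
HWE is computed on all samples (no founders-only logic).

## Phenotype construction

Triglyceride visits are analyzed on the natural-log scale (the base only
rescales effect sizes).  Baseline = mean of log visits 1–2, follow-up =
mean of log visits 3–4, each falling back to the single available visit;
samples missing both visits of either pair are dropped with a recorded
reason.  The follow-up is adjusted by OLS for baseline, age, center
(dummy-coded), smoking and the top-k genotype PCs (default 20), using
complete cases; the final phenotype is the standardized residual vector
(mean 0, SD 1, n−1 denominator — the choice of denominator is immaterial
at these n but fixed for test exactness).  PCs are computed after QC on
the full retained SNP set (mean-imputed, column-standardized dosages; SVD
scores scaled to unit variance; sign fixed by making each component's
largest-magnitude loading positive).  The Q-Q diagnostic reports expected
quantiles −log10((i−0.5)/m) and the genomic-inflation factor
λ_GC = median(χ²₁(p))/0.4549, an added diagnostic supporting the adequacy
of the PC adjustment.

## Association and clumping

Per-SNP simple regression of the final (already adjusted) phenotype on
dosage, complete-case per SNP, two-sided p on n−2 df; monomorphic SNPs are
flagged (β = 0, p = 1).  The Manhattan significance line defaults to the
genome-wide convention 5e-8 (configurable).  Clumping is the greedy
p-value-ordered procedure: the best unassigned SNP seeds a clump and
absorbs unassigned same-chromosome SNPs within ±window whose dosage r²
meets the threshold.  Defaults r² = 0.5, window 250 kb; index/member
p-value caps default to 1.0 because clumping serves here as pure
dimensionality reduction, not hit refinement.  Ties in the p-value
ordering break by position then SNP id, making the procedure fully
deterministic; r² is genotypic (dosage correlation over pairwise-complete
samples), requiring no phasing.  Cross-chromosome pairs never clump.

## Synthetic data

The generator exists so every stage is testable without cohort data; its
defaults are the study conditions of the analyses this package reproduces.

* **Genotypes**: block anchors drawn Binomial(2, maf) with
  maf ~ U(maf_low, maf_high) (defaults 0.05–0.5); within a block each
  non-anchor *allele* copies the anchor allele with probability c
  (`ld_copy_prob`), else is a fresh Bernoulli(maf) draw.  Allelic
  correlation is c, so dosage r² ≈ c² — direct, testable control of LD at
  desk scale, in place of coalescent realism.  Missingness is MCAR.
* **Phenotype**: y = βg + ε with a single causal SNP (default β = −0.44 on
  the dosage scale, causal maf 0.3 — a mid-range frequency, exposed as a
  parameter) and ε variance solved from the target heritability:
  σ² = β²·2f(1−f)·(1−h²)/h² using the column's empirical frequency f.
  This gives Var(genetic)/Var(y) → h² and corr(y, genetic) → √h² (≈ 0.224
  at the default h² = 0.05), which the tests verify by Monte Carlo.  The
  effect size is deliberately parameterized on the raw dosage scale: a
  standardized-genotype parameterization would tie β² to h²·Var(y) and
  could not represent β = −0.44 with h² = 0.05.  β = 0 with h² > 0 is
  rejected as contradictory.
* **Visit tables**: log-normal TG with subject-level covariate effects
  (age, 2-level center, smoking), a treatment shift between visits 2 and
  3, the causal genetic effect injected into the post-treatment change,
  within-subject visit noise and per-visit MCAR missingness.  This
  exercises the phenotype-construction stage end to end; with the causal
  effect at zero the resulting association p-values are uniform, which is
  tested.

What the generator does **not** emulate: real LD (haplotype-scale
correlation decaying with distance), realistic allele-frequency spectra,
family structure, dominance/epistasis.  Consequently, passing tests
demonstrate the pipeline's statistical machinery — calibration, shrinkage
behavior, sample-size dependence — not agreement with any particular
cohort.  In particular, with *independent* SNPs the cross-validated LASSO
shrinks a lone causal coefficient less severely than it does in real data,
where correlated neighbors split the signal; sample-size comparisons
(small-n heavy shrinkage vs large-n recovery, and the shrinking of the
selected λ as n grows) are preserved, absolute coefficient values are
reproduced only approximately.

## Problem sizes used in the test suite

The full-scale analyses (p ≈ 600k SNPs pre-clump) are not desk-scale; the
suite exercises the same designs at the sizes the package's own
simulations support well: the small-sample run at n = 700 with p = 56,000
independent SNPs (10 outer folds, 5 inner folds, 50-point λ grid), the
large-sample comparison at n = 7753 with p = 20,000, and the λ-vs-n
comparison over 5 seeds at p = 2,000.  Larger p changes the noise
threshold only through √log p, so these sizes preserve the phenomena under
study.  Monte-Carlo calibration checks (heritability, type-I error, λ_GC)
use 10⁴–10⁵ draws.

## Known limitations

* The HWE exact test is two-sided in the "sum of no-more-probable
  configurations" sense; mid-p variants are not provided.
* The clumping index/member p-caps retain any SNP not absorbed into a
  clump; with both caps at their defaults (1.0) this coincides with
  "index SNPs plus never-eligible SNPs".
* PC computation uses a dense SVD — fine to ~10⁴ samples, not optimized
  beyond that.
* The pipeline's visits mode assumes the visit table rows align with the
  genotype samples (true for the built-in simulator, checked by id when
  subsetting).
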