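# Methods

`drugrev` implements an integrated drug-repositioning analysis in three
stages — genetic signature imputation, perturbagen reversal screening, and
claims-based clinical validation — together with synthetic-data generators
that stand in for the large proprietary inputs (a GWAS meta-analysis, an
L1000-style perturbagen library, and a longitudinal claims database) while
preserving a known ground truth for every stage.

## 1. Signature imputation (TWAS)

**Model.** For a gene with eQTL weight vector `w` over its variants, GWAS
z-score vector `X` and LD (variant correlation) matrix `V`, the imputed
expression–trait association is

    Z_TWAS = wᵀX / sqrt(wᵀ V w)

which is N(0, 1) when the gene's genetically predicted expression is
unrelated to the trait. `V` is shrunk as `(1−λ)V + λI` (default λ = 0.1,
configurable) before forming the denominator; this stabilizes genes whose
weighted variants sit in near-perfect LD at the cost of a slight
deflation of |Z| when weights are spread across correlated variants. Genes
whose regularized denominator is numerically zero are skipped and logged.
The statistic is invariant to positive rescaling of `w`.

**Gene-level association.** Tissue selection requires per-gene disease
association p-values. We use the statistic S = Σ zᵢ² over the gene's
variants. Under the null z ~ MVN(0, R) for the gene's LD submatrix R, S is
a weighted sum of independent 1-df chi-squares with weights equal to R's
eigenvalues; the p-value is that distribution's exact upper tail, computed
by Imhof's inversion integral (a scaled chi-square shortcut is used when
all eigenvalues coincide). We deliberately compute the exact tail rather
than a two-moment chi-square approximation: the latter is off by ~10%
relative in ordinary LD configurations, which matters when p-values feed a
0.05 threshold. This component is a surrogate for a dedicated gene-based
association tool: it preserves the role (LD-aware gene-level p-values
feeding enrichment), not any particular tool's likelihood.

**Tissue enrichment and selection.** Genes with association p < 0.05 form
the disease gene set. Each tissue's panel is tested for enrichment with a
one-sided Fisher exact test on the 2×2 membership table over the gene
universe (a deterministic, oracle-checkable surrogate for tissue-specific
enrichment tools that work from gene lists). Selected tissues are the
union of (i) tissues with enrichment p < 0.05, (ii) the three
nervous-system tissues with smallest p — included regardless of
significance because of the neurological context — and (iii) whole blood.
Ties break by ascending p then tissue id, everywhere.

**Harmonization.** GWAS, LD, and weight sets are restricted to their
shared variants. When the weight set records alleles, swapped
effect/other alleles negate the GWAS z; variants with irreconcilable
allele pairs are dropped with a logged count.

## 2. Reversal screening

Both screens consume a disease signature (per-gene Z_TWAS) and a library
of perturbagen profiles (per-gene induced-expression z-scores, Level-5
style moderated z-scores), and are pure rank statistics — invariant to any
strictly monotone transform of profile values.

**Spearman screen.** For each tissue, the top 10% of genes by |Z_TWAS| are
selected (floor of fraction×G; at least 20 genes by default, else an
error). For each (signature, profile) pair, Spearman's rho is computed
with average ranks for ties over the gene intersection, and a one-sided
p-value for the alternative rho < 0 is taken from an exact permutation
enumeration when n ≤ 9 and from the t approximation
t = rho·sqrt((n−2)/(1−rho²)) otherwise (the t tail is empirically within
the 3-binomial-SD band at the 1e-4 threshold for n = 200 genes).
A perturbagen qualifies if any of its tissue/cell-context pairs reaches
p < 1e-4; no multiplicity correction is applied, matching the fixed
threshold design.

**Mann-Whitney reverser screen.** The signature's top 150 upregulated and
bottom 150 downregulated genes (ties by gene id; sets forced disjoint,
n reduced to floor(G/2) for small signatures) are located in each
profile's genome-wide ranking. Two directional U tests — "disease-up genes
rank low" and "disease-down genes rank high", each against all remaining
profile genes, continuity-corrected and tie-corrected — are combined as a
Stouffer score (z₁+z₂)/√2. Because the two tests share the pooled
ranking they are positively dependent, so the null score variance is
slightly above 1 (~1.09 at 150+150 sets in 2000 genes); this is a
property of the statistic, harmless because the screen uses score *ranks*:
per tissue, the top 200 profiles by score qualify, and the candidate set
is the union over tissues. For profiles with ≤ 10 genes the score's
p-value is computed by exhaustive label enumeration instead of the normal
tail (the normal approximation is unusable there, and the exact tail is
what a brute-force oracle reproduces).

**Intersection.** Final candidates are perturbagen names suggested by both
screens; an optional drug map flags approved members and deduplicates them
by drug name.

## 3. Claims-based validation

**Cohort.** From raw enrollment/diagnosis/prescription tables, five rules
applied in order with a per-rule attrition table: (1) first migraine
diagnosis (ICD-10 prefix G43) inside the accrual window defines the index
date; (2) at least one migraine-specific medication prescription; (3) at
least 180 days of continuous enrollment *before* the index date (the
anchoring of the 180 days is our reading; the rule is configurable);
(4) no ischemic heart disease (I20–I25), stroke (I60–I69) or TIA (G45)
diagnosis on or before index; (5) at least one day of follow-up.
Censoring is the earliest of enrollment end, study end, and the first
post-index diagnosis in the exclusion set plus heart failure (I50) — the
exclusion/censoring code sets are deliberately both configurable because
reasonable designs differ on whether heart failure belongs in both.
ICD-10 matching is by code prefix.

**Person-periods.** Follow-up is laid out as consecutive non-overlapping
365-day windows from index to censoring. We read "rolling 1-year window"
as consecutive rather than overlapping windows: overlap would double-count
outcome prescriptions and induce residual correlation beyond the random
intercept; a config knob allows overlapping windows for sensitivity. A
final partial window is kept when it spans ≥ 90 days, its length absorbed
by the offset. Per window: Y = count of acute-medication prescription
*records* (triptans, ergotamine, ditans — counted as records, not distinct
drugs), binary drug exposure (any exposure-coded prescription in the
window), covariate presence indicators assessed in the *same* window (the
covariate-assessment window's lag is unstated in the design we follow;
same-window assessment implies exposure/outcome simultaneity, a
limitation we inherit rather than resolve), age at window start
(continuous) and sex.

**Model.** One model per candidate drug:

    ln(Y_ij + 1) = β₀ + α·t_ij + Σ_k β_k x_kij + γ_i + ln(time_ij) + ε_ij

with γ_i ~ N(0, τ²) a per-patient random intercept and ln(time) an offset
(coefficient fixed at 1, implemented by moving it to the left-hand side).
The pseudo-count of 1 is taken literally. exp(α) is the relative risk of
acute-medication use under exposure, with a Wald 95% CI.

**Estimation.** REML. Because the model has a single random intercept, the
variance ratio θ = τ²/σ² is profiled: for fixed θ the group covariance
inverts in closed form (Woodbury), β and σ² profile out, and the REML
criterion is minimized over θ in one dimension (bounded scalar search on
log θ, with an explicit θ = 0 boundary check). This is exact, not an
approximation — it agrees with a general-purpose mixed-model optimizer
(statsmodels MixedLM, kept as an independent cross-check in the test
suite) to ~1e-7 on α — and is ~70× faster, which is what makes
simulation-based coverage checks at 400 fits practical. Singular designs
are detected by rank check and reported per drug; drugs with no exposed
(or no unexposed) windows are skipped, not fatal. No multiplicity
adjustment across drugs (per-drug CIs are reported, with an optional
Benjamini-Hochberg column available in the forest table utilities).

## 4. Synthetic generators — what they emulate and what they don't

**GWAS layer.** LD is block-diagonal AR(1) (within-block correlation
ρ^|i−j|): always positive definite, closed-form checkable, but far
simpler than human LD panels. Variants are split into contiguous per-gene
chunks; each gene's weight vector is drawn Gaussian over its variants and
normalized to wᵀVw = 1 with its largest entry positive (so a one-variant
gene has weight exactly +1 and E[Z_TWAS] equals the planted gene effect).
GWAS z-scores are drawn from MVN(V·W·b, V) with b nonzero only for causal
genes — the exact sampling model under which Z_TWAS is calibrated — drawn
block by block via Cholesky. Causal genes act through the first
nervous-system tissue's weights and are added to that tissue's panel, so
tissue enrichment has signal to find. Defaults: 5% causal genes with
effect magnitudes uniform on (2, 4), block size 5, ρ = 0.3 — desk-scale
stand-ins for a large migraine GWAS; passing tests shows calibration and
recovery under the stated sampling model, not robustness to real LD or
pleiotropy.

**Perturbagen library.** Planted reversers are −s·standardized(signature)
plus N(0, noise²) noise; mimickers flip the sign; all other profiles are
standard normal noise. Defaults s = 0.6, noise SD 1 make planted profiles
detectable but not trivial. Real L1000 structure (dose/time collapsing,
cell-line heterogeneity, correlated compounds) is not emulated.

**Claims layer.** Per patient: an index migraine diagnosis inside the
accrual window, enrollment spanning an integer number of windows
(1 + Poisson(mean−1)), a rule-2 qualifying prophylactic prescription at
index (deliberately not an acute code, so the outcome stays on-model),
and per-window counts Y = max(0, round(exp(L) − 1)) for the latent L
following the validation model exactly (β₀ = ln 5 by default — about five
acute prescriptions per unexposed patient-year, matching the order of
magnitude seen in claims data; τ = 0.5, σ = 0.6). Drug users (50% of
patients per drug) start exposure at a uniformly chosen window and stay
exposed. Prescription dates are uniform within windows; clinical
clustering is a non-goal. Configurable fractions of patients violate each
eligibility rule (pre-index I21, < 180 d enrollment, zero follow-up) so
the cohort filters are exercised. Because counts are rounded and floored
at zero, the log-linear model is correct only up to rounding; recovery
tolerances (|bias| ≤ 0.05 on the RR scale) allow for this. Recovery and
coverage studies plant one drug per dataset, mirroring the one-model-
per-exposure design: planting several effects in one dataset makes the
rounded outcome nonlinear in any single exposure and visibly distorts
coverage, which is a property of the generator, not of the estimator.

## 5. Numerical choices and tie-breaks

- Exact Spearman permutation p for n ≤ 9 (t approximation above);
  exact Mann-Whitney score tail for profiles with ≤ 10 genes.
- All ranking ties broken deterministically (ascending p, then id).
- LD symmetry validated chunk-wise with tolerance 1e-8, diagonal 1e-6;
  asymmetric inputs are rejected naming the offending cell.
- Degenerate inputs (constant profiles, zero weight vectors, empty gene
  intersections) are skipped with logged reasons rather than propagating
  NaNs.
- Simulation sizes in the test suite (5000 null genes for calibration,
  500-profile libraries over 20 seeds, 100 replicates of 2000-patient
  claims per planted effect) were chosen as the smallest scales at which
  the targeted properties are statistically decisive. The reproduction
  script uses 3000 null genes, five library seeds, a 100k-profile null
  screen, and 30 replicates per planted RR (100 for the null-coverage
  proportion, which is binomial and noisier).

## 6. Known limitations

- The imputation layer implements the printed z-score statistic only; no
  Bayesian fine-mapping of credible gene sets is performed, and all gene
  z-scores are passed downstream.
- The Mann-Whitney reverser construction is our reconstruction of a
  published web service's "reverser" ranking from its stated inputs and
  test; the service's internals are not public.
- Same-window covariate/outcome assessment (see §3) and prefix-based
  ICD-10 matching are simplifications carried from the design being
  reproduced.
- The claims generator does not emulate real comorbidity co-occurrence,
  pharmacokinetics, or informative censoring; null-calibration and
  recovery results should be read as internal-validity checks, not as
  evidence about confounding in real claims data.
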