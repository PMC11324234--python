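# Methods

## The problem and the model

`cordmrs` builds a cord-blood DNA-methylation risk score (MRS) for
maternal smoking. The individual-level model is linear,

    y = Xγ + ε,

with `X ∈ ℝ^{n×p}` the column-standardized β-value matrix over `p` CpGs
and `y` the smoking phenotype. Because discovery-scale individual data
are rarely shareable, γ is estimated *from summary statistics alone*,
lassosum-style: marginal discovery effects are reduced to
pseudo-correlations and the CpG–CpG covariance `X′X` is replaced by a
reference correlation matrix estimated from the validation cohort. The
solver minimizes

    f(γ) = γ′(R + λ₂I)γ − 2 b′γ + 2 λ₁‖γ‖₁ ,

the elastic-net generalization of the lasso objective. Some published
formulations carry an `n` multiplier on the quadratic term; since (λ₁, λ₂)
are tuned over a grid, that constant is absorbed into the penalty scale
and is omitted here without loss of generality.

### From summary statistics to `b`

Discovery tables give per-CpG (effect, SE, N). Raw EWAS-catalog
coefficients are not on the standardized-`X` scale, so the default
mapping is the standard summary-statistic pseudo-correlation

    z_j = effect_j / SE_j ,   b_j = z_j / √(N_j + z_j²) ,

which preserves sign, is bounded in (−1, 1), and is exactly the sample
correlation implied by a Wald z at sample size N. A raw-coefficient
pass-through (`prepare_b(..., raw=True)`) is retained as a sensitivity
mode for discovery analyses already run on standardized predictors.

### Solver

Cyclic coordinate descent with the soft-threshold update

    γ_j ← S(b_j − Σ_{k≠j} R_{jk} γ_k, λ₁) / (R_{jj} + λ₂),
    S(x, λ) = sign(x)·max(|x| − λ, 0),

maintaining the residual `r = b − Rγ` incrementally. Sweeps run over an
active set (nonzero coordinates plus coordinates violating stationarity);
convergence requires the maximum coefficient change to fall below `tol`
(default 1e-6) *and* the full KKT conditions to hold. The kernel is
compiled with numba when available, with an identical pure-Python
fallback. Warm starts follow the λ₁ path downward.

When `p` exceeds the reference sample size and λ₂ = 0, `R` is rank
deficient and the objective has flat directions: coordinate descent still
decreases the objective but coefficient changes can shrink slowly, so
those grid cells may hit the sweep cap. `tune` therefore caps sweeps per
grid cell (default 200) and records a `converged` flag per cell;
well-posed cells converge far below the cap, and in practice the selected
cell is a converged one. `elnet_summary` itself defaults to 10,000 sweeps.

### Tuning

λ₁ runs over a 50-point log-spaced path from `λ_max = max_j |b_j|` (the
exactly-all-zero solution) down to `10⁻³·λ_max`; α takes the 10 values
{0.0, 0.1, …, 0.9} with λ₂ = α(1 − λ₁), giving the 10×50 grid. For each
cell, validation samples are scored and smoking history (ordinal 0–3,
deliberately untransformed) is regressed on score + covariates (cell
proportions with one granulocyte column dropped, maternal age, social
disadvantage index, education years, GDM, parity); the cell with the
smallest two-sided score-term p wins. Ties break toward the sparser
model, then the larger λ₁ (parsimony).

### Scoring and transfer

A fitted model is a CpG list with weights plus the fit-time
standardization constants. Scoring restricts to the model CpGs present in
the target matrix (partial overlap is expected across array platforms),
standardizes them with *target-cohort* means/SDs by default — the cohorts
may use different arrays, so frozen constants are not comparable across
platforms — and reports the number of CpGs used. A
`frozen_standardization` mode applies the stored constants instead.

## QC cascade

Fixed order: sample exclusions (sex mismatch by 2-means split of mean
X-chromosome β, duplicates at Pearson r > 0.99) → masked-probe removal →
missingness filters (samples with >10% missing probes first, then probes
with >10% missing samples; strict inequalities) → per-probe mean
imputation → non-informative removal (all β < 0.1 or all β > 0.9,
strict). The order is forced by validity: imputation needs the
missingness filter, and the informativeness rule needs complete data.
Re-running the cascade on its own output is the identity. The duplicate
threshold and the 2-means sex split (abstaining when cluster centers are
closer than 0.1 in β) are package choices where published pipelines leave
the mechanism unstated; both are parameters.

Cell proportions are estimated per sample by least squares of the β
profile on reference mean-methylation profiles under nonnegativity and
sum-to-one (SLSQP on the quadratic program; the reference is an input
file — `synthetic_cell_reference` provides a synthetic panel with the
marker-probe structure of flow-sorted references for testing).

## EWAS and meta-analysis

Per CpG the smoking phenotype is the *outcome* and methylation the
predictor ("reverse regression") — logistic for current (history 3 vs
rest) and ever (≥1 vs 0) smoking, linear for weekly exposure hours, which
are zero-inflated and highly skewed and therefore rank-inverse-normal
transformed (Blom offset 3/8; a raw-scale sensitivity fit is available).
Covariates: cell proportions (one dropped for the sum-to-one
collinearity), maternal age, SDI, education, GDM, parity; complete-case
per model; two-sided Wald p-values. Probes with perfect separation,
non-convergence, or zero variance are flagged with missing statistics and
excluded from the FDR family rather than crashing the run. Newborn sex
and gestational age are deliberately not covariates, matching the
published covariate list.

Meta-analysis is inverse-variance fixed-effect only (w = 1/se², pooled SE
(Σw)^{-1/2}) with Cochran's Q on k−1 df; heterogeneity is reported, never
used to filter. FDR (Benjamini–Hochberg, via statsmodels) is computed
within each run over exactly the probes (or outcomes) analysed.

## Synthetic cohorts

The generator produces the study design the pipeline targets: paired
European-like cohorts (~5.5% current smokers; smoking-history prevalence
(0.67, 0.175, 0.10, 0.055) matching the published subsample) and a
South-Asian-like cohort ((0.994, 0.003, 0.003, 0.0); lighter newborns,
shorter gestation, higher GDM).

* β-values are logit-normal: per-probe baseline U(−1.8, 1.8) on the logit
  scale, plus cell-composition confounding (Dirichlet proportions with
  α=(1,11,2,2,1,60,8), random per-CpG loadings of SD 2.0), plus the
  smoking effect at causal CpGs, plus block-AR(1) noise (block size 10,
  ρ=0.4, SD 0.5) standing in for local co-methylation — the generative
  scale and correlation structure of real arrays are not published, so
  these are explicit, configurable choices.
* The latent smoke burden `u = history + η`, η ~ N(0, 0.5), models
  passive/unreported exposure. Causal CpGs shift by δ·u (δ=0.25 per
  burden unit, signed per probe); birth weight declines by 0.15 kg and
  birth length by 0.45 cm per burden unit; exposure hours are
  zero-inflated log-normal in u (80% structural zeros at u=0). Because η
  varies in the zero-prevalence cohort, the MRS–birth-size association is
  reproducible there without any active smoking — the portability
  phenomenon the design is meant to exhibit.
* Structural parameters (baselines, loadings, causal set, manifest) come
  from `structure_seed`, sample-level draws from `seed`, so cohorts can
  share one generative model.

What the generator does **not** emulate: batch/chip effects, probe-type
(I/II) differences, genetic ancestry structure, non-linear cell effects
on the β scale, realistic genome-wide probe counts. Passing tests
therefore demonstrate correctness of the machinery and recoverability
under the stated model, not field performance on real arrays.

## Evaluation

AUC is the Mann–Whitney statistic (ties 0.5) with a percentile bootstrap
CI over 2000 sample resamples (class-empty resamples redrawn; BCa not
implemented). Dose–response: one-way ANOVA F across history categories
plus Welch t-tests of each category vs never-smokers (the equal-variance
variant is not assumed). Outcome association: per cohort, linear or
logistic regression of the outcome on the MRS, adjusting for child age at
the relevant visit; cohort effects are pooled by fixed-effect IVW and FDR
is applied across the meta-analysed outcome family only. Cohort
descriptive comparisons use ANOVA/Welch-t for continuous and chi-square
for categorical fields, excluding cohorts that contribute expected cell
counts < 5 (iteratively, reported per test).

## Numerical and experiment-scale choices

* Standardization uses the n−1 denominator throughout; R is symmetrized
  and its diagonal pinned to 1.
* Null-calibration experiments use block_rho=0 (the binomial bound on the
  rejection rate presumes independent probes) and n=1000 samples so the
  logistic Wald test has ~50 events; λ is judged on ≥12,000 probes in the
  test suite because the median-based λ has sampling SD ≈ 0.07 at 2,000
  probes.
* The end-to-end recovery experiments run at validation n=400 / test
  n=400 / zero-prevalence n=500 with p=1000 CpGs, 20 causal, and an
  effective discovery size of 5000 — a desk-scale analogue of the
  motivating study design.
* Logistic Wald power degrades under near-separation (Hauck–Donner), so
  power-oriented experiments use moderate per-unit shifts (δ≈0.5) and
  ≥15% smoker prevalence rather than extreme effects.

## Known limitations

Fixed-effect meta-analysis only; no cross-validated tuning or stability
selection; deconvolution assumes the reference spans the true cell types;
the published external score weight lists (Reese/Richmond/Rauschert/
Joubert/air-pollution) are not redistributed, though `score_samples`
applies any externally supplied weight list; raw IDAT preprocessing,
genotype-based ancestry checks, and dietary pattern scores are out of
scope.
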