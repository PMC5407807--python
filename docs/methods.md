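# Methods

## The analysis

`bidirmr` implements a bidirectional Mendelian-randomization (MR) analysis of
body mass index (BMI) and serum total testosterone (T) in men. Genetic risk
scores (GRS) built from published GWAS effect sizes serve as instrumental
variables: 97 autosomal BMI-associated SNPs on one side, and 3
testosterone-associated SNPs (two autosomal, one X-linked and hemizygous in
males) on the other. Under the IV assumptions — the score is associated with
its trait, independent of confounders, and affects the other trait only
through its own — the Wald ratio

    beta_IV = beta(score -> outcome) / beta(score -> exposure)

estimates the causal effect; two-stage least squares (2SLS) gives the same
point estimate for a single instrument and carries the one-sample variance.
All regressions operate on covariate-adjusted Z-scores: ln-transformed BMI
residualized on age, smoking and cohort/site; T (and SHBG) additionally on
time of blood sampling; residuals scaled to unit SD (population SD, so the
Z-score invariants hold exactly).

Per-cohort estimates are combined two ways, mirroring the study design:
inverse-variance meta-analysis (fixed effect, or DerSimonian–Laird random
effects when Cochran's Q rejects homogeneity at alpha = 0.05) and a pooled
individual-level analysis with cohort indicators in the adjustment set.

Companion analyses:

* **Instrument validation** — incremental R² of the score on the adjusted
  trait; single-instrument F = (n−2)·R²/(1−R²); confounder-balance
  regressions (score on age, smoking); score×covariate interaction terms; a
  quadratic-score linearity check; per-SNP scans with nominal (p < α) and
  Bonferroni (p < α/m over the m polymorphic variants tested) flags.
* **SHBG conditioning** — 2SLS re-run with the SHBG Z-score (respectively the
  T Z-score) in both stages, separating an SHBG-mediated from a direct path.
* **Independent-instrument split** — the panel is partitioned (e.g. one
  top SNP vs the remaining 96), each side estimated separately, and the two
  estimates compared by a z-test on independent SEs; agreement argues
  against instrument-specific pleiotropy.
* **Observational-vs-IV comparison** — a Hausman-type z statistic
  (beta_obs − beta_IV)/√(se_IV² − se_obs²), with the variance difference
  floored at se_IV²·1e−6; the test is a reconstruction, the study does not
  name its procedure.
* **Clinical translation** — percent change in T for a BMI change from 30 to
  25 kg/m²: 100 · ratio · (SD(T)/SD(ln BMI)) · (ln 25 − ln 30) / T̂(BMI=30),
  with T̂ from the pooled OLS of native-scale T on ln BMI plus covariates at
  their sample means (the prediction model is unstated in the source design;
  this is the package's choice).
* **Analytic power** — Φ(√(n·R²)·|β| − z₁₋α/₂), the shifted-normal IV power
  for a continuous outcome. At n = 7446, |β| = 0.30 it yields 95% (R² = 1.9%)
  and 98% (R² = 2.5%). The α convention is two-sided; at β = 0 the expression
  returns α/2 (upper-tail rejection only). A half-effect scenario evaluates
  the same formula at β/2. A Monte-Carlo validator (replicate 2SLS on the
  generator) checks the formula empirically.

## Synthetic multi-cohort generator

No individual-level data accompany the design, so a generator emulates the
five male cohorts (929/1682/1912/427/2496 men, total 7446) with their
published phenotype moments. Genotypes are binomial at each variant's
effect-allele frequency (two draws autosomal, one for the male X variant) and
are drawn independently of every confounder — the defining property the MR
analysis assumes and tests. Phenotypes follow a linear-Gaussian structural
model on the standardized scale:

    x* (std ln BMI) = G_BMI + a1·z_age + a2·z_smoke + c1·U + e_x
    s* (std SHBG)   = d·x* + λ·u + e_s
    y* (std T)      = b_direct·x* + γ·s* − G_T + b1·z_age + b2·z_smoke + c2·U + e_y

with G the centered weighted dosage sums, u an SHBG–T latent factor, U a
latent confounder outside the adjustment set, and noise variances solved so
every standardized trait has unit variance (the variance bookkeeping is a
tested invariant). Only second moments matter downstream (everything is
Z-scored), which justifies the linear-Gaussian form. Standardized traits map
to native scales: BMI log-normal matched to each cohort's mean/SD, T and
SHBG linear (floored at a small positive value, touching <0.5% of draws).

Key parameters (`StructuralParams`), all on the standardized scale:

| parameter | default | meaning |
|---|---|---|
| `beta_causal` | −0.25 | total causal effect, SD(T) per SD(ln BMI); `b_direct + γ·d` |
| `r2_grs_bmi`, `r2_grs_t` | 0.019, 0.025 | variance fraction each score explains of its trait |
| `conf_age_*`, `conf_smoke_*` | 0.25/−0.20, 0.10/−0.05 | measured confounder loadings |
| `conf_latent_*` | 0.25/−0.20 | latent confounder loadings; their product (−0.05) is the residual bias of the adjusted observational slope, so the default study shows observational ≈ −0.30 vs causal −0.25 |
| `shbg_t_corr` | 0.51 | target T–SHBG correlation (SHBG explaining ~26% of T variance); γ is solved from it holding the total effect fixed |
| `shbg_bmi_coeff` | −0.10 | ln BMI → SHBG path; `with_shbg_mediation(f)` solves it so a fraction f of the causal effect is SHBG-mediated |
| `heterogeneity_sd` | 0.05 | between-cohort SD of the direct causal path, spreading observational slopes as in a heterogeneous multi-cohort study |
| `missing_rate` | 0 | MCAR per-entry dosage missingness |
| `drop_variants` | {} | cohort-level absent variants (the 96-of-97-SNP cohort) |

Variant panels: effect-allele frequencies uniform on (0.08, 0.86) — centred
slightly below 0.5 so the 97-SNP allele-count score mean sits near the
published ~91 — and log-normal raw weights rescaled so
Σ ploidy·p·(1−p)·w² equals the R² target exactly. Adversarial knobs
(`pleiotropy_rsids`/`pleiotropy_effect`, `grs_age_interaction`) inject
violations for power-of-detection tests; their variance contribution is not
rebalanced, so they perturb total variance slightly — acceptable for the
scenarios they serve.

What the generator does **not** emulate: linkage disequilibrium between
variants (the design uses independent SNPs), Hardy–Weinberg departures,
population stratification, assay-specific measurement error, medication-based
exclusions, or non-linear or threshold effects. Passing tests therefore show
the statistical machinery is correct under the stated structural model, not
that real cohort data would give the published coefficients.

## Score conventions

* Harmonization re-orients every dosage column to the weight table's effect
  allele (complement 2−g, or 1−g for the male X variant); it is idempotent
  and a counted allele matching neither spec allele is an error naming the
  variant.
* The weighted score is rescaled by M/Σw (M = contributing variants) onto the
  allele-count scale; that convention reproduces the published weighted-score
  cohort means (~89 for 97 SNPs) but is a reconstruction — the exact published
  transform is unstated. IV estimates are invariant to any positive linear
  rescaling of the instrument (a tested property), so the choice is cosmetic;
  `rescale=False` exposes raw Σw·g.
* Sporadic missing dosages default to expected-dosage imputation
  (ploidy·EAF; unbiased under MCAR); `omit` treats them as 0 and records the
  per-individual shortfall. Cohort-level absent variants default to omission
  without rescaling, matching the published cohort-mean offset; proportional
  rescaling (×M_total/M_present) is opt-in.
* The X-linked variant contributes dosage in [0,1] by default; an optional
  ×2 scale supports sensitivity analysis since the published coding is
  unstated.

## Numerical choices

* Wald-ratio CIs use the first-order delta method with normal quantiles; at
  first-stage F in the hundreds this agrees with Fieller intervals. The
  delta method treats numerator and denominator as independent; the
  one-sample 2SLS variance is the primary estimator and cross-checks it.
* 2SLS covariance is classical (homoskedastic) by default with an HC0 robust
  option; residuals are taken at the actual (not fitted) exposure. First-stage
  partial F below 10 warns; below 1 the fit is refused.
* DerSimonian–Laird tau² is the closed-form method-of-moments estimator;
  Q and I² are computed with fixed-effect weights; Q ≤ k−1 collapses random
  effects to fixed exactly. No small-sample (Hartung–Knapp) correction at
  k = 5.
* The meta model choice (fixed vs random) uses the Q test at alpha 0.05 — a
  reconstruction; the source design implies but does not state its threshold.
* Standardization divides by the population (ddof 0) residual SD so the
  Z-score mean-0/SD-1 invariants hold to machine precision; degenerate fits
  (zero residual variance, rank-deficient adjustment sets) raise errors that
  name the offending columns.
* Two-sided tests and 95% CIs throughout. P-values are floored at the
  smallest positive double rather than reported as 0.
* The Shapiro–Wilk normality statistic is reported as a diagnostic only
  (subsampled to 5000 values, the test's reliable range) and gates nothing.

## Problem sizes in the test suite

Monte-Carlo checks use the study's n = 7446 with 500 replicates for
parameter recovery (truth grid −0.4, −0.25, 0, 0.25), deconfounding and
empirical power, and 100–300 replicates for null-calibration checks at
smaller n; large-sample structural checks use single cohorts of 50k–200k.
These sizes give Monte-Carlo SEs comfortably inside the asserted bands.

## Known limitations

* The BMI-direction published ratios (−0.25, −0.29) are not exactly
  recoverable from the rounded published coefficients (which give −0.27,
  −0.30); the implementation computes the ratio of whatever coefficients it
  is given and nothing is hard-coded to either value.
* The exact percent-change figure (13%) depends on unpublished exact cohort
  moments; pooled reconstructions land at ~11–15%.
* Multi-instrument summary-statistic estimators (IVW across SNPs, MR-Egger,
  weighted median) are out of scope: the unit of analysis here is the
  aggregate score, with the split-instrument comparison as the pleiotropy
  device.
* The generator's T GRS affects T only; its known association with SHBG
  (two of the three SNPs sit in the SHBG locus) is not modelled.
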