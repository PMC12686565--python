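# Methods

`mitoage` implements an analysis chain linking two mitochondrial DNA (mtDNA)
aging metrics — heteroplasmy burden and copy number — to epigenetic age
acceleration (EAA), with downstream mediation and Mendelian randomization.
Because the cohort data such analyses run on are restricted-access, the
package ships a synthetic multi-cohort generator with a ground-truth ledger;
every inference stage is validated against that truth.

## Heteroplasmy burden scores

A call at mtDNA position *j* with alternate allele *a* in sample *i* is
heteroplasmic when its variant allele fraction (VAF) lies in the inclusive
window [0.05, 0.95]. Both endpoints count as heteroplasmic: "within 5%–95%"
is ambiguous, and the inclusive reading makes the printed endpoints
in-window. A variant (position, alt) is *rare* when its carrier frequency —
distinct samples with an in-window call, divided by all study participants —
is strictly below 1%. Carrier counting uses heteroplasmic calls only;
homoplasmic-like alternate alleles (VAF > 95%) do not count as carriers.

Scores per sample:

- `MHcount_i = Σ_j H_ij` — count of rare heteroplasmic calls at retained
  sites passing the coverage filter;
- `MSS_i = Σ_j m_ja H_ij` — the same calls weighted by the mitochondrial
  local constraint (MLC) score `m_ja ∈ [0, 1]` of the alternate allele
  (higher = more deleterious). Calls without an MLC entry (e.g. D-loop
  INDELs) contribute 0 and are counted in a warning; therefore
  `0 ≤ MSS ≤ MHcount` always;
- `MH_com_count_i = Σ_j C_ij` — count of carried variants from a fixed
  common-heteroplasmy panel, keyed by (position, ref, alt). The published
  39-variant panel is not redistributed; any panel TSV can be supplied, and
  the generator emits a synthetic analog (16 positions / 39 alleles).

Site filtering: the default blacklist is the ranges 1–61, 301, 302, 310,
316, 499, 567, 3107 and 16088–16569 — homopolymer tracts and NUMT-prone
regions of the 16,569 bp rCRS coordinate system. Enumerating these ranges
excludes 550 positions, retaining **16,019**. The source analyses report
16,015 positions used; enumerating their printed list yields 16,019, and the
four additional excluded positions are unidentified. The mask implements the
printed list and is fully configurable; this discrepancy is deliberate and
documented rather than papered over. The per-site coverage filter (default
minimum 250 reads) applies per sample-site when a coverage table is
provided; sample-sites absent from the table are treated as passing, which
is the summary-only workflow. Variant identity is (position, alt); a
multi-allelic VCF record is decomposed into one call per alternate allele.

Filter precedence in the audit trail is masked_site → low_coverage →
vaf_out_of_window; a call failing several filters is recorded once under the
first.

## Copy number, QC, and standardization

mtDNA copy number per cell is `CN = 2 × (mean mitochondrial coverage / mean
nuclear coverage)`; the factor 2 reflects haploid mtDNA against the diploid
nuclear genome. CN is invariant to proportional coverage changes.

Samples with `MHcount > 5` or `CN < 40` are excluded (contamination /
sequencing-error guard). Both inequalities are strict, so MHcount = 5 and
CN = 40.0 are retained. QC runs before residualization, so exclusions do not
perturb the standardization of retained samples.

Each metric (MHcount, MSS, MH_com_count, CN) is regressed within cohort on
white-blood-cell composition, batch indicators and smoking status by OLS;
the residual is divided by its within-cohort sample SD (denominator n−1; the
source does not specify, and n−1 is the convention of the surrounding
stack). "Blood cell counts" are operationalized as estimated WBC proportions;
since the five proportions sum to one, only four enter any design matrix.
Constant columns are dropped from design matrices (absorbed by the
intercept), so e.g. the lab index is active only in the cohort that has two
labs. Rank-deficient designs raise an error naming the collinear columns.

## Clocks and age acceleration

A clock is a linear map from methylation beta values to either years of age
or a pace of aging (pace ≈ 1 = average rate). Two forms are supported:
direct (`intercept + Σ w_k β_k`) and PC (`intercept + Σ_c u_c Σ_k L_kc (β_k
− μ_k)`), the latter matching principal-component clocks trained to suppress
probe noise. Published clock coefficient sets are not bundled (they live in
external calculators with their own licensing); the engine loads any
definition from a documented JSON schema, and the test suite uses
generator-emitted clocks. Pace-scale clocks are handled as plain linear
clocks on the pace scale; proprietary preprocessing of specific commercial
clocks is out of scope. Missing CpGs are mean-imputed with a warning up to a
configurable 5% of the support; beyond that, an error.

EAA is the residual of the clock value regressed on chronological age within
explicit strata, supplied as a label column (typically cohort, optionally
crossed with ancestry group or lab). Within each stratum EAA has mean zero
and is uncorrelated with age by construction. Pace-scale clocks are
residualized identically, in pace units.

## Association and meta-analysis

The primary model is OLS of one EAA on one standardized mtDNA metric,
adjusting for age, age² (uncentered; configurable), sex, smoking, WBC
proportions, batch, and lab index where present. Two-sided p-values use the
t distribution with residual df. Strata: all, age < 60, age ≥ 60 (age
exactly 60 goes to the older stratum), female, male. Sex strata drop the sex
covariate; age strata keep age and age². Cohort estimates are pooled by
fixed-effect inverse-variance weighting: `w_i = 1/SE_i²`, `β_pool =
Σw_iβ_i/Σw_i`, `SE_pool = 1/√Σw_i`, p from the standard normal (the
large-sample convention of standard meta-analysis packages). Cochran's Q and
I² are reported as diagnostics but never drive model choice. The default
significance flag is p < 0.01 = 0.05/5, the Bonferroni share for five EAA
outcomes; the family size is configurable. Discovery/replication is a
reporting layout only — the pooled meta uses all cohorts.

The per-CpG secondary analysis regresses each CpG beta on the metric plus
covariates. All CpGs share one design matrix, so the fits are solved as one
multi-outcome least-squares problem (identical to per-CpG OLS, verified in
tests against statsmodels). Benjamini–Hochberg controls FDR at 0.05.

## Mediation

Product-of-coefficients decomposition with models
`mediator ~ a·predictor + covariates` and
`outcome ~ b·mediator + c′·predictor + covariates`;
NIE = a·b, TE = a·b + c′, PM = NIE/TE × 100. Model 2 is OLS for continuous
outcomes and logistic for binary ones, placing the decomposition on the
log-odds scale under the rare-outcome convention; exact counterfactual
integration and exposure–mediator interactions are out of scope. SE(NIE) is
the Sobel delta method √(a²SE_b² + b²SE_a²); a seeded nonparametric
bootstrap CI is optional. PM is reported as NA when |TE| < 1e-8 or when NIE
and TE disagree in sign (PM would leave [0, 100]%); a numerically negligible
NIE yields PM = 0. Both causal orientations are always fit, because
cross-sectional data cannot privilege one; in the pipeline, mediation is
restricted by default to participants aged ≥ 60 (configurable). Separation
in the logistic fit raises a diagnostic error rather than returning
implausible coefficients.

## Mendelian randomization

Inputs are pre-clumped two-sample GWAS summary statistics; LD clumping is
not implemented (duplicate SNP ids trigger a warning). Harmonization aligns
outcome effects to the exposure effect allele, sign-flipping swapped pairs,
resolving strand flips via complements, and dropping palindromic SNPs with
exposure EAF in (0.42, 0.58) plus allele-incompatible rows, with an audit.

Estimators on Wald ratios `β_out/β_exp` with weights `β_exp²/SE_out²`:

- **IVW**: weighted mean of ratios (= weighted regression through the
  origin). The default SE uses multiplicative random-error scaling —
  inflated by residual dispersion when it exceeds 1, never deflated — with a
  fixed-error variant available; which error model a given published
  analysis used is often unstated, so both are provided.
- **MR-Egger** (≥ 3 SNPs): weighted regression with intercept after
  orienting exposure betas positive; the intercept estimates average
  directional pleiotropy. With exactly 3 SNPs there is 1 residual df and a
  warning flags the unstable SEs.
- **Weighted median** (≥ 3 SNPs): linear interpolation of the ordered
  ratios at cumulative normalized weight 0.5; SE by seeded parametric
  bootstrap (default 1000 reps) on ratio-scale first-order SEs.

Leave-one-out recomputes IVW dropping each SNP, flagging any whose removal
shifts θ by more than one full-sample SE (configurable multiple).

## The synthetic generator

Defaults encode the emulated study design; they were fixed once from the
study description, not adjusted afterwards:

- **Cohorts**: four, sizes (1745, 2289, 1424, 858), ages Normal with
  (mean, SD) = (60.8, 13.6), (45.6, 6.3), (55.3, 12.4), (60.2, 9.7)
  clipped to [18, 100]; 58% female; smoking 15% current / 30% former; WBC
  proportions Dirichlet(55, 30, 8, 5, 2); 3 batches per cohort; two labs in
  cohort 1 to exercise the lab-index covariate.
- **Rare heteroplasmy**: counts Poisson with log-rate η0 + η1·max(0,
  age−55), η0 = −1.05, η1 = 0.035/yr — a hinge at 55 capturing the
  qualitative post-55 rise; the hinge form and rates are modeling choices
  (only the qualitative pattern is reported upstream). Positions uniform
  over retained non-panel sites; VAF ~ Beta(0.6, 2.5) truncated to the
  window — skewed to low fractions, as somatic heteroplasmy is; the true
  VAF distribution of the cohorts is unknown, so this is a configurable
  modeling choice, not an inference. MLC per variant ~ Beta(2, 5) with 20%
  missing (exercising the missing-MLC path).
- **Decoys**: Poisson(0.05)/sample calls at blacklisted sites, Poisson(0.05)
  at out-of-window VAFs, and 2% of true calls flagged low-coverage in the
  per-site table — so every filter has work to do. The truth ledger counts
  only calls that survive all filters, and the scoring pipeline reproduces
  the ledger exactly on generator output (tested).
- **Copy number**: mean trajectory rising 0.3/yr to a peak of 110 at age
  47.5 then declining 0.6/yr, Gaussian noise SD 15, floored at 5; expressed
  as mitochondrial coverage against Normal(39, 3) nuclear coverage, so CN
  recomputed from coverage equals the latent CN.
- **Methylation**: latent biological age BA = age + γ_MSS·MSS_std +
  γ_CN·CN_std + N(0, 3²) with γ_MSS = 0.2, γ_CN = −0.15 years/SD; pace = 1
  + θ_CN·CN_std + N(0, 0.05²) with θ_CN = −0.005/SD. CpG betas are linear
  in BA (slopes ±0.001–0.003) or pace (slopes ±0.1–0.3) around intercepts
  bounded away from 0 and 1, plus N(0, 0.01²) noise, clipped to [0, 1];
  the bounds make clipping rare so clock errors stay effectively Gaussian.
  Emitted clocks invert this construction analytically (the year clock in
  both direct and PC form — algebraically identical), recovering BA and
  pace up to noise.
- **Traits**: obesity and T2DM are drawn from logistic models in pace
  (coefficient 4.0 per pace unit) and CN_std directly (−0.16 and −0.165),
  giving true mediated percentages of 11.1% and 10.8%; continuous BMI and
  glucose are then drawn consistently with case status so that the clinical
  threshold rules (BMI ≥ 30; glucose ≥ 126 mg/dL or treatment) reproduce
  the flags exactly. Blood pressure, lipids and CVD are generated with mild
  age trends and thresholded per the stated clinical rules, for use as
  sensitivity covariates.
- **MR**: 41 SNPs by default, exposure betas Uniform(0.02, 0.10) (oriented
  positive — the convention under which a constant pleiotropy δ equals the
  Egger intercept), outcome β = θ·β_exp + δ + noise with θ = 0.3, SE_out =
  0.01; invalid-instrument fraction and extra pleiotropy configurable;
  palindromic allele pairs are avoided by default so no instruments are
  lost in harmonization.

What the generator does *not* emulate: raw reads, NUMT artifacts beyond the
blacklist decoys, array-level intensities, nonlinear CpG–age dynamics,
population structure, relatedness, or real LD between instruments. Passing
tests therefore demonstrate that the *statistical machinery* is correct and
calibrated under the assumed data-generating process, not that the
biological effect sizes hold in any real cohort.

## Numerical choices and degenerate inputs

Determinism: every generator stage draws from `numpy` Generators seeded as
(seed, stage-index), so identical (config, seed) gives identical output, and
pipeline TSVs use a fixed float format so re-runs are byte-identical.
Residualization and EAA use least squares via pseudo-inverse/`polyfit`;
zero-variance residuals, undersized strata (< 3 samples), undersized cohorts
and rank-deficient designs all raise informative errors. IVW with k = 0
studies, MR with no overlapping SNPs, all-zero exposure betas, < 3 SNPs for
Egger/median, and < 2 for leave-one-out are errors; a zero exposure beta on
one SNP excludes that SNP with a warning.

## Problem sizes used in validation

The validation experiments use scaled problem sizes chosen to exercise the
asymptotics the methods rely on: CI-coverage runs use 4 cohorts × 1500
samples × 200 replicates; null calibration 1000 tests (250 four-cohort
studies of 150 samples each, with 40+10 CpGs — under a null generator the
clock's CpG count only affects clock noise, not calibration); null EWAS 100
replicates × 200 CpGs × 150 samples; mediation 100 replicates × 2000
samples; MR 200 simulated datasets per scenario. `scripts/acceptance.py`
reruns these same experiments and additionally analyzes one study at the
full default cohort sizes (n = 6316).

## Known limitations

- The mediation decomposition for binary outcomes is the regression-based
  rare-outcome approximation; it is not a counterfactual estimator and PM
  inherits ratio-estimator noise (visible as mild upward spread at n = 2000).
- The weighted-median SE is a parametric bootstrap, not the analytic
  order-statistic variance.
- Mixed-effects models for family structure, random-effects meta-analysis,
  multivariable MR, Steiger filtering and clock training are out of scope.
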