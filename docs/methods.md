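# Methods

This package re-creates, on synthetic data, a prognosis and trial-design
analysis for cognitively unimpaired (CU) elderly cohorts: how well baseline
plasma ATN biomarkers (the Aβ42/Aβ40 ratio, P-tau217, NfL) predict
longitudinal cognitive decline and incident AD dementia, and how much a
biomarker screening step shrinks the sample size a prevention trial needs.
The real cohort it emulates is available only by request, so a calibrated
generator stands in for the data; everything downstream of the generator is
the same analysis a real cohort would receive.

## Synthetic cohort model

**Subjects.** n = 435 by default (268 CN, 167 SCD). Age ~ N(72.6, 5.45²)
(SCD 2.7 years younger), education ~ N(12.2, 3.7²), 55.6% male. *APOE* ε4
status is drawn from a logistic model in amyloid and tau abnormality with
group-specific intercepts solved to hit 27% (CN) / 45% (SCD) carriage, so
carriers are enriched for pathology without distorting the marginal
biomarker distributions.

**Biomarkers.** A six-dimensional latent Gaussian holds the three plasma
markers and their CSF analogues on a standardized *abnormality* scale
(higher = more pathological; the amyloid ratio is sign-flipped). The plasma
block has correlations (A,T) = 0.22, (T,N) = 0.20, (A,N) = 0.10; the CSF
block repeats that structure, with per-marker plasma–CSF correlations
(0.55, 0.70, 0.75) via a `sqrt(c_j c_k) R_jk` cross block (positive
semi-definiteness is validated at configuration time). Raw assay scales are
affine/exponential decorations chosen so the *analysis-scale* descriptives
(natural log for everything except plasma Aβ42/Aβ40) match the published
baseline means/SDs. Raw cutoff values in pg/mL are treated as
documentation; positivity is defined by the published rates
(46.2% / 37.2% / 37.9%).

**Trajectories.** Latent PACC is linear in time:
`y_i(t) = b0_i + b1_i t + ε`, with bivariate-normal random effects
(intercept SD 0.57, slope SD 0.40, correlation 0.30) and visit-level
residual SD 0.40. Fixed effects enter both the intercept and the slope.
Effect sizes are stored as **marginal** per-SD targets — the quantity a
single-biomarker model recovers — and mapped to direct coefficients through
the latent correlation matrix (`direct = R⁻¹ · marginal`). The calibrated
slope targets are −0.18 / −0.20 / −0.16 PACC points/year per SD (A/T/N);
baseline targets −0.12 / −0.12 / −0.08 points per SD. SCD carries a −0.40
baseline offset and, by design, **no** slope offset (the emulated cohort
showed baseline differences and conversion-rate differences but no
longitudinal-change difference between CN and SCD).

**Cognitive components.** Each visit produces MMSE, ADAS delayed recall,
animal fluency and TMT-B. The four component z-scores share the latent
visit value plus component noise built orthogonal to the PACC weighting
(weights 1/2/1/1), so the reconstructed composite tracks the latent
trajectory rather than a noisier version of it; component scales and
bounds (MMSE capped at 30, integer rounding, ADAS floor) are realistic
decorations. Two analytic/empirical corrections keep the observable scale
honest: a fixed-point scalar maps analysis-scale parameters to the latent
scale so that z-scoring components against the cohort baseline returns the
composite to the analysis scale; and `slope_calibration = 1.16` inflates
the latent slope to absorb the mild flattening the bounded component
scales (mostly the MMSE ceiling) impose on fitted slopes. Both are frozen
in the preset; `analysis/00_calibrate.py` re-derives them.

**Events.** AD dementia follows a constant-baseline-hazard proportional
hazards model: hazard = `h0 · exp(η·z + θ_SCD · SCD)` with `η = R⁻¹ · log
HR_targets` times a per-marker correction (1.29, 1.17, 0.70) that absorbs
the non-collapsibility of the marginal hazard ratio under the strong SCD
frailty (the marginal single-biomarker HR of a conditional Cox model is
attenuated when a large independent risk factor is omitted; the correction
is the fixed point making the *fitted* marginal HRs equal the targets 2.00
/ 3.54 / 1.51). `h0 = 7.4e-4`/year and `θ_SCD = 3.16` reproduce the 1.1%
(CN) / 15.0% (SCD) AD-conversion split, i.e. 6.4% overall. An independent
competing non-AD dementia process (baseline 2.4e-3/year, NfL log-HR 0.35,
SCD offset 1.69) brings all-cause dementia to 9.0%. The first event within
follow-up wins; follow-up ~ N(4.75, 1.66²) years (SCD 0.64 years shorter),
clipped to [0.5, 11]. Visits are biennial (0/2/4/6 years), truncated at
the end of follow-up and at conversion.

**Seeding.** Everything flows from one integer seed through
`numpy.random.SeedSequence` spawning; identical configs give byte-identical
tables. Pipeline child seeds use a counter-based scheme
(`SeedSequence([global_seed, index])`) so module-level reruns match
pipeline runs.

### A deliberate calibration trade-off

The published effect sizes (≈ −0.2 PACC points/year per SD), the published
4-year PACC change (−0.33 ± 0.85) and the published screening yield
(≈ 70% sample-size reduction) are mutually inconsistent under any model in
which subject slopes are a function of baseline biomarkers: a marginal
covariance of 0.2/year/SD forces a screened-subpopulation slope shift of
about 0.2/year, which next to a mean slope of −0.08/year would make
screening reduce the required sample by >90%, and the biomarker-explained
slope variance alone would exceed the printed variance of the 4-year
change. The preset resolves this in favor of the quantities the analyses
actually test — marginal effect sizes, conversion rates and the headline
sample-size reductions — by giving the cohort a steeper mean decline
(−0.575 points/year) than the printed 4-year change implies. Consequently
the synthetic cohort declines faster, and fixed effects explain a larger
share of outcome variance (marginal R² ≈ 0.33–0.46 vs the published
0.07–0.14), than the real one. Descriptive baseline quantities (PACC
0 ± 0.74, MMSE 28.8 ± 1.2, biomarker scales) are unaffected.

## Analysis pipeline

**Preprocessing.** Natural-log transform per the registry, a single-pass
4-SD outlier screen (mean/SD computed before exclusion), z-scoring of
survivors, abnormality orientation. Nonpositive values under a log
transform become row-level errors, not failures. The PACC is the weighted
mean (recall double) of component z-scores against the full-CU baseline
distribution, recall and TMT-B sign-flipped; visits missing more than half
the component weight get a missing composite. Youden cutoffs
(J = sens + spec − 1, candidates at midpoints of sorted unique values,
ties toward specificity) are derived from CU converters vs CSF-Aβ-negative
CU nonconverters; the screening analyses use positivity-rate-matched
cutoffs. Values exactly at a threshold are negative.

**Longitudinal models.** `statsmodels` MixedLM fit by **ML** (not REML) so
AIC and likelihood-ratio comparisons are coherent across nested
fixed-effect sets. Random intercepts and slopes with unstructured 2×2
covariance; a singular fit falls back to a diagonal covariance and is
flagged. Fixed effects: time, the basic set (age, sex, education) with
main effects and time interactions, plus biomarkers (main + time
interaction) singly or together; baseline biomarker main effects are
included because trajectories differ at baseline. AIC = 2k − 2·logLik with
k counting fixed effects, random-effect covariance parameters and the
residual variance. Model comparison reports AIC_Δ (≤ −2 read as a
meaningful improvement, boundary inclusive) and a χ² LRT. R² is the
marginal (fixed-effects) variance share, with the conditional R² alongside;
bootstrap CIs resample subjects, not observations. Residual normality is
summarized with a D'Agostino–Pearson test as a diagnostic.

**Survival models.** `lifelines` Cox PH (Efron ties, natural for a visit
grid), right-censored at last follow-up or conversion, same covariate
batteries; HRs are per SD of abnormality. AIC uses the partial likelihood
with k = number of covariates. Discrimination is the fixed-horizon (4-year)
AUC of the linear predictor with non-events censored before the horizon
excluded from the label set — the simplest defensible reading of "4-year
conversion"; a proportional-hazards test is attached as a diagnostic. CSF
prediction of AD dementia runs in synthetic data without circularity (in
the real setting CSF informed the diagnosis itself, so that comparison was
declined there).

**Trial enrichment.** Two-arm 1:1 trial, 4 years, two-sided α = 0.05, 80%
power, 30% effect. Cognitive endpoint: the mixed-model slope-difference
formula `n/arm = 2(z_{1−α/2}+z_pow)² σ_eff² / (0.3·|mean slope|)²` with
`σ_eff² = Var(subject slopes) + σ²_res / Σ(t_j − t̄)²` over the trial's
visit schedule (0/2/4 years). Event endpoint: Schoenfeld's event count
`d = 4(z_{1−α/2}+z_pow)² / ln(0.7)²` converted to N via the average of the
control-arm Kaplan–Meier 4-year conversion probability and its
proportional-hazards counterpart under HR = 0.7. Both formulas are
validated against Monte-Carlo power simulations (t-test on per-subject
slopes; log-rank) in the test suite, to within 3 rejection points.

Endpoint parameters are estimated on the screened (sub)population with a
two-stage estimator — per-subject OLS slopes, method-of-moments variance
partition, pooled residual variance — rather than a mixed-model refit.
This is deliberate: the estimator is unbiased for the three quantities the
formula needs, and it makes each of the 1000 bootstrap resamples an
indexing exercise over precomputed per-subject statistics (the OLS slope,
S_xx, RSS and df of a subject do not change when subjects are resampled).

Screening schemes: per-biomarker positivity cutoffs (univariate), SCD
status, and a combined scheme that fits the endpoint-specific model
(regression of per-subject slopes, or the Cox linear predictor, on
demographics + all three biomarkers), freezes its coefficients, and admits
the top 30% of the screening sample by predicted risk. The 30% inclusion
fraction is itself a calibrated constant: the published univariate yields
imply cutoffs at the positivity rates (37–46%), while the published
combined yields (70% cognitive / 63% conversion) are only reached by a
stricter combined rule; 0.30 reproduces both published combined headline
values at their printed magnitudes. SS_Δ = 1 − N_enriched/N_unenriched
counts randomized subjects only; the number needed to screen is reported
alongside. Bootstrap: subjects resampled with replacement, percentile
2.5/97.5 CIs, P = two-sided tail probability of SS_Δ ≤ 0 floored at 1/B.
The threshold sweep shifts the raw-scale cutoff by ±20% (mapped back to
the analysis z-scale through the stored standardization, the way assay
drift would propagate) and flags grid points whose CI excludes zero.

## What the generator does and does not emulate

It reproduces: the cohort composition and descriptives, the correlation
structure of the plasma/CSF panel, marginal biomarker effect sizes on both
endpoints, CN/SCD conversion splits, censoring at dropout/conversion, and
the qualitative ordering of screening schemes (combined > univariate;
SCD screening strong for the conversion endpoint, weak for the cognitive
one). It does not emulate: assay measurement error or plate effects,
longitudinal biomarker drift (baseline values only), non-Gaussian biomarker
tails, MCI participants (the Youden contrast uses CU converters only), or
a CSF advantage over plasma — CSF analogues are correlated decorations of
the plasma latents, so CSF fits are *weaker* here, opposite to the real
cohort where CSF was the stronger modality. Passing tests therefore show
the analysis machinery is correct and well-calibrated under the stated
generative model, not that plasma ATN screening performs this way in any
particular real population.

## Numerical choices and degenerate inputs

ML optimizer ladder lbfgs → powell → cg with a diagonal random-effects
fallback; complete separation in Cox surfaces as an error naming the
suspect covariate; fewer than 5 events refuses a fit; screens passing
fewer than 20 subjects are refused (recorded as missing inside sweeps);
zero-variance biomarker columns are reported, not fatal; values exactly at
a cutoff are negative; the identity comparison defines P = 1. Problem
sizes in the validation suite (50 replicate cohorts for effect recovery;
one cohort with B = 1000 for the headline bootstrap; 1500/800 simulated
trials per power-formula check) were chosen to put Monte-Carlo error well
inside each check's tolerance.

## Known limitations

* The calibration trade-off above: longitudinal-change descriptives
  (4-year PACC/MMSE change, R²) are intentionally steeper/larger than the
  emulated cohort's.
* Marginal Cox targets are enforced through a simulation-calibrated
  correction rather than closed form; residual error in the recovered HRs
  is ~2%.
* The bootstrap treats the screening model's coefficients as fixed (fitted
  once on the full sample), so CI width reflects cohort resampling, not
  screening-model refitting variability.
* Single-imputation-free complete-case handling: subjects with an excluded
  biomarker value drop out of models that use that biomarker.
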