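# atnpower

Prognostic modeling and clinical-trial enrichment analysis for plasma ATN
biomarkers — amyloid (Aβ42/Aβ40 ratio), tau (P-tau217) and
neurodegeneration (NfL) — in cognitively unimpaired (CU) elderly cohorts.

Prevention trials in CU populations are expensive because most
participants neither decline nor convert during the trial. If cheap blood
biomarkers can identify the people who will, screening them into the trial
raises the event/decline rate and shrinks the required sample size. This
package quantifies that gain end to end on a calibrated synthetic cohort
(the cohort it emulates is request-only): a seeded generator produces
subjects, longitudinal cognitive visits and dementia conversion events;
linear mixed-effects and Cox models estimate the biomarkers' prognostic
value; and a power analysis converts screening rules into required sample
sizes with bootstrap uncertainty.

## The models

**Cognition.** Longitudinal PACC (Preclinical Alzheimer Cognitive
Composite: z-scored MMSE, ADAS delayed recall ×2, animal fluency, TMT-B)
is modeled as

```
PACC_ij = β₀ + β_t t_ij + Σ_k (β_k x_ik + β_{kt} x_ik t_ij) + b_0i + b_1i t_ij + ε_ij
```

with random intercepts/slopes (unstructured covariance), fit by ML so AIC
and likelihood-ratio comparisons across nested models are valid. Biomarker
effects β_{kt} are reported as PACC points/year per SD of abnormality.

**Conversion.** Cause-specific Cox proportional hazards for incident AD
dementia (Efron ties, right-censored at last follow-up or conversion),
hazard ratios per SD; discrimination as the 4-year fixed-horizon AUC of
the linear predictor.

**Trial enrichment.** For a 4-year, 80%-power, two-sided α = 0.05 trial
targeting a 30% effect:

```
slope endpoint:  n/arm = 2 (z₁₋α/₂ + z_pow)² σ_eff² / (0.3 |μ_slope|)²,
                 σ_eff² = Var(b_1i) + σ²_ε / Σ_j (t_j − t̄)²
event endpoint:  d = 4 (z₁₋α/₂ + z_pow)² / ln(0.7)²,   N = 2⌈d / 2p̄⌉
```

with parameters estimated on the screened subpopulation (Kaplan–Meier for
p̄). A screening scheme — a single biomarker beyond its positivity cutoff,
SCD status, or a fitted three-biomarker risk score — yields
SS_Δ = 1 − N_enriched/N_unenriched, with subject-bootstrap CIs and
P-values. Both formulas are validated in-repo against Monte-Carlo power
simulations.

## Worked example

```
$ atn trial --seed 2 --endpoint pacc --schemes T,ATN --bootstrap 50 --out /tmp/trial
                       T: SS_delta =  43.8% [24.2, 59.1]  P < 0.02
     combined:pacc_slope: SS_delta =  69.5% [56.2, 77.6]  P < 0.02
```

Read: screening on plasma P-tau217 positivity alone lets the simulated
PACC-endpoint trial randomize ~44% fewer participants for the same power;
screening on the combined three-biomarker score cuts the requirement by
~70% on this seed. The bracketed interval is the bootstrap 95% CI; P is the bootstrap
tail probability that screening does not help.

The numbered drivers under `analysis/` reproduce the full result set on a
fresh cohort (`seed=1`) and write their tables under `results/`:

| script | writes | what it shows |
| --- | --- | --- |
| `01_simulate_cohort.py` | `results/cohort/*.csv` | 435 CU subjects (167 SCD), 6.9% AD conversion on this seed |
| `02_descriptives.py` | `table1.csv`, `youden_cutoffs.json` | baseline characteristics, CN-vs-SCD tests, Youden cutoffs |
| `03_longitudinal_models.py` | `table2_lmm.csv` | ATN model best by AIC (AIC_Δ = −81); single-biomarker β: A −0.17, T −0.15, N −0.13 points/yr/SD on this seed |
| `04_survival_models.py` | `table3_cox.csv` | P-tau217 HR 4.3 per SD, ATN AUC 0.89 on this seed |
| `05_trial_enrichment.py` | `enrichment.csv` | SS_Δ per scheme and endpoint, B = 1000 |
| `06_threshold_sweep.py` | `sweep.csv` | SS_Δ across ±20% cutoff shifts |

`atn simulate` / `atn analyze` / `atn trial` expose the same steps as a
CLI; the generator's full parameterization is a JSON-serializable config
(`--config`), with the calibrated defaults as the `paper_calibrated`
preset. `docs/methods.md` describes the generative model, the calibration
procedure and its deliberate trade-offs.

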