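# ttvmonitor

Statistical analysis of longitudinal Torque teno virus (TTV) plasma-load
monitoring in kidney-transplant recipients.

TTV is a ubiquitous, non-pathogenic anellovirus whose plasma DNA load rises
and falls with the host's immune competence, making it a candidate marker
for the *net state of immunosuppression* after solid-organ transplantation —
something neither drug doses nor trough levels measure directly.  This
package implements the analysis pipeline for a monitoring design in which
~45 paediatric kidney-graft recipients have their plasma TTV load quantified
roughly monthly for a year (reportable range 2–10 log10 copies/ml, loads
below the 2-log10 detection limit recorded as 0), alongside
immunosuppressant doses, trough levels, eGFR, co-virus loads (EBV, CMV,
BKV) and monthly clinical event flags.

It is aimed at biostatisticians and transplant researchers who want to run,
audit or extend this kind of analysis.  Because such cohorts cannot be
shared, the package includes a synthetic-cohort generator that reproduces
the study's data structure, so every stage is testable end to end without
patient data.

## What it computes

For raw loads `v` (copies/ml), the transform sets undetectable values to 1
before taking logs, so `x = log10 max(v, 1)` and undetectable samples enter
all analyses as 0.

1. **Patient-level associations** — each patient is summarised by the mean
   of their monthly log10 loads, `x̄_i`; categorical covariates are tested
   by one-way ANOVA, continuous covariates by simple linear regression.
2. **Repeated-measures correlation** — for each monthly covariate `z` (drug
   doses, trough levels, co-virus loads, eGFR), the per-patient Spearman
   coefficient `ρ_i = corr(rank x_it, rank z_it)` is averaged over patients,
   `T = (1/N) Σ ρ_i`, and tested with a 10,000-iteration permutation test
   that independently permutes each patient's covariate series in time
   (two-sided, add-one correction; the null preserves each patient's TTV
   trajectory).
3. **Event models** — monthly binary outcomes (infection, infection in the
   following month, febrile infection, suspected non-adherence) are
   modelled by random-intercept logistic regression,

   `y_it | u_i ~ Bernoulli(logit⁻¹(α + β x_it + u_i))`, `u_i ~ N(0, σ_u²)`,

   fitted from scratch by maximising the Gauss–Hermite-integrated marginal
   likelihood; odds ratios `exp(β)` are reported with Wald 95% intervals.

No multiple-testing adjustment is applied anywhere: the screens are
explicitly descriptive and hypothesis-generating.

## Worked example

```sh
python analysis/01_generate_cohort.py
python analysis/03_repeated_correlations.py
```

prints (abridged):

```
cohort: 45 patients, 501 monthly samples
detectable samples: 99.2%
median detectable load: 5.6 log10 copies/ml (IQR 4.7-6.3)

variable                mean rho      p   patients
prednisolone_dose      +0.250  0.0001*   45
tacrolimus_dose        -0.039  0.4430    40
egfr                   +0.006  0.9018    45
```

The generator injects a within-patient Spearman coupling of 0.224 between
the prednisolone dose and the load; the pipeline recovers a mean coefficient
of +0.250 (cohort sampling noise ≈ ±0.09) and the permutation p of 0.0001
is the smallest value attainable with 10,000 iterations — the steroid-dose
signal is real, while the trough levels and eGFR, generated independent of
the load, correctly test null.  `analysis/02_patient_associations.py` and
`analysis/04_event_models.py` produce the patient-level association table
and the four odds-ratio rows the same way, and
`analysis/05_operating_characteristics.py` re-estimates the permutation
test's type-I error (0.062 ± 0.01 at α = 0.05 over 500 null cohorts) and
the mixed model's slope recovery (0.497 for a true 0.5).

The same stages are scriptable via the `ttvmonitor` CLI
(`generate`, `analyze`, `simulate-power`).

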