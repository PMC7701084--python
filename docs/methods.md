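# Methods

## Data model

Two long-format tables describe a cohort.  `patients.csv` holds one row per
patient: demographics, primary kidney disease, donation type, HLA mismatch
count, DSA status and the immunosuppressive regimen (maintenance class:
tacrolimus / cyclosporin / rapamycin; anti-proliferative: MMF /
azathioprine / none).  `visits.csv` holds one row per patient-month: the raw
TTV load in copies/ml, drug doses and trough levels, eGFR, EBV/CMV/BKV
log10 loads and three binary event flags.  Missing visits are absent rows;
missing measurements are empty cells and stay missing — `0` is legal only
where zero is meaningful (an undetectable load; the dose of a drug actually
taken).  Doses and troughs of drugs a patient is not on must be missing,
never zero-filled, and validation enforces this together with key
uniqueness, the `febrile ⇒ infection` implication and the reportable range.

The TTV assay is linear from 2 to 10 log10 copies/ml with a detection limit
of 2 log10; undetectable samples are recorded as raw 0.  The transform sets
0 to 1 before taking log10, so recorded log-loads live in `{0} ∪ [2, 10]`
and values in the open interval (0, 2) are rejected as impossible.  The
derived `ttv_log10` column is never stored; it is recomputed on load so the
rule has one implementation.

## Patient-level associations

Each patient's monthly log10 loads are averaged (missing months dropped;
undetectable months *included* as 0, which follows mechanically from the
transform — an assumption worth remembering when a cohort has many
censored samples).  Categorical covariates are tested by classical one-way
fixed-effects ANOVA, written closed-form so degenerate inputs are
well-defined: zero between-group variance gives F = 0, p = 1 even when the
within-group variance is also zero.  Binary covariates go through the same
ANOVA path (equivalent to the pooled-variance t test).  Continuous
covariates use OLS simple regression with the two-sided t test on the
slope; an exact fit reports p = 0.  The HLA mismatch count is treated as
continuous by default with a switch for categorical treatment.  No
covariate adjustment or multiplicity correction is applied, by design.

## Repeated-measures correlation

Spearman's coefficient is computed as the Pearson correlation of midranks
(average ranks under ties), undefined (NaN) for fewer than three complete
pairs or a constant series; undefined patients are excluded.  The cohort
statistic is the *unweighted* mean of per-patient coefficients — patients,
not visits, are the exchangeable units.

Significance comes from a within-patient permutation test: each iteration
independently permutes every patient's covariate series in time while the
TTV series stays fixed, and recomputes the mean coefficient.  This is the
minimal exchangeability assumption targeting the within-patient
association: it preserves each patient's own load trajectory (and hence its
autocorrelation) and the patient-level structure.  The test is two-sided on
|T| with the add-one correction, `p = (#{|T*| ≥ |T|} + 1)/(B + 1)`, so p is
a valid p-value with floor `1/(B+1)`; B defaults to 10,000.  Patients with
undefined coefficients are excluded from the observed and permuted
statistics alike, so both use the same patient set.  Implementation note:
ranking a permuted series equals permuting its ranks, so each patient's
centred, normalised rank vectors are precomputed and each iteration is a
batched dot product; one variable at full B on 45 patients takes ~0.15 s.

One- versus two-sided testing is not dictated by the design; two-sided was
chosen as the conservative default.  A parametric repeated-measures
correlation (rmcorr-style ANCOVA) is deliberately out of scope.

## Random-intercept logistic event models

Four outcomes are modelled against the log10 load: same-month infection,
infection in the following month (pairing month *m*'s load with month
*m+1*'s flag, strictly adjacent calendar months, no tolerance window — a
gap month contributes no pair), febrile infection and suspected
non-adherence.  The model has a single fixed effect and a Gaussian patient
intercept; the marginal likelihood integrates the intercept out by
Gauss–Hermite quadrature (probabilists' rule, 21 nodes by default, odd so a
node sits at the centre).  An adaptive variant recentres and rescales the
rule at each patient's Laplace mode; the plain rule is the default because
it is 2–3× faster and accurate to ~1e-7 per patient for σ_u ≲ 1.2, the
regime these models inhabit, while the adaptive rule holds to 1e-6 out to
σ_u ≈ 2 and beyond.

Optimisation is L-BFGS-B over (α, β, log σ_u), initialised at the plain
logistic MLE with σ_u = 0.5; convergence at relative likelihood change
< 1e-12 or gradient norm < 1e-8, max 500 iterations.  Standard errors come
from inverting the central-finite-difference observed information in
(α, β, σ_u); the 95% CI is Wald on the log-odds scale, `exp(β ± 1.96·SE)`
(a profile-likelihood interval is available as a non-default option).
Boundary and degenerate cases are handled explicitly: an estimated
σ_u < 1e-4 triggers an exact refit as plain logistic regression (the
σ_u = 0 sub-model); one observation per patient makes σ_u unidentifiable
(confounded with the link scale), so it is profiled at 0 and the model
reduces to plain logistic; quasi-complete separation is reported as
`converged=False` with a diagnostic message rather than a number; a
single-class outcome is an error at the single-model level and a
"not fitted, reason given" row at the battery level, letting the other
models proceed.

## Synthetic cohort generator

The generator emulates the monitoring study's structure, not TTV biology.
Patient covariates are drawn from the published marginals (69% male, mean
age 12.8 ± 5.2 y, mean post-transplant time 4.5 ± 4.2 y truncated at the
0.25-y eligibility floor, 86.7/6.7/6.7% tacrolimus/cyclosporin/rapamycin,
84.4/8.9/6.7% MMF/azathioprine/none, 67% living donors, 18% DSA+).  The
latent log10 load of patient *i* at month *t* is

    L_it = μ + Δ·[rapamycin] + s·(post-tx years − 4.5) + b_i + e_it

with baseline μ = 5.8, mTORi shift Δ = −2.0, follow-up slope s = −0.1/y
(centred at the cohort-mean follow-up time so μ keeps its meaning as the
typical CNI-patient level), b_i ~ N(0, 1.25²) between patients and
stationary AR(1) noise e_it (SD 0.8, lag correlation 0.3 — monthly
biological series are autocorrelated; set it to 0 for i.i.d. tests).  The
recorded load is 0 below the 2-log10 floor and min(L, 10) otherwise, and
~6% of visit slots are dropped at random (≈509 of 540 observed).  The
between/within split is not published; these defaults reproduce the
printed detectable-load IQR (≈2 log10 wide around a 5.8 median).  They give
~95–99% detectable samples; the published 94.5% includes two patients who
stayed negative essentially all year, a heavy lower tail a Gaussian
patient effect does not produce — a known, accepted mismatch.

The prednisolone dose shares the within-patient process with the load:
`dose_it = m_i + c·(κ·e_it/σ_w + η_it)`, which yields a latent Pearson
correlation `κ/√(1+κ²)`; κ is set analytically from the Spearman target
via the bivariate-normal relation `ρ_P = 2 sin(π ρ_S/6)` (default target
0.224; 0 decouples them).  Other doses vary around patient-specific means
independent of the load, and trough levels are always generated
independent of the load, mirroring the trough-level null finding.
Co-virus loads are sparse independent positives above the floor.

Events come from the random-intercept logistic model itself:
infection probability `logit⁻¹(α₀ + β·x_it + u_i)` with the *recorded*
load x_it (so the injected β is exactly the estimand of the analysis
model; using the pre-censoring latent load would build in an
errors-in-variables bias), u_i ~ N(0, 0.8²), α₀ set so the marginal rate
is near the published 119/509 episodes; febrile infections are a ~17%
sub-draw of infections.  Non-adherence is a patient trait (24% of
patients) flagged in ~50% of a flagged patient's months, with a 3%
background rate elsewhere so the flag is not perfectly separable by
patient.  Default infection slope is 0 (the null finding); fixtures inject
0.3–0.5 for recovery tests.

What passing tests therefore show: the pipeline recovers exactly the kinds
of effects it models (shift, trend, rank coupling, log-odds slope) under
Gaussian heterogeneity, AR(1) noise and missing-at-random visits.  They do
not certify behaviour under informative missingness, heavy-tailed patient
effects, dose changes *responding* to viral load, or measurement error —
none of which the generator produces.

## Numerical and testing choices

Result tables are written with nine significant digits and sorted rows, so
identical analyses give byte-identical files; the run manifest records the
seed, version and a hash of the analysis parameters (not the output path),
making report bundles comparable across directories.  Cohort CSVs are
written at full round-trip precision and re-read with the round-trip float
parser, so write→read is the identity.

Monte-Carlo problem sizes used by the validity suite: 1,000 null cohorts ×
200 permutations for the type-I error of the permutation test (two
binomial SEs around 0.05); exhaustive enumeration of all 36 joint
permutations on a 2-patient × 3-visit fixture against a 10,000-draw sample;
200 replicates of 200 patients × 12 months for mixed-model slope recovery
(bias bounded by two Monte-Carlo SEs) and Wald coverage (accepted in
[0.92, 0.98]).  The regimen-effect round trip at 2,000 patients compares
the ANOVA group gap with the injected 2.0 log10 allowing ±0.45: the
floor-to-0 recording of undetectable samples inflates the observed gap by
an analytically computed ≈ +0.14 under the default variances (the
mTORi group loses ~11% of its samples to the floor), and three Monte-Carlo
SEs add ~0.33; the gap is additionally checked against its exact censored
prediction.  The same censoring formula (`expected_observed_mean`) is part
of the package so the prediction is reproducible.

Known limitations: Wald intervals can undercover for very sparse outcomes
(the febrile model at 20 events is near that edge); the permutation test
assumes within-patient exchangeability of the covariate under the null,
which a strongly trending covariate violates; and the generator's defaults
encode published marginals, not joint distributions, so covariate
correlations (e.g. age with regimen) are absent unless injected.
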