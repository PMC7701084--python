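"""Synthetic paediatric kidney-transplant cohorts for desk-scale analysis.

The generator emulates the statistical structure of a 12-month TTV
monitoring study in ~45 paediatric kidney-graft recipients: monthly log10
viral loads with between-patient heterogeneity and AR(1) within-patient
noise, left-censoring at the assay detection limit (2 log10 copies/ml,
reported as 0) and a ceiling at 10 log10, an mTOR-inhibitor regimen effect,
a post-transplant-time trend, a tunable within-patient coupling between the
prednisolone dose and the viral load, and sparse binary events (infection,
febrile infection, suspected non-adherence) driven by a random-intercept
logistic model.

Category frequencies and cohort moments default to the study's published
marginals (86.7% tacrolimus / 6.7% cyclosporin / 6.7% rapamycin, 84.4% MMF,
69% male, 24% non-adherent, mean age 12.8 +/- 5.2 y, mean post-transplant
time 4.5 +/- 4.2 y, ~509 of 540 monthly samples available).

It models only the statistical structure the analyses assume — no TTV
strain dynamics or immune kinetics.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_io import Cohort, validate_cohort
from .preprocessing import log10_viral_load

__all__ = ["GeneratorConfig", "generate_cohort", "make_fixture", "expected_observed_mean"]


@dataclasses.dataclass
class GeneratorConfig:
    """Tunable structure of the synthetic cohort.

    Viral-load parameters are on the log10 copies/ml scale.  The
    prednisolone-dose coupling is calibrated so the population within-patient
    Spearman correlation with the load is ``dose_corr_target``.
    """

    n_patients: int = 45
    n_months: int = 12
    visit_missingness: float = 31.0 / 540.0   # ~509 of 540 slots observed
    detection_floor: float = 2.0
    ceiling: float = 10.0
    baseline_mean: float = 5.8                # CNI patient at mean follow-up time
    between_patient_sd: float = 1.25
    within_patient_sd: float = 0.8
    ar1_rho: float = 0.3
    mtori_effect: float = -2.0                # rapamycin shift, log10
    post_tx_slope: float = -0.1               # log10 per post-transplant year
    mean_post_tx_years: float = 4.5           # centring point for the slope
    dose_corr_target: float = 0.224           # within-patient Spearman, prednisolone
    infection_beta: float = 0.0               # log-odds per log10 observed load
    infection_base_rate: float = 119.0 / 509.0
    infection_sigma_u: float = 0.8
    febrile_given_infection: float = 20.0 / 119.0
    nonadherence_patient_fraction: float = 11.0 / 45.0
    nonadherence_month_rate: float = 0.5
    nonadherence_background_rate: float = 0.03  # one-off suspicions elsewhere
    regimen_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"tacrolimus": 39 / 45, "cyclosporin": 3 / 45, "rapamycin": 3 / 45}
    )
    antiprolif_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"MMF": 38 / 45, "azathioprine": 4 / 45, "none": 3 / 45}
    )
    disease_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {
            "CAKUT": 23 / 44, "glomerular": 5 / 44, "cystic": 8 / 44,
            "nephrotic": 6 / 44, "metabolic": 2 / 44,
        }
    )
    donation_probs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"living": 30 / 45, "deceased": 15 / 45}
    )
    male_prob: float = 31.0 / 45.0
    dsa_prob: float = 8.0 / 45.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_months < 1:
            raise ValueError("n_patients and n_months must be positive")
        for name in (
            "visit_missingness", "infection_base_rate", "febrile_given_infection",
            "nonadherence_patient_fraction", "nonadherence_month_rate",
            "nonadherence_background_rate", "male_prob", "dsa_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not self.detection_floor < self.ceiling:
            raise ValueError("detection_floor must lie below ceiling")
        if self.between_patient_sd <= 0 or self.within_patient_sd <= 0:
            raise ValueError("variance components must be positive")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must lie in [0, 1)")
        if not -1.0 < self.dose_corr_target < 1.0:
            raise ValueError("dose_corr_target must lie in (-1, 1)")
        for name in ("regimen_probs", "antiprolif_probs", "disease_probs", "donation_probs"):
            probs = dict(getattr(self, name))
            if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a distribution summing to 1")


# Dose and trough marginals per drug: (patient-mean, between-SD, monthly SD).
# Troughs are generated independent of the viral load, mirroring the null
# finding for trough levels.
_DRUG_DOSE = {
    "tacrolimus": ("tacrolimus_dose", 0.15, 0.05, 0.02),     # mg/kg
    "cyclosporin": ("cyclosporin_dose", 4.0, 1.0, 0.3),      # mg/kg
    "rapamycin": ("rapamycin_dose", 0.10, 0.03, 0.01),       # mg/kg
}
_DRUG_TROUGH = {
    "tacrolimus": ("tacrolimus_trough", 6.0, 1.5, 1.5),      # ng/ml
    "cyclosporin": ("cyclosporin_trough", 80.0, 20.0, 15.0),
    "rapamycin": ("rapamycin_trough", 6.0, 1.5, 1.5),
}
_ANTIPROLIF_DOSE = {
    "MMF": ("mmf_dose", 600.0, 100.0, 30.0),                 # mg/m²
    "azathioprine": ("azathioprine_dose", 1.5, 0.4, 0.1),    # mg/kg
}
# Co-virus plasma loads: (monthly positivity, log10 mean above floor, sd).
_COVIRUS = {
    "ebv_log10": (0.20, 0.8, 0.5),
    "cmv_log10": (0.05, 0.6, 0.4),
    "bkv_log10": (0.10, 0.9, 0.6),
}


def _spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal conversion: latent Pearson giving Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def expected_observed_mean(latent_mean: float, sd: float, floor: float, ceiling: float) -> float:
    """Expected recorded log10 load for a Normal(latent_mean, sd²) latent load.

    Below-floor values are recorded as 0; above-ceiling values are clipped.
    Used to predict the censoring distortion of group means analytically.
    """
    from scipy.stats import norm

    a = (floor - latent_mean) / sd
    b = (ceiling - latent_mean) / sd
    p_mid = norm.cdf(b) - norm.cdf(a)
    if p_mid <= 0:
        return ceiling if latent_mean > ceiling else 0.0
    mid_mean = latent_mean + sd * (norm.pdf(a) - norm.pdf(b)) / p_mid
    return p_mid * mid_mean + norm.sf(b) * ceiling


def _ar1(rng, n_months: int, n_patients: int, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise, shape (n_patients, n_months), marginal SD sd."""
    e = np.empty((n_patients, n_months))
    e[:, 0] = rng.normal(0.0, sd, size=n_patients)
    innov_sd = sd * math.sqrt(1.0 - rho**2)
    for t in range(1, n_months):
        e[:, t] = rho * e[:, t - 1] + rng.normal(0.0, innov_sd, size=n_patients)
    return e


def generate_cohort(config: GeneratorConfig | None = None) -> Cohort:
    """Draw a full synthetic cohort; bit-reproducible from ``config.seed``."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_patients, cfg.n_months

    pid = np.array([f"P{i + 1:04d}" for i in range(n)])
    gender = np.where(rng.random(n) < cfg.male_prob, "male", "female")
    age = np.clip(rng.normal(12.8, 5.2, size=n), 1.0, 21.0)
    post_tx = np.clip(np.abs(rng.normal(4.5, 4.2, size=n)), 0.25, None)
    post_tx = np.minimum(post_tx, np.maximum(age - 0.3, 0.25))
    age_at_tx = age - post_tx
    disease = rng.choice(list(cfg.disease_probs), p=list(cfg.disease_probs.values()), size=n)
    donation = rng.choice(list(cfg.donation_probs), p=list(cfg.donation_probs.values()), size=n)
    mismatch = rng.binomial(6, 0.45, size=n).astype(float)
    dsa = rng.random(n) < cfg.dsa_prob
    regimen = rng.choice(list(cfg.regimen_probs), p=list(cfg.regimen_probs.values()), size=n)
    antiprolif = rng.choice(list(cfg.antiprolif_probs), p=list(cfg.antiprolif_probs.values()), size=n)

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "gender": gender,
            "age_at_study_start": age,
            "age_at_transplant": age_at_tx,
            "post_transplant_time": post_tx,
            "primary_disease": disease,
            "donation_type": donation,
            "hla_mismatch": pd.array(mismatch, dtype="Float64"),
            "dsa_positive": pd.array(dsa, dtype="boolean"),
            "cni_or_mtori": regimen,
            "antiproliferative": antiprolif,
        }
    )

    # Latent log10 load: patient level + centred follow-up-time trend + AR(1).
    b_i = rng.normal(0.0, cfg.between_patient_sd, size=n)
    mu_i = (
        cfg.baseline_mean
        + np.where(regimen == "rapamycin", cfg.mtori_effect, 0.0)
        + cfg.post_tx_slope * (post_tx - cfg.mean_post_tx_years)
        + b_i
    )
    e = _ar1(rng, m, n, cfg.within_patient_sd, cfg.ar1_rho)
    latent = mu_i[:, None] + e

    raw = np.where(latent < cfg.detection_floor, 0.0, 10.0 ** np.minimum(latent, cfg.ceiling))

    # Prednisolone couples to the within-patient load deviation: sharing the
    # AR(1) process with loading kappa gives latent Pearson correlation
    # kappa/sqrt(1+kappa^2); kappa is set from the Spearman target via the
    # bivariate-normal relation rho_p = 2 sin(pi rho_s / 6).
    rho_p = _spearman_to_pearson(cfg.dose_corr_target)
    kappa = rho_p / math.sqrt(1.0 - rho_p**2) if abs(rho_p) < 1 else math.inf
    pred_mu = np.clip(rng.normal(8.0, 2.0, size=n), 2.0, None)
    shared = kappa * e / cfg.within_patient_sd + rng.normal(0.0, 1.0, size=(n, m))
    pred_dose = np.maximum(
        pred_mu[:, None] + 1.5 * shared / math.sqrt(1.0 + kappa**2), 0.1
    )

    def drug_series(spec_map, on_label):
        out = {}
        for drug, (col, mean, b_sd, w_sd) in spec_map.items():
            mu = np.clip(rng.normal(mean, b_sd, size=n), mean * 0.2, None)
            series = np.clip(mu[:, None] + rng.normal(0.0, w_sd, size=(n, m)), mean * 0.05, None)
            mask = (on_label == drug)[:, None]
            out[col] = np.where(mask, series, np.nan)
        return out

    drug_cols = drug_series(_DRUG_DOSE, regimen)
    drug_cols.update(drug_series(_DRUG_TROUGH, regimen))
    drug_cols.update(drug_series(_ANTIPROLIF_DOSE, antiprolif))

    egfr_mu = np.clip(rng.normal(75.0, 20.0, size=n), 15.0, None)
    egfr = np.clip(egfr_mu[:, None] + rng.normal(0.0, 5.0, size=(n, m)), 5.0, None)

    covirus = {}
    for col, (p_pos, above, sd) in _COVIRUS.items():
        pos = rng.random((n, m)) < p_pos
        level = cfg.detection_floor + np.abs(rng.normal(above, sd, size=(n, m)))
        covirus[col] = np.where(pos, np.minimum(level, cfg.ceiling), 0.0)

    # Events from the *observed* load so the injected log-odds slope is the
    # estimand of the downstream random-intercept model.
    obs_log10 = np.asarray(log10_viral_load(raw))
    u_i = rng.normal(0.0, cfg.infection_sigma_u, size=n)
    alpha_inf = logit(cfg.infection_base_rate) - cfg.infection_beta * cfg.baseline_mean
    p_inf = expit(alpha_inf + cfg.infection_beta * obs_log10 + u_i[:, None])
    infection = rng.random((n, m)) < p_inf
    febrile = infection & (rng.random((n, m)) < cfg.febrile_given_infection)
    nonadh_patient = rng.random(n) < cfg.nonadherence_patient_fraction
    month_rate = np.where(
        nonadh_patient, cfg.nonadherence_month_rate, cfg.nonadherence_background_rate
    )
    nonadherent = rng.random((n, m)) < month_rate[:, None]

    present = rng.random((n, m)) >= cfg.visit_missingness

    rows = {
        "patient_id": np.repeat(pid, m),
        "month_index": np.tile(np.arange(m), n),
        "ttv_raw": raw.ravel(),
        "prednisolone_dose": pred_dose.ravel(),
        "tacrolimus_dose": drug_cols["tacrolimus_dose"].ravel(),
        "cyclosporin_dose": drug_cols["cyclosporin_dose"].ravel(),
        "rapamycin_dose": drug_cols["rapamycin_dose"].ravel(),
        "mmf_dose": drug_cols["mmf_dose"].ravel(),
        "azathioprine_dose": drug_cols["azathioprine_dose"].ravel(),
        "tacrolimus_trough": drug_cols["tacrolimus_trough"].ravel(),
        "cyclosporin_trough": drug_cols["cyclosporin_trough"].ravel(),
        "rapamycin_trough": drug_cols["rapamycin_trough"].ravel(),
        "egfr": egfr.ravel(),
        "ebv_log10": covirus["ebv_log10"].ravel(),
        "cmv_log10": covirus["cmv_log10"].ravel(),
        "bkv_log10": covirus["bkv_log10"].ravel(),
        "infection": infection.ravel(),
        "febrile_infection": febrile.ravel(),
        "nonadherence_suspected": nonadherent.ravel(),
    }
    visits = pd.DataFrame(rows)[present.ravel()].reset_index(drop=True)
    for col in ("infection", "febrile_infection", "nonadherence_suspected"):
        visits[col] = visits[col].astype("boolean")
    visits["ttv_log10"] = log10_viral_load(visits["ttv_raw"].to_numpy())

    validate_cohort(patients, visits)
    return Cohort(patients=patients, visits=visits)


_FIXTURE_SEEDS = {"null": 101, "dose_effect": 202, "infection_effect": 303}


def make_fixture(name: str) -> tuple[Cohort, dict]:
    """Named frozen-seed cohorts for testing, with their true parameters.

    ``tiny`` is a hand-built 2-patient x 3-visit cohort with all-distinct
    values, sized for exhaustive permutation enumeration; ``null`` has the
    prednisolone dose independent of the load; ``dose_effect`` injects the
    default dose-load coupling; ``infection_effect`` injects a 0.5 log-odds
    infection slope per log10 load.
    """
    if name == "tiny":
        return _tiny_fixture()
    if name not in _FIXTURE_SEEDS:
        raise ValueError(f"unknown fixture {name!r}")
    cfg = GeneratorConfig(seed=_FIXTURE_SEEDS[name])
    if name == "null":
        cfg.dose_corr_target = 0.0
        cfg.infection_beta = 0.0
    elif name == "infection_effect":
        cfg.infection_beta = 0.5
        cfg.infection_sigma_u = 1.0
    truth = dataclasses.asdict(cfg)
    truth["fixture"] = name
    return generate_cohort(cfg), truth


def _tiny_fixture() -> tuple[Cohort, dict]:
    patients = pd.DataFrame(
        {
            "patient_id": ["T01", "T02"],
            "gender": ["male", "female"],
            "age_at_study_start": [10.0, 14.0],
            "age_at_transplant": [6.0, 9.0],
            "post_transplant_time": [4.0, 5.0],
            "primary_disease": ["CAKUT", "cystic"],
            "donation_type": ["living", "deceased"],
            "hla_mismatch": pd.array([2.0, 3.0], dtype="Float64"),
            "dsa_positive": pd.array([False, True], dtype="boolean"),
            "cni_or_mtori": ["tacrolimus", "tacrolimus"],
            "antiproliferative": ["MMF", "none"],
        }
    )
    log_loads = [4.1, 5.3, 3.7, 6.2, 2.9, 5.0]
    visits = pd.DataFrame(
        {
            "patient_id": ["T01"] * 3 + ["T02"] * 3,
            "month_index": [0, 1, 2, 0, 1, 2],
            "ttv_raw": [10.0**v for v in log_loads],
            "prednisolone_dose": [7.1, 9.4, 8.2, 6.5, 10.1, 7.9],
            "tacrolimus_dose": [0.15, 0.14, 0.16, 0.12, 0.13, 0.11],
            "cyclosporin_dose": [np.nan] * 6,
            "rapamycin_dose": [np.nan] * 6,
            "mmf_dose": [580.0, 610.0, 595.0, np.nan, np.nan, np.nan],
            "azathioprine_dose": [np.nan] * 6,
            "tacrolimus_trough": [5.8, 6.4, 6.1, 7.2, 5.5, 6.8],
            "cyclosporin_trough": [np.nan] * 6,
            "rapamycin_trough": [np.nan] * 6,
            "egfr": [72.0, 75.0, 70.0, 88.0, 85.0, 90.0],
            "ebv_log10": [0.0, 2.5, 0.0, 0.0, 0.0, 3.1],
            "cmv_log10": [0.0] * 6,
            "bkv_log10": [0.0, 0.0, 2.2, 0.0, 0.0, 0.0],
            "infection": pd.array([False, True, False, False, False, True], dtype="boolean"),
            "febrile_infection": pd.array([False] * 6, dtype="boolean"),
            "nonadherence_suspected": pd.array([False, False, False, True, True, False], dtype="boolean"),
        }
    )
    visits["ttv_log10"] = log10_viral_load(visits["ttv_raw"].to_numpy())
    validate_cohort(patients, visits)
    truth = {"fixture": "tiny", "n_patients": 2, "n_months": 3, "log_loads": log_loads}
    return Cohort(patients=patients, visits=visits), truth
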