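"""Operating-characteristic simulations: type-I error, power and recovery.

These harnesses regenerate synthetic cohorts many times and push them
through the analysis modules, measuring empirical rejection rates, estimator
bias and confidence-interval coverage.  They back the `simulate-power` CLI
subcommand and the validity checks in the test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .associations import one_way_anova, run_association_table
from .mixed_logit import QuadratureSpec, fit_random_intercept_logit
from .repeated_correlation import mean_correlation_permutation_test
from .synthetic import GeneratorConfig, expected_observed_mean, generate_cohort

__all__ = [
    "permutation_rejection_rate",
    "mixed_logit_recovery",
    "regimen_gap_recovery",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=2 * n).reshape(n, 2)


def permutation_rejection_rate(
    n_replicates: int,
    dose_corr_target: float = 0.0,
    alpha: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> dict:
    """Rejection rate of the mean-correlation permutation test.

    Each replicate draws a fresh cohort with the prednisolone-dose coupling
    set to ``dose_corr_target`` (0 for a type-I-error run) and tests the
    prednisolone variable at level ``alpha``.  Returns the empirical rate
    and its binomial standard error.
    """
    rejections = 0
    p_values = np.empty(n_replicates)
    for i, (gen_seed, perm_seed) in enumerate(_child_seeds(seed, n_replicates)):
        cfg = dataclasses.replace(
            config or GeneratorConfig(),
            dose_corr_target=dose_corr_target,
            seed=int(gen_seed),
        )
        cohort = generate_cohort(cfg)
        res = mean_correlation_permutation_test(
            cohort, "prednisolone_dose", n_permutations=n_permutations, seed=int(perm_seed)
        )
        p_values[i] = res.p_value
        rejections += res.p_value <= alpha
    rate = rejections / n_replicates
    return {
        "rate": rate,
        "se": float(np.sqrt(alpha * (1 - alpha) / n_replicates)),
        "alpha": alpha,
        "n_replicates": n_replicates,
        "p_values": p_values,
    }


def mixed_logit_recovery(
    n_replicates: int = 200,
    n_patients: int = 200,
    infection_beta: float = 0.5,
    infection_sigma_u: float = 1.0,
    n_nodes: int = 21,
    seed: int = 0,
) -> dict:
    """Bias and 95%-CI coverage of the random-intercept infection model.

    Cohorts are generated with a known log-odds slope per log10 load and a
    known random-intercept SD; each replicate refits the same-month
    infection model and records the slope estimate and whether the Wald CI
    covers the truth.
    """
    quad = QuadratureSpec(n_nodes=n_nodes)
    betas, covers, sigmas = [], [], []
    for gen_seed, _ in _child_seeds(seed, n_replicates):
        cfg = GeneratorConfig(
            n_patients=n_patients,
            infection_beta=infection_beta,
            infection_sigma_u=infection_sigma_u,
            seed=int(gen_seed),
        )
        cohort = generate_cohort(cfg)
        df = cohort.visits[["patient_id", "ttv_log10", "infection"]].dropna()
        pairs = df.rename(columns={"infection": "outcome"})
        pairs["outcome"] = pairs["outcome"].astype(bool).astype(int)
        res = fit_random_intercept_logit(pairs, quad, outcome_name="infection")
        if not res.converged:
            continue
        betas.append(res.beta)
        sigmas.append(res.sigma_u)
        covers.append(
            np.log(res.or_lower) <= infection_beta <= np.log(res.or_upper)
        )
    betas = np.asarray(betas)
    return {
        "true_beta": infection_beta,
        "mean_beta": float(betas.mean()),
        "mc_se": float(betas.std(ddof=1) / np.sqrt(betas.size)),
        "coverage": float(np.mean(covers)),
        "mean_sigma_u": float(np.mean(sigmas)),
        "n_fitted": int(betas.size),
        "betas": betas,
    }


def regimen_gap_recovery(
    n_patients: int = 2000, mtori_effect: float = -2.0, seed: int = 0
) -> dict:
    """Recover the CNI-vs-mTORi mean-load gap on a large generated cohort.

    Returns the ANOVA result for the regimen class, the estimated gap
    (CNI mean minus mTORi mean, on the recorded log10 scale) and the
    analytically predicted gap under the detection-floor/ceiling coding,
    which the recorded means are expected to match.
    """
    cfg = GeneratorConfig(n_patients=n_patients, mtori_effect=mtori_effect, seed=seed)
    cohort = generate_cohort(cfg)
    results = {r.variable: r for r in run_association_table(cohort)}
    res = results["regimen_class"]
    # one_way_anova sorts group labels: ("CNI", "mTORi")
    gap = res.effect[0] - res.effect[1]
    sd = float(np.hypot(cfg.between_patient_sd, cfg.within_patient_sd))
    predicted = expected_observed_mean(
        cfg.baseline_mean, sd, cfg.detection_floor, cfg.ceiling
    ) - expected_observed_mean(
        cfg.baseline_mean + mtori_effect, sd, cfg.detection_floor, cfg.ceiling
    )
    return {
        "anova": res,
        "gap": float(gap),
        "predicted_gap": float(predicted),
        "injected_gap": float(-mtori_effect),
    }
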