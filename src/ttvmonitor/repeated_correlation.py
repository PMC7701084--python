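"""Repeated-measures correlation with a within-patient permutation test.

For each patient, the Spearman rank correlation between the monthly log10
TTV load and a monthly covariate (drug dose, trough level, co-virus load or
eGFR) is computed across that patient's visits.  The cohort statistic is the
unweighted mean of those per-patient coefficients.  Its significance is
assessed by a permutation test that independently permutes, within each
patient, the time order of the covariate series while holding the TTV
series fixed — the minimal exchangeability assumption that targets the
within-patient association while preserving each patient's own TTV
trajectory and the patient-level structure.

The test is two-sided and uses the add-one finite-sample correction, so the
smallest attainable p with B permutations is 1/(B+1) and the p-value is
valid by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CorrelationResult",
    "spearman_rho",
    "per_patient_correlations",
    "mean_correlation_permutation_test",
    "run_correlation_table",
    "CORRELATION_VARIABLES",
]

# Monthly metric fields correlated with the same-visit TTV load.  Patients
# not on a drug have that drug's dose/trough missing on every visit, so they
# drop out of that variable's analysis through the complete-pair rule.
CORRELATION_VARIABLES = [
    "prednisolone_dose",
    "tacrolimus_dose",
    "cyclosporin_dose",
    "rapamycin_dose",
    "mmf_dose",
    "azathioprine_dose",
    "tacrolimus_trough",
    "cyclosporin_trough",
    "rapamycin_trough",
    "ebv_log10",
    "cmv_log10",
    "bkv_log10",
    "egfr",
]

DEFAULT_MIN_PAIRS = 3  # smallest n with a nondegenerate rank correlation


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    variable: str
    per_patient_rho: dict  # patient_id -> Spearman rho
    mean_rho: float
    p_value: float
    n_patients: int
    n_permutations: int
    seed: int


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of midranks.

    Missing values are removed pairwise.  Returns NaN (not an error) when
    fewer than three complete pairs remain or either series is constant, so
    the caller decides inclusion.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        return float("nan")
    rx = rankdata(x)  # midranks for ties
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def _patient_rank_pairs(cohort, variable: str, min_pairs: int):
    """Per-patient centred, unit-norm rank vectors of (TTV, covariate).

    Only patients with >= min_pairs complete pairs and a defined (non-
    degenerate) rank correlation are kept; observed rho is the dot product
    of the two normalised rank vectors.
    """
    if variable not in cohort.visits.columns:
        raise KeyError(f"unknown monthly variable {variable!r}")
    pairs = {}
    for pid, sub in cohort.visits.groupby("patient_id", sort=False):
        x = sub["ttv_log10"].to_numpy(dtype=float)
        y = sub[variable].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        x, y = x[keep], y[keep]
        if x.size < max(min_pairs, 2):
            continue
        rx, ry = rankdata(x), rankdata(y)
        if np.ptp(rx) == 0 or np.ptp(ry) == 0 or x.size < min_pairs:
            continue
        rx = rx - rx.mean()
        ry = ry - ry.mean()
        pairs[str(pid)] = (rx / np.linalg.norm(rx), ry / np.linalg.norm(ry))
    return pairs


def per_patient_correlations(
    cohort, variable: str, min_pairs: int = DEFAULT_MIN_PAIRS
) -> dict[str, float]:
    """Spearman rho per patient between monthly TTV and ``variable``.

    Patients with fewer than ``min_pairs`` complete pairs, or with a
    constant series (undefined rho), are excluded.  An empty result is an
    error naming the variable.
    """
    pairs = _patient_rank_pairs(cohort, variable, min_pairs)
    if not pairs:
        raise ValueError(f"no patient has enough complete pairs for {variable!r}")
    return {pid: float(rx @ ry) for pid, (rx, ry) in pairs.items()}


def mean_correlation_permutation_test(
    cohort,
    variable: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> CorrelationResult:
    """Permutation test of the mean per-patient Spearman correlation.

    The observed statistic is T = mean of per-patient rho.  Each of the
    ``n_permutations`` null draws independently permutes every patient's
    covariate series in time (TTV fixed) and recomputes T.  Two-sided
    p = (#{|T*| >= |T|} + 1) / (B + 1).  Patients with undefined rho are
    excluded from both the observed and the permuted statistic, so both use
    the same patient set.  Bit-reproducible for a given seed.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pairs = _patient_rank_pairs(cohort, variable, min_pairs)
    if len(pairs) < 2:
        raise ValueError(
            f"permutation test needs >= 2 contributing patients for "
            f"{variable!r}, got {len(pairs)}"
        )
    rhos = {pid: float(rx @ ry) for pid, (rx, ry) in pairs.items()}
    t_obs = float(np.mean(list(rhos.values())))

    rng = np.random.default_rng(seed)
    b = int(n_permutations)
    t_null = np.zeros(b)
    # Permuting a series then ranking equals permuting its midranks, so the
    # normalised rank vectors can be permuted directly; per patient, B
    # permutations are drawn at once via argsort of uniform keys.
    for rx, ry in pairs.values():
        perms = np.argsort(rng.random((b, ry.size)), axis=1)
        t_null += ry[perms] @ rx
    t_null /= len(pairs)

    exceed = int(np.count_nonzero(np.abs(t_null) >= abs(t_obs) - 1e-12))
    p = (exceed + 1) / (b + 1)
    return CorrelationResult(
        variable=variable,
        per_patient_rho=rhos,
        mean_rho=t_obs,
        p_value=float(p),
        n_patients=len(rhos),
        n_permutations=b,
        seed=int(seed),
    )


def run_correlation_table(
    cohort,
    variables: list[str] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> list[CorrelationResult]:
    """Permutation tests for every monthly metric variable.

    Each variable gets an independent child seed derived deterministically
    from ``seed``; variables that no patient can contribute to are skipped.
    """
    if variables is None:
        variables = CORRELATION_VARIABLES
    seed_rng = np.random.default_rng(seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=len(variables))
    results = []
    for variable, child in zip(variables, child_seeds):
        try:
            results.append(
                mean_correlation_permutation_test(
                    cohort,
                    variable,
                    n_permutations=n_permutations,
                    seed=int(child),
                    min_pairs=min_pairs,
                )
            )
        except (ValueError, KeyError):
            continue
    if not results:
        raise ValueError("no correlation variable could be analysed")
    return results
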