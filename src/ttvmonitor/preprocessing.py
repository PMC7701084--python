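"""Transformations every downstream analysis consumes.

The viral-load transform, the paediatric Schwartz eGFR formula, per-patient
summaries of the monthly log10 TTV series, and the one-month-lag pairing of
viral load with next-month events.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "PatientSummary",
    "log10_viral_load",
    "schwartz_egfr",
    "schwartz_k",
    "summarize_patient",
    "summarize_cohort",
    "build_lagged_pairs",
    "lagged_outcome_table",
    "prevalence_percent",
]


@dataclasses.dataclass(frozen=True)
class PatientSummary:
    """Per-patient aggregate of the monthly log10 TTV series."""

    patient_id: str
    mean_ttv_log10: float
    n_visits: int      # visits with a non-missing load entering the mean
    n_detectable: int  # visits with load above the detection limit


def log10_viral_load(raw):
    """log10-transform a raw viral load (copies/ml).

    Undetectable samples are reported by the assay as 0 and are set to 1
    before the transform, so they contribute log10(1) = 0.  Values in the
    open interval (0, 1) cannot be produced by the assay and are rejected,
    as are negative inputs.  Accepts scalars or arrays.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("viral load must be >= 0 copies/ml")
    finite = arr[~np.isnan(arr)]
    if np.any((finite > 0) & (finite < 1)):
        raise ValueError("viral load in (0, 1) copies/ml is not a possible assay output")
    with np.errstate(divide="ignore"):
        out = np.where(arr == 0, 0.0, np.log10(np.where(arr == 0, 1.0, arr)))
    out = np.where(np.isnan(arr), np.nan, out)
    return float(out) if np.isscalar(raw) else out


def schwartz_k(age_years: float, gender: str) -> float:
    """Original-Schwartz proportionality constant from age and gender.

    0.45 for infants under one year, 0.70 for adolescent males (>= 13 y),
    0.55 otherwise.
    """
    if age_years < 1.0:
        return 0.45
    if gender == "male" and age_years >= 13.0:
        return 0.70
    return 0.55


def schwartz_egfr(
    height_cm: float,
    serum_creatinine_mgdl: float,
    k: float | None = None,
    *,
    age_years: float | None = None,
    gender: str | None = None,
) -> float:
    """Estimated GFR (ml/min/1.73 m²) by the original Schwartz formula.

    eGFR = k × height (cm) / serum creatinine (mg/dl).  Supply ``k``
    directly, or ``age_years`` and ``gender`` to pick the standard constant.
    """
    if k is None:
        if age_years is None or gender is None:
            raise ValueError("supply k, or age_years and gender to derive it")
        k = schwartz_k(age_years, gender)
    if height_cm <= 0:
        raise ValueError("height must be positive")
    if serum_creatinine_mgdl <= 0:
        raise ValueError("serum creatinine must be positive (division by zero)")
    if k <= 0:
        raise ValueError("Schwartz constant k must be positive")
    return k * height_cm / serum_creatinine_mgdl


def summarize_patient(visits: pd.DataFrame) -> PatientSummary:
    """Mean log10 TTV across one patient's visits.

    Missing loads are dropped (complete-case per time point); undetectable
    loads are *kept* and enter the mean as 0, following mechanically from
    the set-0-to-1 transform rule.
    """
    pids = visits["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"expected one patient's visits, got {len(pids)} patients")
    pid = pids[0]
    vals = visits["ttv_log10"].astype(float).dropna()
    if vals.empty:
        raise ValueError(f"patient {pid!r} has no usable TTV measurements")
    return PatientSummary(
        patient_id=str(pid),
        mean_ttv_log10=float(vals.mean()),
        n_visits=int(vals.size),
        n_detectable=int((vals > 0).sum()),
    )


def summarize_cohort(cohort) -> pd.DataFrame:
    """Patient-level table: fixed covariates joined with the TTV summary."""
    rows = []
    for pid, sub in cohort.visits.groupby("patient_id", sort=False):
        rows.append(dataclasses.asdict(summarize_patient(sub)))
    summary = pd.DataFrame(rows)
    return cohort.patients.merge(summary, on="patient_id", how="inner")


def build_lagged_pairs(visits: pd.DataFrame, outcome_field: str) -> pd.DataFrame:
    """Pair each month's TTV load with the next month's event flag.

    A pair (load at month m, outcome at month m+1) is emitted only when both
    calendar months are present and both fields are non-missing; gaps in the
    visit schedule produce no pair.  Returns a frame with columns
    ``patient_id``, ``month_index`` (the predictor month), ``ttv_log10`` and
    ``outcome``.
    """
    v = visits.sort_values("month_index")
    by_month = v.set_index("month_index")
    rows = []
    for m in by_month.index:
        if m + 1 not in by_month.index:
            continue
        x = by_month.at[m, "ttv_log10"]
        y = by_month.at[m + 1, outcome_field]
        if pd.isna(x) or pd.isna(y):
            continue
        rows.append(
            {
                "patient_id": by_month.at[m, "patient_id"],
                "month_index": int(m),
                "ttv_log10": float(x),
                "outcome": int(bool(y)),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "month_index", "ttv_log10", "outcome"])


def lagged_outcome_table(cohort, outcome_field: str) -> pd.DataFrame:
    """Cohort-wide one-month-lag pairs, one frame across all patients."""
    parts = [
        build_lagged_pairs(sub, outcome_field)
        for _, sub in cohort.visits.groupby("patient_id", sort=False)
    ]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame(columns=["patient_id", "month_index", "ttv_log10", "outcome"])
    return pd.concat(parts, ignore_index=True)


def prevalence_percent(n_detectable: int, n_total: int, ndigits: int = 1) -> float:
    """Percentage of samples with detectable virus, rounded for reporting."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_detectable <= n_total:
        raise ValueError("n_detectable must lie in [0, n_total]")
    return round(100.0 * n_detectable / n_total, ndigits)
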