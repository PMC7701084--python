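"""Cohort table I/O and validation.

The analysis consumes two long-format CSV tables:

``patients.csv``
    One row per patient with the fixed covariates (demographics, transplant
    characteristics, immunosuppressive regimen, DSA status).

``visits.csv``
    One row per patient-month with the raw TTV load (copies/ml, ``0``
    encoding below the detection limit), immunosuppressant doses and trough
    levels, eGFR, co-virus log10 loads and binary event flags.

Missing values are empty cells and stay missing in memory (NaN / pandas NA);
``0`` is a legal value only where zero is meaningful (an undetectable viral
load, the dose of a drug the patient actually takes).  The derived
``ttv_log10`` column is never stored on disk — it is recomputed on load from
``ttv_raw`` so the transform rule has a single home.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "write_results",
    "validate_cohort",
    "PATIENT_COLUMNS",
    "VISIT_CSV_COLUMNS",
    "GENDERS",
    "PRIMARY_DISEASES",
    "DONATION_TYPES",
    "REGIMENS",
    "ANTIPROLIFERATIVES",
    "REGIMEN_COLUMNS",
    "ANTIPROLIFERATIVE_COLUMNS",
]


class ValidationError(ValueError):
    """A cohort table violates one of the documented invariants."""


GENDERS = frozenset({"male", "female"})
PRIMARY_DISEASES = frozenset({"CAKUT", "glomerular", "cystic", "nephrotic", "metabolic"})
DONATION_TYPES = frozenset({"living", "deceased"})
REGIMENS = frozenset({"tacrolimus", "cyclosporin", "rapamycin"})
ANTIPROLIFERATIVES = frozenset({"MMF", "azathioprine", "none"})

PATIENT_COLUMNS = [
    "patient_id",
    "gender",
    "age_at_study_start",
    "age_at_transplant",
    "post_transplant_time",
    "primary_disease",
    "donation_type",
    "hla_mismatch",
    "dsa_positive",
    "cni_or_mtori",
    "antiproliferative",
]

# Visit columns as stored on disk; ttv_log10 is derived in memory.
VISIT_CSV_COLUMNS = [
    "patient_id",
    "month_index",
    "ttv_raw",
    "prednisolone_dose",
    "tacrolimus_dose",
    "cyclosporin_dose",
    "rapamycin_dose",
    "mmf_dose",
    "azathioprine_dose",
    "tacrolimus_trough",
    "cyclosporin_trough",
    "rapamycin_trough",
    "egfr",
    "ebv_log10",
    "cmv_log10",
    "bkv_log10",
    "infection",
    "febrile_infection",
    "nonadherence_suspected",
]

BOOL_VISIT_COLUMNS = ["infection", "febrile_infection", "nonadherence_suspected"]

# Which dose/trough columns a maintenance regimen licenses; doses of drugs a
# patient is not on must stay missing, never zero-filled.
REGIMEN_COLUMNS = {
    "tacrolimus": ["tacrolimus_dose", "tacrolimus_trough"],
    "cyclosporin": ["cyclosporin_dose", "cyclosporin_trough"],
    "rapamycin": ["rapamycin_dose", "rapamycin_trough"],
}
ANTIPROLIFERATIVE_COLUMNS = {
    "MMF": ["mmf_dose"],
    "azathioprine": ["azathioprine_dose"],
    "none": [],
}

MIN_POST_TRANSPLANT_YEARS = 0.25  # study exclusion: < 3 months post-transplant

_FLOAT_FMT = "%.9g"  # >= 6 significant digits, deterministic


@dataclasses.dataclass
class Cohort:
    """A validated pair of patient and visit tables.

    ``visits`` carries the derived ``ttv_log10`` column; ``patients`` is
    indexed positionally with ``patient_id`` as an ordinary column so the
    frames round-trip through CSV unchanged.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def visits_for(self, patient_id: str) -> pd.DataFrame:
        """One patient's visits, sorted by month."""
        sub = self.visits[self.visits["patient_id"] == patient_id]
        return sub.sort_values("month_index").reset_index(drop=True)

    def equals(self, other: "Cohort") -> bool:
        a = self.patients.reset_index(drop=True)
        b = other.patients.reset_index(drop=True)
        c = self.visits.reset_index(drop=True)
        d = other.visits.reset_index(drop=True)
        return a.equals(b) and c.equals(d)


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


def validate_cohort(patients: pd.DataFrame, visits: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` on the first violated invariant."""
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    _check(not missing, f"patient table is missing columns: {missing}")
    missing = [c for c in VISIT_CSV_COLUMNS if c not in visits.columns]
    _check(not missing, f"visit table is missing columns: {missing}")

    dup = patients["patient_id"][patients["patient_id"].duplicated()]
    _check(dup.empty, f"duplicate patient_id: {sorted(set(dup))}")

    for col, allowed in [
        ("gender", GENDERS),
        ("primary_disease", PRIMARY_DISEASES),
        ("donation_type", DONATION_TYPES),
        ("cni_or_mtori", REGIMENS),
        ("antiproliferative", ANTIPROLIFERATIVES),
    ]:
        bad = set(patients[col].dropna()) - allowed
        _check(not bad, f"invalid {col} values: {sorted(bad)}")

    ptt = patients["post_transplant_time"].astype(float)
    short = patients.loc[ptt < MIN_POST_TRANSPLANT_YEARS, "patient_id"]
    _check(
        short.empty,
        f"post_transplant_time below {MIN_POST_TRANSPLANT_YEARS} y (study "
        f"exclusion) for patients: {sorted(short)}",
    )
    mm = pd.to_numeric(patients["hla_mismatch"], errors="coerce")
    _check((mm.dropna() >= 0).all(), "hla_mismatch must be >= 0 where present")

    keys = visits[["patient_id", "month_index"]]
    dup_mask = keys.duplicated()
    if dup_mask.any():
        first = keys[dup_mask].iloc[0]
        raise ValidationError(
            f"duplicate visit key (patient_id={first['patient_id']!r}, "
            f"month_index={first['month_index']})"
        )

    month = pd.to_numeric(visits["month_index"], errors="coerce")
    _check(month.notna().all(), "month_index must be an integer")
    _check(
        ((month >= 0) & (month <= 11) & (month == month.round())).all(),
        "month_index must be an integer in 0..11",
    )

    unknown = set(visits["patient_id"]) - set(patients["patient_id"])
    _check(not unknown, f"visits reference unknown patients: {sorted(unknown)}")

    raw = visits["ttv_raw"].astype(float)
    _check((raw.dropna() >= 0).all(), "ttv_raw must be >= 0")
    in_gap = (raw > 0) & (raw < 1)
    _check(not in_gap.any(), "ttv_raw in (0,1) is not a possible assay output")
    log10 = _derive_ttv_log10(raw)
    bad = log10.dropna()
    bad = bad[(bad != 0) & ((bad < 2 - 1e-9) | (bad > 10 + 1e-9))]
    if not bad.empty:
        raise ValidationError(
            f"ttv_log10 outside {{0}} ∪ [2, 10] (reportable range): "
            f"first offending value {bad.iloc[0]:.4g}"
        )

    feb = visits["febrile_infection"].fillna(False).astype(bool)
    inf = visits["infection"].fillna(False).astype(bool)
    _check((inf | ~feb).all(), "febrile_infection implies infection")

    # Regimen category licenses which dose/trough columns may be non-missing.
    drug_cols = {c for cols in REGIMEN_COLUMNS.values() for c in cols}
    ap_cols = {c for cols in ANTIPROLIFERATIVE_COLUMNS.values() for c in cols}
    regimen = patients.set_index("patient_id")["cni_or_mtori"]
    antiprolif = patients.set_index("patient_id")["antiproliferative"]
    for pid, sub in visits.groupby("patient_id", sort=False):
        allowed = set(REGIMEN_COLUMNS.get(regimen.get(pid), []))
        allowed |= set(ANTIPROLIFERATIVE_COLUMNS.get(antiprolif.get(pid), []))
        for col in sorted((drug_cols | ap_cols) - allowed):
            if sub[col].notna().any():
                raise ValidationError(
                    f"patient {pid!r} is not on the drug for column {col!r} "
                    f"but has non-missing values there"
                )


def _derive_ttv_log10(raw: pd.Series) -> pd.Series:
    """Left-censored log10 transform: raw 0 (undetectable) maps to 0."""
    out = pd.Series(np.nan, index=raw.index, dtype=float)
    pos = raw.notna()
    vals = raw[pos].astype(float)
    out[pos] = np.where(vals == 0, 0.0, np.log10(np.where(vals == 0, 1.0, vals)))
    return out


def _coerce_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "1": True, "0": False, "true": True, "false": False,
        1: True, 0: False, 1.0: True, 0.0: False, True: True, False: False,
    }

    def conv(v):
        if pd.isna(v):
            return pd.NA
        key = v.strip().lower() if isinstance(v, str) else v
        if key not in mapping:
            raise ValidationError(f"cannot interpret {v!r} as a boolean flag")
        return mapping[key]

    return series.map(conv).astype("boolean")


def read_cohort(patient_table_path: str | Path, visit_table_path: str | Path) -> Cohort:
    """Read and validate the two cohort tables.

    Raises :class:`ValidationError` on duplicate keys, out-of-range viral
    loads, visits referencing unknown patients, or regimen/dose mismatches.
    Missing values are preserved as missing, never imputed.
    """
    patients = pd.read_csv(
        patient_table_path, dtype={"patient_id": str}, float_precision="round_trip"
    )
    visits = pd.read_csv(
        visit_table_path, dtype={"patient_id": str}, float_precision="round_trip"
    )

    if "dsa_positive" in patients.columns:
        patients["dsa_positive"] = _coerce_bool(patients["dsa_positive"])
    if "hla_mismatch" in patients.columns:
        patients["hla_mismatch"] = pd.to_numeric(patients["hla_mismatch"]).astype("Float64")
    for col in BOOL_VISIT_COLUMNS:
        if col in visits.columns:
            visits[col] = _coerce_bool(visits[col])

    validate_cohort(patients, visits)
    visits = visits.copy()
    visits["month_index"] = visits["month_index"].astype(int)
    visits["ttv_log10"] = _derive_ttv_log10(visits["ttv_raw"].astype(float))
    return Cohort(patients=patients.reset_index(drop=True), visits=visits.reset_index(drop=True))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``patients.csv`` and ``visits.csv`` under ``out_dir``.

    The derived ``ttv_log10`` column is dropped; booleans are stored as 0/1
    with missing flags left empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p_path = out_dir / "patients.csv"
    v_path = out_dir / "visits.csv"

    # No float_format: pandas writes shortest round-trip reprs, so writing
    # and re-reading a cohort is the identity.
    patients = cohort.patients.copy()
    if str(patients["dsa_positive"].dtype) == "boolean":
        patients["dsa_positive"] = patients["dsa_positive"].astype("Int64")
    patients.to_csv(p_path, index=False)

    visits = cohort.visits.drop(columns=["ttv_log10"], errors="ignore").copy()
    for col in BOOL_VISIT_COLUMNS:
        visits[col] = visits[col].astype("boolean").astype("Int64")
    visits.to_csv(v_path, index=False)
    return p_path, v_path


def write_results(results: Iterable, out_dir: str | Path) -> dict[str, Path]:
    """Write association / correlation / mixed-model results as CSV tables.

    One file per result family, rows sorted by variable (outcome) name, all
    floats at nine significant digits so identical results produce
    byte-identical files.
    """
    from .associations import AssociationResult
    from .repeated_correlation import CorrelationResult
    from .mixed_logit import MixedLogitResult

    results = list(results)
    if not results:
        raise ValueError("empty result collection: nothing to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    assoc = [r for r in results if isinstance(r, AssociationResult)]
    corr = [r for r in results if isinstance(r, CorrelationResult)]
    mixed = [r for r in results if isinstance(r, MixedLogitResult)]
    stray = [r for r in results if not isinstance(r, (AssociationResult, CorrelationResult, MixedLogitResult))]
    if stray:
        raise TypeError(f"unsupported result object: {stray[0]!r}")

    written: dict[str, Path] = {}
    if assoc:
        df = pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "family": r.family,
                    "statistic": r.statistic,
                    "effect": r.effect_label(),
                    "p_value": r.p_value,
                    "n": r.n,
                }
                for r in sorted(assoc, key=lambda r: r.variable)
            ]
        )
        path = out_dir / "table2_associations.csv"
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written["associations"] = path
    if corr:
        df = pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "mean_rho": r.mean_rho,
                    "p_value": r.p_value,
                    "n_patients": r.n_patients,
                    "n_permutations": r.n_permutations,
                    "seed": r.seed,
                }
                for r in sorted(corr, key=lambda r: r.variable)
            ]
        )
        path = out_dir / "table3_correlations.csv"
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written["correlations"] = path
    if mixed:
        df = pd.DataFrame(
            [
                {
                    "outcome": r.outcome,
                    "or_estimate": r.or_estimate,
                    "or_lower": r.or_lower,
                    "or_upper": r.or_upper,
                    "p_value": r.p_value,
                    "sigma_u": r.sigma_u,
                    "n_obs": r.n_obs,
                    "n_patients": r.n_patients,
                    "converged": r.converged,
                }
                for r in sorted(mixed, key=lambda r: r.outcome)
            ]
        )
        path = out_dir / "table4_mixed_logit.csv"
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written["mixed_logit"] = path
    return written
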