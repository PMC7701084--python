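"""Patient-level association tests of mean log10 TTV against fixed covariates.

Categorical covariates are tested by classical one-way fixed-effects ANOVA
(for two groups this is equivalent to the pooled-variance t test);
continuous covariates by ordinary least-squares simple linear regression
with a t test on the slope.  No covariate adjustment and no multiple-testing
correction are applied: the tests are descriptive and hypothesis-generating.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import summarize_cohort

__all__ = [
    "AssociationResult",
    "one_way_anova",
    "simple_linear_regression",
    "run_association_table",
    "ASSOCIATION_VARIABLES",
]


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    variable: str
    family: str            # "anova" or "linear_regression"
    statistic: float       # F, or the slope t statistic
    effect: tuple          # group means (anova) or (slope,) (regression)
    p_value: float
    n: int                 # patients with a non-missing covariate

    def effect_label(self) -> str:
        return ";".join(f"{v:.6g}" for v in self.effect)


def one_way_anova(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    variable: str = "",
) -> AssociationResult:
    """Classical one-way fixed-effects ANOVA on per-patient mean TTV.

    Groups that are empty after missing-data removal are dropped with a
    warning; fewer than two surviving groups is an error.  When there is no
    between-group variance the F statistic is 0 and p is 1, even if the
    within-group variance is also zero.
    """
    if isinstance(groups, Mapping):
        items = [(str(k), np.asarray(v, dtype=float)) for k, v in groups.items()]
    else:
        items = [(str(i), np.asarray(v, dtype=float)) for i, v in enumerate(groups)]
    items = [(k, v[~np.isnan(v)]) for k, v in items]
    dropped = [k for k, v in items if v.size == 0]
    if dropped:
        warnings.warn(f"dropping empty groups from ANOVA: {dropped}", stacklevel=2)
    items = [(k, v) for k, v in items if v.size > 0]
    if len(items) < 2:
        raise ValueError("one-way ANOVA needs at least two non-empty groups")

    k = len(items)
    n = sum(v.size for _, v in items)
    if n <= k:
        raise ValueError(f"ANOVA needs more observations ({n}) than groups ({k})")
    grand = np.concatenate([v for _, v in items]).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for _, v in items)
    ss_within = sum(((v - v.mean()) ** 2).sum() for _, v in items)
    df_b, df_w = k - 1, n - k

    if ss_between == 0.0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0.0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    return AssociationResult(
        variable=variable,
        family="anova",
        statistic=float(f_stat),
        effect=tuple(float(v.mean()) for _, v in items),
        p_value=p,
        n=n,
    )


def simple_linear_regression(
    x: Sequence[float], y: Sequence[float], variable: str = ""
) -> AssociationResult:
    """OLS of per-patient mean TTV on a continuous covariate.

    Two-sided p for the slope from the t distribution with n−2 df.  An
    exact fit (zero residual variance) yields p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"linear regression needs >= 3 complete pairs, got {n}")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0.0:
        raise ValueError("covariate is constant; slope is not identifiable")
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    sigma2 = (resid**2).sum() / (n - 2)
    if sigma2 == 0.0:
        t_stat, p = np.inf if slope > 0 else (-np.inf if slope < 0 else 0.0), 0.0
        if slope == 0.0:
            p = 1.0
    else:
        se = np.sqrt(sigma2 / sxx)
        t_stat = slope / se
        p = float(2.0 * stats.t.sf(abs(t_stat), n - 2))
    return AssociationResult(
        variable=variable,
        family="linear_regression",
        statistic=float(t_stat),
        effect=(float(slope),),
        p_value=p,
        n=n,
    )


# (variable name, family, column builder). "anova" columns are grouping
# labels; "linear_regression" columns are numeric.
ASSOCIATION_VARIABLES = [
    ("gender", "anova"),
    ("primary_disease", "anova"),
    ("donation_type", "anova"),
    ("dsa_positive", "anova"),
    ("is_intensity", "anova"),       # dual vs triple immunosuppression
    ("regimen_class", "anova"),      # CNI- vs mTORi-based maintenance
    ("age_at_study_start", "linear_regression"),
    ("age_at_transplant", "linear_regression"),
    ("post_transplant_time", "linear_regression"),
    ("hla_mismatch", "linear_regression"),
]


def _derived_columns(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table["is_intensity"] = np.where(
        table["antiproliferative"].astype(str) == "none", "dual", "triple"
    )
    table["regimen_class"] = np.where(
        table["cni_or_mtori"].astype(str) == "rapamycin", "mTORi", "CNI"
    )
    return table


def run_association_table(
    cohort, mismatch_as: str = "continuous"
) -> list[AssociationResult]:
    """Run the full patient-level association screen.

    ``mismatch_as`` switches the HLA mismatch count between regression
    (default) and ANOVA treatment.  Variables that cannot be tested on the
    given cohort (too few patients or groups) are skipped with a warning;
    if nothing is testable an error is raised.
    """
    table = _derived_columns(summarize_cohort(cohort))
    results: list[AssociationResult] = []
    for variable, family in ASSOCIATION_VARIABLES:
        if variable == "hla_mismatch" and mismatch_as == "categorical":
            family = "anova"
        sub = table[[variable, "mean_ttv_log10"]].dropna()
        try:
            if family == "anova":
                groups = {
                    str(level): grp["mean_ttv_log10"].to_numpy()
                    for level, grp in sub.groupby(variable, sort=True)
                }
                results.append(one_way_anova(groups, variable=variable))
            else:
                results.append(
                    simple_linear_regression(
                        sub[variable].astype(float).to_numpy(),
                        sub["mean_ttv_log10"].to_numpy(),
                        variable=variable,
                    )
                )
        except ValueError as exc:
            warnings.warn(f"skipping {variable}: {exc}", stacklevel=2)
    if not results:
        raise ValueError("no association test could be run on this cohort")
    return results
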