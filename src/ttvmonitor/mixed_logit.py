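"""Random-intercept logistic regression fitted by maximum marginal likelihood.

The model for a binary monthly outcome y_ij of patient i at visit j with
log10 TTV load x_ij is

    y_ij | u_i  ~  Bernoulli( logit^-1( alpha + beta * x_ij + u_i ) ),
    u_i  ~  Normal(0, sigma_u^2),

with a single fixed effect (the viral load) and a patient-specific random
intercept capturing within-patient clustering of events.  The patient
random effects are integrated out by Gauss-Hermite quadrature (optionally
adaptive, i.e. recentred per patient at the mode of the integrand), and
(alpha, beta, log sigma_u) is found by quasi-Newton maximisation of the
marginal log-likelihood.  Standard errors come from the inverse of the
finite-difference observed information; the 95% confidence interval for the
odds ratio is Wald on the log-odds scale, exp(beta +/- 1.96 * SE).

Everything here is written against numpy/scipy primitives only; no external
mixed-model fitter is involved.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_expit, expit, logsumexp, roots_hermitenorm

from .preprocessing import lagged_outcome_table

__all__ = [
    "QuadratureSpec",
    "MixedLogitResult",
    "fit_random_intercept_logit",
    "run_event_models",
    "plain_logistic_newton",
    "EVENT_OUTCOMES",
]

_Z975 = 1.96
_SIGMA_BOUNDARY = 1e-4


@dataclasses.dataclass(frozen=True)
class QuadratureSpec:
    """Gauss-Hermite rule for integrating out the random intercept.

    An odd node count keeps a node at the centre; ``adaptive`` recentres and
    rescales the rule per patient at the Laplace mode of the integrand.
    """

    n_nodes: int = 21
    adaptive: bool = False

    def __post_init__(self):
        if self.n_nodes < 5:
            raise ValueError("quadrature needs at least 5 nodes")


@dataclasses.dataclass(frozen=True)
class MixedLogitResult:
    outcome: str
    beta: float            # log-odds per log10 TTV
    se_beta: float
    or_estimate: float
    or_lower: float
    or_upper: float
    p_value: float
    sigma_u: float
    intercept: float
    n_obs: int
    n_patients: int
    converged: bool
    message: str = ""

    @classmethod
    def not_fitted(cls, outcome: str, reason: str, n_obs: int = 0, n_patients: int = 0):
        nan = float("nan")
        return cls(
            outcome=outcome, beta=nan, se_beta=nan, or_estimate=nan,
            or_lower=nan, or_upper=nan, p_value=nan, sigma_u=nan,
            intercept=nan, n_obs=n_obs, n_patients=n_patients,
            converged=False, message=reason,
        )


def plain_logistic_newton(
    x: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[float, float, np.ndarray]:
    """Ordinary logistic MLE (intercept + one slope) by Newton-Raphson.

    Returns (alpha, beta, covariance).  Raises on apparent separation
    (unbounded likelihood, coefficients diverging).
    """
    X = np.column_stack([np.ones_like(x), x])
    theta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ theta
        p = expit(eta)
        grad = X.T @ (y - p)
        w = p * (1 - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(f"singular information matrix: {exc}") from exc
        theta = theta + step
        if np.max(np.abs(theta)) > 50:
            raise FloatingPointError("coefficients diverging: quasi-complete separation")
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ theta
    w = expit(eta) * (1 - expit(eta))
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return float(theta[0]), float(theta[1]), cov


class _MarginalLikelihood:
    """Marginal log-likelihood of the random-intercept logistic model.

    Observations are sorted by patient; per-patient sums use reduceat over
    the (observation x node) matrix.
    """

    def __init__(self, patient_ids, x, y, quad: QuadratureSpec):
        order = np.argsort(patient_ids, kind="stable")
        self.x = np.asarray(x, dtype=float)[order]
        self.y = np.asarray(y, dtype=float)[order]
        ids = np.asarray(patient_ids)[order]
        change = np.flatnonzero(np.r_[True, ids[1:] != ids[:-1]])
        self.starts = change
        self.counts = np.diff(np.r_[change, ids.size])
        self.n_patients = change.size
        self.quad = quad
        nodes, weights = roots_hermitenorm(quad.n_nodes)
        self.nodes = nodes                       # integrate against exp(-z^2/2)
        self.log_w = np.log(weights)
        self.sign = 2.0 * self.y - 1.0

    def _loglik_nonadaptive(self, alpha, beta, sigma):
        eta = alpha + beta * self.x                       # (n_obs,)
        arg = self.sign[:, None] * (eta[:, None] + sigma * self.nodes[None, :])
        per_obs = log_expit(arg)                          # (n_obs, K)
        per_patient = np.add.reduceat(per_obs, self.starts, axis=0)
        ll_i = logsumexp(self.log_w[None, :] + per_patient, axis=1)
        return float(np.sum(ll_i) - self.n_patients * 0.5 * math.log(2 * math.pi))

    def _modes(self, alpha, beta, sigma):
        """Laplace mode and curvature of the per-patient integrand."""
        eta = alpha + beta * self.x
        u = np.zeros(self.n_patients)
        for _ in range(25):
            uu = np.repeat(u, self.counts)
            p = expit(eta + uu)
            grad = np.add.reduceat(self.y - p, self.starts) - u / sigma**2
            curv = np.add.reduceat(p * (1 - p), self.starts) + 1.0 / sigma**2
            step = grad / curv
            u = u + step
            if np.max(np.abs(step)) < 1e-10:
                break
        uu = np.repeat(u, self.counts)
        p = expit(eta + uu)
        curv = np.add.reduceat(p * (1 - p), self.starts) + 1.0 / sigma**2
        return u, 1.0 / np.sqrt(curv)

    def _loglik_adaptive(self, alpha, beta, sigma):
        u_hat, tau = self._modes(alpha, beta, sigma)
        eta = alpha + beta * self.x
        u_nodes = u_hat[:, None] + tau[:, None] * self.nodes[None, :]   # (P, K)
        uu = np.repeat(u_nodes, self.counts, axis=0)                    # (n_obs, K)
        per_obs = log_expit(self.sign[:, None] * (eta[:, None] + uu))
        per_patient = np.add.reduceat(per_obs, self.starts, axis=0)
        log_phi = -0.5 * (u_nodes / sigma) ** 2 - math.log(sigma) - 0.5 * math.log(2 * math.pi)
        h = per_patient + log_phi
        ll_i = np.log(tau) + logsumexp(
            self.log_w[None, :] + h + 0.5 * self.nodes[None, :] ** 2, axis=1
        )
        return float(np.sum(ll_i))

    def loglik(self, alpha, beta, sigma):
        if sigma <= 0:
            sigma = 1e-12
        if self.quad.adaptive:
            return self._loglik_adaptive(alpha, beta, sigma)
        return self._loglik_nonadaptive(alpha, beta, sigma)

    def nll_logsigma(self, theta):
        alpha, beta, log_sigma = theta
        return -self.loglik(alpha, beta, math.exp(log_sigma))

    def nll_sigma(self, theta):
        alpha, beta, sigma = theta
        return -self.loglik(alpha, beta, abs(sigma))


def _fd_hessian(fun, theta, rel_step=1e-4):
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    h = rel_step * (1.0 + np.abs(theta))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            val = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    return hess


def fit_random_intercept_logit(
    pairs: pd.DataFrame,
    quad: QuadratureSpec | None = None,
    outcome_name: str = "outcome",
    ci_method: str = "wald",
) -> MixedLogitResult:
    """Fit the random-intercept logistic model to (patient, x, y) rows.

    ``pairs`` needs columns ``patient_id``, ``ttv_log10`` and ``outcome``
    (0/1).  Requires at least two patients and both outcome classes present
    overall.  When the random-intercept SD collapses to the boundary
    (< 1e-4) the model is refitted as a plain logistic regression, which is
    the exact sigma_u = 0 sub-model.  Apparent quasi-complete separation is
    reported via ``converged=False`` with a diagnostic message rather than a
    numeric answer.

    ``ci_method`` is ``"wald"`` (default) or ``"profile"`` for a
    profile-likelihood interval on the odds ratio.
    """
    quad = quad or QuadratureSpec()
    df = pairs.dropna(subset=["ttv_log10", "outcome"])
    n_obs = len(df)
    ids = df["patient_id"].to_numpy()
    n_patients = len(pd.unique(ids))
    if n_patients < 2:
        raise ValueError("random-intercept model needs >= 2 patients")
    y = df["outcome"].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError(
            f"outcome {outcome_name!r} has a single class; model not identifiable"
        )
    x = df["ttv_log10"].astype(float).to_numpy()

    try:
        alpha0, beta0, cov0 = plain_logistic_newton(x, y)
    except FloatingPointError as exc:
        return MixedLogitResult.not_fitted(
            outcome_name, f"separation in initial logistic fit: {exc}", n_obs, n_patients
        )

    ml = _MarginalLikelihood(ids, x, y, quad)
    if ml.counts.max() == 1:
        # One observation per patient: sigma_u is confounded with the link
        # scale, so it is profiled at the boundary and the model reduces
        # exactly to ordinary logistic regression.
        se0 = float(np.sqrt(cov0[1, 1]))
        lo0, hi0 = beta0 - _Z975 * se0, beta0 + _Z975 * se0
        return MixedLogitResult(
            outcome=outcome_name, beta=beta0, se_beta=se0,
            or_estimate=float(math.exp(beta0)), or_lower=float(math.exp(lo0)),
            or_upper=float(math.exp(hi0)),
            p_value=float(2.0 * stats.norm.sf(abs(beta0 / se0))),
            sigma_u=0.0, intercept=alpha0, n_obs=n_obs, n_patients=n_patients,
            converged=True,
            message="one observation per patient: sigma_u unidentifiable, profiled at 0",
        )
    theta0 = np.array([alpha0, beta0, math.log(0.5)])
    res = optimize.minimize(
        ml.nll_logsigma,
        theta0,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    alpha, beta, log_sigma = res.x
    sigma = math.exp(log_sigma)

    if abs(beta) > 30 or abs(alpha) > 30:
        return MixedLogitResult.not_fitted(
            outcome_name, "coefficients diverging: quasi-complete separation",
            n_obs, n_patients,
        )

    if sigma < _SIGMA_BOUNDARY:
        # Boundary solution: the sigma_u = 0 sub-model is plain logistic.
        alpha, beta, cov = plain_logistic_newton(x, y)
        sigma = 0.0
        se_beta = float(np.sqrt(cov[1, 1]))
        converged = True
        message = "sigma_u at boundary; refitted as plain logistic"
    else:
        hess = _fd_hessian(ml.nll_sigma, np.array([alpha, beta, sigma]))
        try:
            cov = np.linalg.inv(hess)
            se_beta = float(np.sqrt(cov[1, 1]))
            converged = bool(res.success)
            message = "" if converged else str(res.message)
        except (np.linalg.LinAlgError, ValueError):
            se_beta = float("nan")
            converged = False
            message = "observed information not invertible"
        if not np.isfinite(se_beta):
            converged = False
            message = message or "non-finite standard error"

    if np.isfinite(se_beta) and se_beta > 0:
        z = beta / se_beta
        p_value = float(2.0 * stats.norm.sf(abs(z)))
        lo, hi = beta - _Z975 * se_beta, beta + _Z975 * se_beta
        if ci_method == "profile":
            lo, hi = _profile_ci(ml, alpha, beta, sigma, lo, hi)
        elif ci_method != "wald":
            raise ValueError(f"unknown ci_method {ci_method!r}")
    else:
        p_value, lo, hi = float("nan"), float("nan"), float("nan")

    return MixedLogitResult(
        outcome=outcome_name,
        beta=float(beta),
        se_beta=se_beta,
        or_estimate=float(math.exp(beta)),
        or_lower=float(math.exp(lo)),
        or_upper=float(math.exp(hi)),
        p_value=p_value,
        sigma_u=float(sigma),
        intercept=float(alpha),
        n_obs=n_obs,
        n_patients=n_patients,
        converged=converged,
        message=message,
    )


def _profile_ci(ml, alpha_hat, beta_hat, sigma_hat, wald_lo, wald_hi, level=0.95):
    """Profile-likelihood CI for beta by inverting the deviance at 3.84."""
    crit = stats.chi2.ppf(level, 1) / 2.0
    ll_max = ml.loglik(alpha_hat, beta_hat, max(sigma_hat, 1e-8))
    log_sigma0 = math.log(max(sigma_hat, 1e-8))

    def profile_deficit(beta_fixed):
        res = optimize.minimize(
            lambda t: -ml.loglik(t[0], beta_fixed, math.exp(t[1])),
            np.array([alpha_hat, log_sigma0]),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400},
        )
        return (ll_max - (-res.fun)) - crit

    width = max(wald_hi - beta_hat, 1e-3)

    def bracket(direction):
        step = width
        for _ in range(40):
            candidate = beta_hat + direction * step
            if profile_deficit(candidate) > 0:
                return candidate
            step *= 1.6
        return beta_hat + direction * step

    hi = optimize.brentq(profile_deficit, beta_hat, bracket(+1), xtol=1e-6)
    lo = optimize.brentq(profile_deficit, bracket(-1), beta_hat, xtol=1e-6)
    return lo, hi


# Outcome name -> how to build (patient_id, ttv_log10, outcome) rows.
EVENT_OUTCOMES = ["infection", "infection_next_month", "fever", "nonadherence"]

_SAME_MONTH_FLAG = {
    "infection": "infection",
    "fever": "febrile_infection",
    "nonadherence": "nonadherence_suspected",
}


def _outcome_pairs(cohort, outcome: str) -> pd.DataFrame:
    if outcome == "infection_next_month":
        return lagged_outcome_table(cohort, "infection")
    flag = _SAME_MONTH_FLAG[outcome]
    df = cohort.visits[["patient_id", "ttv_log10", flag]].dropna()
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"].to_numpy(),
            "ttv_log10": df["ttv_log10"].astype(float).to_numpy(),
            "outcome": df[flag].astype(bool).astype(int).to_numpy(),
        }
    )


def run_event_models(cohort, quad: QuadratureSpec | None = None) -> list[MixedLogitResult]:
    """The four event models: same-month infection, next-month infection,
    febrile infection and suspected non-adherence, each with the log10 TTV
    load as the single fixed effect.

    An outcome with a single observed class is reported as not fitted with
    the reason; the remaining models still run.  Fitting is deterministic:
    identical cohorts give identical results.
    """
    quad = quad or QuadratureSpec()
    results = []
    for outcome in EVENT_OUTCOMES:
        pairs = _outcome_pairs(cohort, outcome)
        try:
            results.append(fit_random_intercept_logit(pairs, quad, outcome_name=outcome))
        except ValueError as exc:
            results.append(
                MixedLogitResult.not_fitted(
                    outcome, str(exc), n_obs=len(pairs),
                    n_patients=pairs["patient_id"].nunique() if len(pairs) else 0,
                )
            )
    return results
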