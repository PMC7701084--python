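"""Random-intercept logistic regression: reductions, quadrature accuracy,
independent-oracle agreement and model-battery behaviour."""

import math
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.special import log_expit

from ttvmonitor import (
    GeneratorConfig,
    QuadratureSpec,
    fit_random_intercept_logit,
    generate_cohort,
    run_event_models,
)
from ttvmonitor.mixed_logit import _MarginalLikelihood, plain_logistic_newton


def _simulate_pairs(n_patients, n_per_patient, alpha, beta, sigma_u, seed):
    rng = np.random.default_rng(seed)
    ids = np.repeat([f"p{i}" for i in range(n_patients)], n_per_patient)
    x = rng.normal(5.0, 1.5, n_patients * n_per_patient)
    u = np.repeat(rng.normal(0.0, sigma_u, n_patients), n_per_patient)
    p = 1.0 / (1.0 + np.exp(-(alpha + beta * x + u)))
    y = (rng.random(x.size) < p).astype(int)
    return pd.DataFrame({"patient_id": ids, "ttv_log10": x, "outcome": y})


class TestReductionToPlainLogistic:
    def test_one_observation_per_patient_matches_newton_oracle(self):
        pairs = _simulate_pairs(300, 1, -2.0, 0.4, 0.0, seed=2)
        res = fit_random_intercept_logit(pairs)
        # independent oracle: statsmodels Newton logistic fit
        sm = pytest.importorskip("statsmodels.api")
        X = sm.add_constant(pairs["ttv_log10"].to_numpy())
        fit = sm.Logit(pairs["outcome"].to_numpy(), X).fit(disp=False, method="newton")
        assert res.sigma_u == 0.0
        assert res.beta == pytest.approx(fit.params[1], abs=1e-6)
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-6)
        assert res.se_beta == pytest.approx(fit.bse[1], rel=1e-4)

    def test_own_newton_matches_statsmodels(self):
        pairs = _simulate_pairs(100, 3, -1.0, 0.3, 0.0, seed=5)
        sm = pytest.importorskip("statsmodels.api")
        a, b, cov = plain_logistic_newton(
            pairs["ttv_log10"].to_numpy(), pairs["outcome"].to_numpy(dtype=float)
        )
        X = sm.add_constant(pairs["ttv_log10"].to_numpy())
        fit = sm.Logit(pairs["outcome"].to_numpy(), X).fit(disp=False, method="newton")
        assert b == pytest.approx(fit.params[1], abs=1e-8)
        assert math.sqrt(cov[1, 1]) == pytest.approx(fit.bse[1], rel=1e-6)


class TestQuadrature:
    @staticmethod
    def _small_instance():
        pairs = _simulate_pairs(8, 6, -1.0, 0.3, 1.0, seed=3)
        ids = pairs["patient_id"].to_numpy()
        x = pairs["ttv_log10"].to_numpy()
        y = pairs["outcome"].to_numpy(dtype=float)
        return ids, x, y

    @staticmethod
    def _brute_force_loglik(ids, x, y, alpha, beta, sigma):
        total = 0.0
        for pid in np.unique(ids):
            m = ids == pid
            eta = alpha + beta * x[m]
            u = np.linspace(-8 * sigma, 8 * sigma, 40_001)
            ll_obs = np.sum(
                log_expit((2 * y[m] - 1)[:, None] * (eta[:, None] + u[None, :])), axis=0
            )
            dens = np.exp(ll_obs - 0.5 * (u / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
            total += math.log(np.trapezoid(dens, u))
        return total

    # The plain rule is accurate in the sigma_u range the event models see
    # (< ~1.2); the adaptive rule stays accurate for diffuse intercepts too.
    @pytest.mark.parametrize(
        "adaptive, params",
        [
            (False, [(-1.0, 0.3, 1.0), (0.5, -0.2, 0.6)]),
            (True, [(-1.0, 0.3, 1.0), (0.5, -0.2, 0.6), (-2.0, 0.5, 1.8)]),
        ],
    )
    def test_marginal_loglik_matches_fine_trapezoid(self, adaptive, params):
        ids, x, y = self._small_instance()
        ml = _MarginalLikelihood(ids, x, y, QuadratureSpec(21, adaptive=adaptive))
        for alpha, beta, sigma in params:
            exact = self._brute_force_loglik(ids, x, y, alpha, beta, sigma)
            approx = ml.loglik(alpha, beta, sigma)
            n_patients = len(np.unique(ids))
            assert abs(approx - exact) / n_patients < 1e-6

    def test_node_count_converged_beyond_15(self):
        pairs = _simulate_pairs(40, 8, -1.0, 0.4, 1.0, seed=11)
        betas = {
            n: fit_random_intercept_logit(pairs, QuadratureSpec(n)).beta
            for n in (15, 21, 31)
        }
        assert abs(betas[21] - betas[15]) < 1e-4
        assert abs(betas[31] - betas[21]) < 1e-4


class TestFit:
    def test_wald_ci_symmetric_on_log_odds_scale(self):
        pairs = _simulate_pairs(60, 8, -1.0, 0.3, 0.8, seed=7)
        res = fit_random_intercept_logit(pairs)
        upper = math.log(res.or_upper) - res.beta
        lower = res.beta - math.log(res.or_lower)
        assert upper == pytest.approx(lower, abs=1e-10)
        assert res.or_lower <= res.or_estimate <= res.or_upper
        assert res.or_estimate == pytest.approx(math.exp(res.beta))

    def test_single_class_outcome_rejected(self):
        pairs = _simulate_pairs(20, 5, -1.0, 0.3, 0.5, seed=9)
        pairs["outcome"] = 0
        with pytest.raises(ValueError, match="single class"):
            fit_random_intercept_logit(pairs)

    def test_separation_reported_not_crashed(self):
        pairs = _simulate_pairs(30, 4, 0.0, 0.0, 0.0, seed=13)
        pairs["outcome"] = (pairs["ttv_log10"] > 5.0).astype(int)  # perfect split
        res = fit_random_intercept_logit(pairs)
        assert not res.converged
        assert "separation" in res.message

    def test_agrees_with_lme4_glmer(self):
        # independent cross-check against R's adaptive-quadrature fitter
        pairs = _simulate_pairs(40, 8, -1.5, 0.4, 1.0, seed=21)
        res = fit_random_intercept_logit(pairs, QuadratureSpec(25, adaptive=True))
        with tempfile.TemporaryDirectory() as d:
            csv = Path(d) / "pairs.csv"
            pairs.to_csv(csv, index=False)
            script = (
                "suppressMessages(library(lme4));"
                f"d <- read.csv('{csv}');"
                "f <- glmer(outcome ~ ttv_log10 + (1|patient_id), data=d,"
                " family=binomial, nAGQ=25);"
                "cat(fixef(f)[2], sqrt(unlist(VarCorr(f))[1]), sep='\\n')"
            )
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, check=True
            )
        r_beta, r_sigma = map(float, out.stdout.strip().splitlines())
        assert res.beta == pytest.approx(r_beta, abs=5e-3)
        assert res.sigma_u == pytest.approx(r_sigma, abs=5e-3)

    def test_profile_ci_close_to_wald_in_regular_problem(self):
        pairs = _simulate_pairs(80, 8, -1.0, 0.3, 0.8, seed=17)
        wald = fit_random_intercept_logit(pairs, ci_method="wald")
        prof = fit_random_intercept_logit(pairs, ci_method="profile")
        assert math.log(prof.or_lower) == pytest.approx(math.log(wald.or_lower), abs=0.05)
        assert math.log(prof.or_upper) == pytest.approx(math.log(wald.or_upper), abs=0.05)


class TestEventModels:
    def test_zero_febrile_events_marked_not_fitted(self):
        cfg = GeneratorConfig(febrile_given_infection=0.0, seed=31)
        cohort = generate_cohort(cfg)
        results = {r.outcome: r for r in run_event_models(cohort)}
        assert set(results) == {"infection", "infection_next_month", "fever", "nonadherence"}
        assert not results["fever"].converged
        assert "single class" in results["fever"].message
        for name in ("infection", "infection_next_month", "nonadherence"):
            assert results[name].converged

    def test_deterministic_given_cohort(self, default_cohort):
        a = run_event_models(default_cohort)
        b = run_event_models(default_cohort)
        assert a == b

    def test_injected_infection_slope_recovered(self):
        cfg = GeneratorConfig(
            n_patients=400, infection_beta=0.3, infection_sigma_u=0.8, seed=37
        )
        cohort = generate_cohort(cfg)
        results = {r.outcome: r for r in run_event_models(cohort)}
        res = results["infection"]
        # OR should be near e^0.3 ~ 1.35, within the model's own CI
        assert res.or_lower < math.exp(0.3) < res.or_upper
        assert res.beta == pytest.approx(0.3, abs=3 * res.se_beta)
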