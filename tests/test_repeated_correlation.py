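"""Per-patient Spearman correlation and the within-patient permutation test."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ttvmonitor import (
    GeneratorConfig,
    generate_cohort,
    mean_correlation_permutation_test,
    per_patient_correlations,
    spearman_rho,
)


class TestSpearmanRho:
    def test_perfect_concordance_and_discordance(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_pearson_on_hand_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        y = [5.0, 5.0, 7.0, 8.0, 9.0, 9.0]
        rx = [1.0, 2.5, 2.5, 4.0, 5.5, 5.5]
        ry = [1.5, 1.5, 3.0, 4.0, 5.5, 5.5]
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, abs=1e-15)

    def test_degenerate_inputs_signalled_as_nan(self):
        assert np.isnan(spearman_rho([1, 2], [3, 4]))
        assert np.isnan(spearman_rho([2, 2, 2], [1, 2, 3]))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, 3 * y + 1) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, -y) == pytest.approx(-base, abs=1e-12)


class TestPerPatientCorrelations:
    def test_values_in_range(self, default_cohort):
        rhos = per_patient_correlations(default_cohort, "egfr")
        assert rhos and all(-1.0 <= r <= 1.0 for r in rhos.values())

    def test_constant_series_patient_excluded(self, default_cohort):
        cohort = dataclasses.replace(
            default_cohort, visits=default_cohort.visits.copy()
        )
        pid = cohort.visits["patient_id"].iloc[0]
        cohort.visits.loc[cohort.visits["patient_id"] == pid, "prednisolone_dose"] = 8.0
        rhos = per_patient_correlations(cohort, "prednisolone_dose")
        assert pid not in rhos

    def test_drug_specific_variable_limited_to_patients_on_drug(self, default_cohort):
        n_rapa = (default_cohort.patients["cni_or_mtori"] == "rapamycin").sum()
        if n_rapa == 0:
            with pytest.raises(ValueError, match="rapamycin_dose"):
                per_patient_correlations(default_cohort, "rapamycin_dose")
        else:
            rhos = per_patient_correlations(default_cohort, "rapamycin_dose")
            assert len(rhos) <= n_rapa


class TestPermutationTest:
    def test_covariate_identical_to_load_gives_maximal_statistic(self, default_cohort):
        cohort = dataclasses.replace(
            default_cohort, visits=default_cohort.visits.copy()
        )
        cohort.visits["egfr"] = cohort.visits["ttv_log10"]
        # constant-load patients (all undetectable) drop out automatically
        res = mean_correlation_permutation_test(cohort, "egfr", n_permutations=500, seed=0)
        assert res.mean_rho == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_sampled_p_matches_exhaustive_enumeration(self, tiny_cohort):
        cohort, _ = tiny_cohort
        res = mean_correlation_permutation_test(
            cohort, "prednisolone_dose", n_permutations=10_000, seed=42
        )
        stats_all = []
        per_patient = [cohort.visits_for(p) for p in cohort.patients["patient_id"]]
        xs = [v["ttv_log10"].to_numpy() for v in per_patient]
        ys = [v["prednisolone_dose"].to_numpy() for v in per_patient]
        for p1 in itertools.permutations(range(3)):
            for p2 in itertools.permutations(range(3)):
                r1 = spearman_rho(xs[0], ys[0][list(p1)])
                r2 = spearman_rho(xs[1], ys[1][list(p2)])
                stats_all.append(0.5 * (r1 + r2))
        stats_all = np.asarray(stats_all)
        p_exact = np.mean(np.abs(stats_all) >= abs(res.mean_rho) - 1e-12)
        se = np.sqrt(p_exact * (1 - p_exact) / res.n_permutations)
        assert abs(res.p_value - p_exact) <= 3 * se

    def test_bit_reproducible_given_seed(self, default_cohort):
        a = mean_correlation_permutation_test(default_cohort, "egfr", 300, seed=9)
        b = mean_correlation_permutation_test(default_cohort, "egfr", 300, seed=9)
        assert a == b

    def test_p_value_floor(self, dose_cohort):
        cohort, _ = dose_cohort
        res = mean_correlation_permutation_test(
            cohort, "prednisolone_dose", n_permutations=99, seed=1
        )
        assert res.p_value >= 1.0 / (99 + 1)
        assert res.n_patients == len(res.per_patient_rho)
        assert res.mean_rho == pytest.approx(np.mean(list(res.per_patient_rho.values())))

    def test_null_rejection_rate_controlled(self):
        # small-scale validity check; the full-size run lives in the
        # acceptance suite
        alphas = (0.01, 0.05, 0.10)
        n_reps = 200
        rng = np.random.default_rng(123)
        rejections = {a: 0 for a in alphas}
        for _ in range(n_reps):
            cfg = GeneratorConfig(
                n_patients=20, dose_corr_target=0.0, seed=int(rng.integers(2**31))
            )
            cohort = generate_cohort(cfg)
            res = mean_correlation_permutation_test(
                cohort, "prednisolone_dose", n_permutations=100,
                seed=int(rng.integers(2**31)),
            )
            for a in alphas:
                rejections[a] += res.p_value <= a
        for a in alphas:
            se = np.sqrt(a * (1 - a) / n_reps)
            assert rejections[a] / n_reps <= a + 3 * se

    def test_power_at_study_scale(self):
        # 45 patients x 12 months with a 0.25 within-patient coupling: the
        # test is essentially certain to reject (frozen regression value:
        # 200/200 rejections at alpha = 0.05)
        from ttvmonitor.simulations import permutation_rejection_rate

        res = permutation_rejection_rate(
            60, dose_corr_target=0.25, alpha=0.05, n_permutations=200, seed=777
        )
        assert res["rate"] > 0.5
        assert res["rate"] >= 0.95  # regression: observed power is ~1.0

    def test_injected_correlation_detected(self, dose_cohort):
        cohort, truth = dose_cohort
        res = mean_correlation_permutation_test(
            cohort, "prednisolone_dose", n_permutations=2000, seed=3
        )
        assert res.mean_rho == pytest.approx(truth["dose_corr_target"], abs=0.15)
        assert res.p_value < 0.05
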