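"""The viral-load transform, Schwartz eGFR, patient summaries and lag pairs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttvmonitor import (
    build_lagged_pairs,
    log10_viral_load,
    prevalence_percent,
    schwartz_egfr,
    summarize_patient,
)


class TestLog10ViralLoad:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (0.0, 0.0),            # undetectable: set to 1 before the transform
            (1.0, 0.0),
            (100.0, 2.0),
            (630_957, math.log10(630_957)),  # ~5.8
        ],
    )
    def test_values(self, raw, expected):
        assert log10_viral_load(raw) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("raw", [-1.0, 0.5])
    def test_domain_errors(self, raw):
        with pytest.raises(ValueError):
            log10_viral_load(raw)

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(min_value=1.0, max_value=1e10)),
            min_size=2,
            max_size=30,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_on_domain(self, raws):
        raws = sorted(raws)
        out = log10_viral_load(np.array(raws))
        assert np.all(np.diff(out) >= 0)

    @given(st.one_of(st.just(0.0), st.floats(min_value=2.0, max_value=10.0)))
    @settings(max_examples=100, derandomize=True)
    def test_inverts_power_of_ten(self, exponent):
        raw = 0.0 if exponent == 0.0 else 10.0**exponent
        assert log10_viral_load(raw) == pytest.approx(exponent, abs=1e-9)


class TestSchwartz:
    @pytest.mark.parametrize(
        "height, creat, k, expected",
        [(140.0, 1.0, 0.55, 77.0), (70.0, 0.5, 0.45, 63.0)],
    )
    def test_hand_values(self, height, creat, k, expected):
        assert schwartz_egfr(height, creat, k) == pytest.approx(expected)

    def test_zero_creatinine_rejected(self):
        with pytest.raises(ValueError, match="creatinine"):
            schwartz_egfr(140.0, 0.0, 0.55)

    def test_constant_from_age_and_gender(self):
        # infant, adolescent male, and everyone else
        assert schwartz_egfr(70, 0.5, age_years=0.5, gender="female") == pytest.approx(63.0)
        assert schwartz_egfr(160, 1.0, age_years=15, gender="male") == pytest.approx(112.0)
        assert schwartz_egfr(140, 1.0, age_years=10, gender="male") == pytest.approx(77.0)


def _visits(log_values, patient_id="P1"):
    return pd.DataFrame(
        {
            "patient_id": [patient_id] * len(log_values),
            "month_index": range(len(log_values)),
            "ttv_log10": log_values,
        }
    )


class TestSummarizePatient:
    def test_constant_series(self):
        s = summarize_patient(_visits([5.0, 5.0, 5.0]))
        assert s.mean_ttv_log10 == 5.0 and s.n_detectable == 3

    def test_undetectable_enters_mean_as_zero(self):
        s = summarize_patient(_visits([0.0, 4.0, 8.0]))
        assert s.mean_ttv_log10 == pytest.approx(4.0)
        assert s.n_detectable == 2
        assert s.n_visits == 3

    def test_missing_dropped_from_mean(self):
        s = summarize_patient(_visits([6.0, np.nan, 4.0]))
        assert s.mean_ttv_log10 == pytest.approx(5.0)
        assert s.n_visits == 2

    def test_no_usable_visits_names_patient(self):
        with pytest.raises(ValueError, match="P7"):
            summarize_patient(_visits([np.nan, np.nan], patient_id="P7"))

    @given(
        st.lists(
            st.one_of(st.just(0.0), st.floats(min_value=2, max_value=10)),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_mean_within_range(self, values):
        s = summarize_patient(_visits(values))
        assert min(values) <= s.mean_ttv_log10 <= max(values)


def _event_visits(months, infection_months, loads=None):
    loads = loads or {m: 4.0 + 0.1 * m for m in months}
    return pd.DataFrame(
        {
            "patient_id": ["P1"] * len(months),
            "month_index": months,
            "ttv_log10": [loads[m] for m in months],
            "infection": [m in infection_months for m in months],
        }
    )


class TestLaggedPairs:
    def test_full_year_single_event(self):
        pairs = build_lagged_pairs(_event_visits(list(range(12)), {5}), "infection")
        assert len(pairs) == 11
        assert pairs.loc[pairs["month_index"] == 4, "outcome"].item() == 1
        assert pairs.loc[pairs["month_index"] != 4, "outcome"].eq(0).all()

    def test_gap_month_produces_no_pair(self):
        months = [m for m in range(12) if m != 4]
        pairs = build_lagged_pairs(_event_visits(months, {5}), "infection")
        assert 4 not in set(pairs["month_index"])
        assert pairs["outcome"].eq(0).all()  # the month-5 event has no predictor

    def test_single_visit_yields_nothing(self):
        pairs = build_lagged_pairs(_event_visits([3], set()), "infection")
        assert pairs.empty

    @given(st.sets(st.integers(min_value=0, max_value=11), min_size=1))
    @settings(max_examples=100, derandomize=True)
    def test_count_bounded_by_visits_minus_one(self, months):
        pairs = build_lagged_pairs(_event_visits(sorted(months), set()), "infection")
        assert len(pairs) <= len(months) - 1


def test_prevalence_percent_rounding():
    assert prevalence_percent(481, 509) == 94.5
    with pytest.raises(ValueError):
        prevalence_percent(10, 0)
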