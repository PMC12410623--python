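"""Outcome dichotomization, eligibility and missing-data filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

import endopredict as ep
from conftest import toy_table


class TestDichotomizeVAS:
    @pytest.mark.parametrize(
        "baseline,followup,expected",
        [
            (10, 7, 1),  # exactly 30% reduction counts as improved
            (8, 8, 0),  # zero reduction
            (5, 6, 0),  # pain increased
            (10, 7.01, 0),  # just under the threshold
            (1, 0.7, 1),
        ],
    )
    def test_threshold_rule(self, baseline, followup, expected):
        assert ep.dichotomize_vas(baseline, followup) == expected

    def test_baseline_zero_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            ep.dichotomize_vas(0, 0)

    @pytest.mark.parametrize("baseline,followup", [(-1, 5), (5, 11), (12, 3)])
    def test_out_of_range_scores_rejected(self, baseline, followup):
        with pytest.raises(ValueError):
            ep.dichotomize_vas(baseline, followup)

    @given(
        baseline=st.floats(0.5, 10),
        followup=st.floats(0, 10),
        factor=st.floats(0.05, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_invariant_to_common_rescaling(self, baseline, followup, factor):
        # relative reduction is scale-free: shrinking both scores by a common
        # positive factor cannot change the improvement status. Exact equality
        # holds away from the threshold, where one ulp of rounding in the
        # rescaled scores cannot flip the comparison.
        assume(abs((baseline - followup) / baseline - 0.30) > 1e-9)
        direct = ep.dichotomize_vas(baseline, followup)
        scaled = ep.dichotomize_vas(baseline * factor, followup * factor)
        assert direct == scaled


class TestDichotomizeQoL:
    @pytest.mark.parametrize(
        "baseline,followup,expected",
        [(50, 60, 1), (50, 59, 0), (95, 100, 0), (0, 10, 1), (90, 100, 1)],
    )
    def test_ten_point_rule(self, baseline, followup, expected):
        assert ep.dichotomize_qol(baseline, followup) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ep.dichotomize_qol(50, 101)


class TestOutcomeIndicator:
    def test_vas_table_logs_zero_baselines(self):
        tab = toy_table(
            [
                {"baseline_score": 10.0, "followup_score": 7.0},
                {"baseline_score": 0.0, "followup_score": 0.0},
                {"baseline_score": 6.0, "followup_score": 6.0},
            ]
        )
        y, log = ep.outcome_indicator(tab)
        assert log["undefined_relative_reduction"] == 1
        assert y.tolist()[0] == 1.0 and np.isnan(y.tolist()[1]) and y.tolist()[2] == 0.0


class TestScreenMissingness:
    def _table_with_missing(self, n_missing: int, n: int = 100):
        rows = [
            {"baseline_score": 5.0, "followup_score": 2.0, "flag": (np.nan if i < n_missing else 1.0)}
            for i in range(n)
        ]
        return toy_table(rows)

    def test_exactly_half_missing_is_excluded(self):
        retained, log = ep.screen_missingness(self._table_with_missing(50), ["flag"])
        assert retained == []
        assert log["predictors"]["flag"]["missing_fraction"] == pytest.approx(0.5)

    def test_just_below_half_is_retained(self):
        retained, _ = ep.screen_missingness(self._table_with_missing(49), ["flag"])
        assert retained == ["flag"]

    def test_fully_observed_is_retained(self):
        retained, _ = ep.screen_missingness(self._table_with_missing(0), ["flag"])
        assert retained == ["flag"]

    def test_row_order_irrelevant(self, rng):
        tab = self._table_with_missing(30)
        perm = rng.permutation(len(tab.df))
        shuffled = ep.CohortTable(tab.df.iloc[perm].reset_index(drop=True), tab.codebook)
        assert ep.screen_missingness(tab, ["flag"])[0] == ep.screen_missingness(shuffled, ["flag"])[0]

    def test_empty_table_is_an_error(self):
        tab = toy_table([{"baseline_score": 5.0, "followup_score": 2.0, "flag": 1.0}])
        empty = ep.CohortTable(tab.df.iloc[:0], tab.codebook)
        with pytest.raises(ValueError):
            ep.screen_missingness(empty, ["flag"])


class TestCompleteCase:
    def _toy(self):
        preds = {"a": ep.PredictorSpec(type="binary"), "b": ep.PredictorSpec(type="binary")}
        rows = [
            {"baseline_score": 5.0, "followup_score": 2.0, "a": 1.0, "b": 0.0},
            {"baseline_score": 5.0, "followup_score": 2.0, "a": np.nan, "b": 0.0},
            {"baseline_score": 5.0, "followup_score": 2.0, "a": 1.0, "b": np.nan},
            {"baseline_score": 5.0, "followup_score": 2.0, "a": 0.0, "b": 1.0},
            {"baseline_score": 5.0, "followup_score": 2.0, "a": 1.0, "b": 1.0},
        ]
        return toy_table(rows, predictors=preds)

    def test_rows_with_any_listed_missing_are_dropped(self):
        out, log = ep.complete_case(self._toy(), ["a", "b"])
        assert log == {"n_in": 5, "retained": 3, "dropped": 2}

    def test_missing_in_non_listed_column_is_retained(self):
        # enumerating rows against the rule: only columns in use matter
        out, log = ep.complete_case(self._toy(), ["b"])
        assert log["retained"] == 4

    def test_idempotent(self):
        once, _ = ep.complete_case(self._toy(), ["a", "b"])
        twice, log = ep.complete_case(once, ["a", "b"])
        assert log["dropped"] == 0
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_no_missing_is_identity(self):
        tab = toy_table([{"baseline_score": 5.0, "followup_score": 2.0, "flag": 1.0}] * 3)
        out, log = ep.complete_case(tab, ["flag"])
        pd.testing.assert_frame_equal(out.df, tab.df)

    def test_zero_surviving_rows_is_an_error(self):
        tab = toy_table([{"baseline_score": np.nan, "followup_score": 2.0, "flag": 1.0}] * 3)
        with pytest.raises(ValueError):
            ep.complete_case(tab, ["flag"])


class TestEligibilityAndIO:
    def test_age_filter_logs_exclusions(self, small_cohort):
        df = small_cohort.df.copy()
        df.loc[0, "age"] = 15.0
        df.loc[1, "age"] = 70.0
        tab = ep.CohortTable(df, small_cohort.codebook)
        out, log = ep.filter_eligibility(tab)
        assert log["excluded_age"] == 2
        assert len(out.df) == len(df) - 2

    def test_csv_codebook_roundtrip(self, small_cohort, tmp_path):
        csv, yml = tmp_path / "cohort.csv", tmp_path / "codebook.yaml"
        small_cohort.save(csv, yml)
        back = ep.CohortTable.load(csv, yml)
        assert back.codebook == small_cohort.codebook
        pd.testing.assert_frame_equal(
            back.df, small_cohort.df, check_dtype=False, check_exact=False, rtol=1e-12
        )

    def test_duplicate_ids_rejected(self):
        rows = [{"id": "x", "baseline_score": 5.0, "followup_score": 2.0, "flag": 1.0}] * 2
        with pytest.raises(ValueError, match="duplicated"):
            toy_table(rows)

    def test_out_of_range_scores_rejected_at_validation(self):
        with pytest.raises(ValueError, match="outside"):
            toy_table([{"baseline_score": 11.0, "followup_score": 2.0, "flag": 1.0}])
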