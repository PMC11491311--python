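"""Imputation, dichotomization rules and prevalence arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from symptomnet.data_model import (
    BinaryMatrix,
    build_binary_matrix,
    dichotomize_item,
    heavy_alcohol_flag,
    impute_median,
    percent_half_up,
    prevalence_report,
)
from symptomnet.instruments import NODE_LABELS


class TestImputeMedian:
    def _frame(self, col):
        return pd.DataFrame({"H1": col})

    def test_odd_count_median(self):
        out = impute_median(self._frame([1, 2, 2, 3, np.nan]), ("H1",))
        assert out["H1"].tolist() == [1, 2, 2, 3, 2]

    def test_even_count_ties_round_down(self):
        # median 2.5 between ordinal codes -> lower code
        out = impute_median(self._frame([1, 2, 3, 3, np.nan]), ("H1",))
        assert out["H1"].iloc[-1] == 2

    def test_fully_missing_column_is_an_error(self):
        with pytest.raises(ValueError, match="fully missing.*H1"):
            impute_median(self._frame([np.nan, np.nan]), ("H1",))

    def test_out_of_range_response_is_an_error(self):
        with pytest.raises(ValueError, match="out of range"):
            impute_median(self._frame([1, 7]), ("H1",))

    def test_observed_values_unchanged(self):
        col = [0, 3, 1, np.nan, 2]
        out = impute_median(self._frame(col), ("H1",))
        assert out["H1"].tolist()[:3] == [0, 3, 1]


class TestDichotomize:
    @pytest.mark.parametrize(
        "rule,raw,reverse,expected",
        [
            ("hads", 0, False, 0),
            ("hads", 1, False, 1),
            ("hads", 2, False, 1),
            ("hads", 3, False, 1),
            ("bis11", 1, False, 0),
            ("bis11", 2, False, 0),
            ("bis11", 3, False, 1),
            ("bis11", 4, False, 1),
            ("bis11", 4, True, 0),  # reflect 5-4=1, below the cut
            ("bis11", 1, True, 1),
            ("mmas_binary", 0, False, 0),
            ("mmas_binary", 1, False, 1),
            ("mmas_likert", 0, False, 0),
            ("mmas_likert", 1, False, 1),
            ("mmas_likert", 4, False, 1),
            ("eq5d", 1, False, 0),  # "no problems"
            ("eq5d", 2, False, 1),  # "slight problems"
            ("eq5d", 5, False, 1),
            ("mateq_freq", 0, False, 0),
            ("mateq_freq", 1, False, 1),
        ],
    )
    def test_instrument_rules(self, rule, raw, reverse, expected):
        assert dichotomize_item(rule, raw, reverse) == expected

    @given(st.integers(min_value=1, max_value=4))
    def test_reverse_bis_item_is_complement_threshold(self, x):
        # reflect-then-threshold == "present iff raw <= 2" for reverse items
        assert dichotomize_item("bis11", x, reverse=True) == int(x <= 2)

    @given(st.integers(min_value=0, max_value=1))
    def test_binary_rule_idempotent(self, x):
        assert dichotomize_item("mmas_binary", x) == x
        assert dichotomize_item("mmas_binary", dichotomize_item("mmas_binary", x)) == x

    def test_unknown_rule_and_out_of_range(self):
        with pytest.raises(ValueError, match="unknown"):
            dichotomize_item("nope", 1)
        with pytest.raises(ValueError, match="outside scale"):
            dichotomize_item("hads", 9)


class TestHeavyAlcohol:
    @pytest.mark.parametrize(
        "sex,units,expected",
        [
            ("male", 25, 1),
            ("male", 21, 0),  # strict inequality at the cut-off
            ("male", 21.5, 1),
            ("female", 15, 1),
            ("female", 14, 0),
        ],
    )
    def test_sex_specific_threshold(self, sex, units, expected):
        assert heavy_alcohol_flag(sex, units) == expected

    def test_unknown_sex_is_an_error(self):
        with pytest.raises(ValueError, match="sex"):
            heavy_alcohol_flag("unknown", 10)


class TestBuildBinaryMatrix:
    def test_all_sixty_five_labels_in_order(self, small_cohort):
        responses, truth = small_cohort
        mat = build_binary_matrix(responses)
        assert mat.p == 65
        assert mat.node_labels == NODE_LABELS

    def test_round_trip_recovers_binary_layer(self, small_cohort):
        responses, truth = small_cohort
        mat = build_binary_matrix(impute_median(responses))
        assert np.array_equal(mat.values, truth["binary"].values)

    def test_partner_count_cut(self, small_cohort):
        responses, _ = small_cohort
        df = responses.copy()
        df.loc[df.index[:4], "partners_year"] = [0, 1, 2, 5]
        mat = build_binary_matrix(df)
        pr = mat.values[:, mat.node_labels.index("PR")]
        assert pr[:4].tolist() == [0, 0, 1, 1]

    def test_excluded_substance_columns_are_ignored(self, small_cohort):
        responses, truth = small_cohort
        df = responses.copy()
        df["opioids"] = 1  # excluded MATE-Q items never become nodes
        df["sedatives"] = 2
        df["gambling"] = 1
        mat = build_binary_matrix(df)
        assert mat.p == 65
        assert not {"opioids", "sedatives", "gambling"} & set(mat.node_labels)

    def test_duplicate_ids_rejected(self, small_cohort):
        responses, _ = small_cohort
        df = responses.copy()
        df.loc[df.index[1], "participant_id"] = df["participant_id"].iloc[0]
        with pytest.raises(ValueError, match="duplicate"):
            build_binary_matrix(df)

    def test_vas_median_split(self, small_cohort):
        responses, _ = small_cohort
        mat = build_binary_matrix(responses)
        qv = mat.values[:, mat.node_labels.index("QV")]
        vas = responses["vas"].to_numpy()
        assert np.array_equal(qv, (vas < np.median(vas)).astype(int))


class TestPrevalence:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(179, 1615, 11.1), (463, 1615, 28.7), (0, 1615, 0.0), (1, 8, 12.5)],
    )
    def test_half_up_percentages(self, count, total, expected):
        assert percent_half_up(count, total) == expected

    def test_report_from_matrix(self):
        mat = BinaryMatrix(np.array([[1, 0], [1, 1], [0, 0]]), ("a", "b"))
        rep = prevalence_report(mat)
        assert rep.loc[rep.label == "a", "percent"].item() == 66.7
        assert rep.loc[rep.label == "b", "count"].item() == 1

    @given(st.integers(min_value=1, max_value=5000), st.integers(min_value=0, max_value=5000))
    def test_round_trip_count_within_one(self, n, count):
        count = min(count, n)
        pct = percent_half_up(count, n)
        assert abs(round(pct * n / 100) - count) <= max(1, n // 1000)

    def test_binary_matrix_rejects_missing(self):
        with pytest.raises(ValueError):
            BinaryMatrix(np.array([[0, 2]]), ("a", "b"))
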