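"""The 0-5 rubric, per-sample sums, positivity filter, group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rishquant.scoring import (
    load_example_cohort_scores,
    positivity_filter,
    score_counts,
    score_field,
    score_sample,
    summarize_groups,
)


class TestScoreField:
    @pytest.mark.parametrize(
        ("count", "channel", "expected"),
        [
            (85, "blue_WT", 5),
            (70, "blue_WT", 4),
            (25, "red_TR", 3),
            (0, "blue_WT", 0),
            (0, "red_TR", 0),
            (20, "blue_WT", 1),  # upper edge belongs to the lower score
            (21, "blue_WT", 2),
            (10, "red_TR", 1),
            (41, "red_TR", 5),
            (80, "blue_WT", 4),
            (81, "blue_WT", 5),
        ],
    )
    def test_rubric_bins(self, count, channel, expected):
        assert score_field(count, channel) == expected

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            score_field(-1, "blue_WT")
        with pytest.raises(ValueError):
            score_field(5, "green")

    @given(st.integers(0, 10_000))
    def test_every_count_maps_to_exactly_one_score(self, count):
        for channel in ("blue_WT", "red_TR"):
            s = score_field(count, channel)
            assert s in range(6)

    def test_monotone_in_count(self):
        for channel in ("blue_WT", "red_TR"):
            scores = [score_field(c, channel) for c in range(0, 10_001)]
            assert all(a <= b for a, b in zip(scores, scores[1:]))


class TestScoreSample:
    def test_ten_fields_of_four_reach_ceiling(self):
        s = score_sample([4] * 10, "ctrl")
        assert s.total_score == 40
        assert not s.over_ceiling

    def test_all_zero_fields(self):
        assert score_sample([0] * 10).total_score == 0

    def test_mixed_fields_sum(self):
        assert score_sample([5, 5, 3, 0, 0, 0, 0, 0, 0, 0]).total_score == 13

    def test_sum_above_forty_flagged_not_clamped(self):
        s = score_sample([5] * 10)
        assert s.total_score == 50
        assert s.over_ceiling

    def test_warns_when_not_ten_fields(self):
        with pytest.warns(UserWarning, match="10 expected"):
            score_sample([4, 4, 4])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score_sample([])


class TestPositivityFilter:
    def test_bundled_cohort_all_23_patients_positive(self):
        table = load_example_cohort_scores()
        assert len(table) == 23
        kept, n = positivity_filter(table, wt_min=4, tr_min=3)
        assert n == 23

    def test_or_semantics(self):
        table = pd.DataFrame(
            {"wt_score": [3, 4, 3], "tr_score": [2, 0, 3]}
        )
        kept, n = positivity_filter(table)
        assert n == 2  # row 0 fails both thresholds

    def test_matches_row_by_row_predicate_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = pd.DataFrame(
                {
                    "wt_score": rng.integers(0, 41, size=30),
                    "tr_score": rng.integers(0, 41, size=30),
                }
            )
            _, n = positivity_filter(table)
            expected = sum(
                (row.wt_score >= 4) or (row.tr_score >= 3)
                for row in table.itertuples()
            )
            assert n == expected

    def test_missing_column_rejected(self):
        with pytest.raises(KeyError):
            positivity_filter(pd.DataFrame({"wt_score": [4]}))


class TestSummarizeGroups:
    def test_mean_and_sd(self):
        t = pd.DataFrame({"race": ["a", "a"], "wt_score": [10, 20], "tr_score": [0, 0]})
        out = summarize_groups(t, "race")
        assert out.loc[0, "wt_score_mean"] == 15.0
        assert out.loc[0, "wt_score_sd"] == pytest.approx(7.0711, abs=1e-4)

    def test_singleton_group_flagged(self):
        t = pd.DataFrame({"race": ["x"], "wt_score": [5], "tr_score": [1]})
        out = summarize_groups(t, "race")
        assert out.loc[0, "sd_degenerate"]
        assert out.loc[0, "wt_score_sd"] == 0.0

    def test_one_row_per_group(self):
        t = pd.DataFrame(
            {"stage": ["3", "4", "3"], "wt_score": [1, 2, 3], "tr_score": [0, 0, 0]}
        )
        assert len(summarize_groups(t, "stage")) == 2

    def test_unknown_column_rejected(self):
        with pytest.raises(KeyError):
            summarize_groups(pd.DataFrame({"wt_score": [1]}), "race")


def test_score_counts_table_roundtrip():
    counts = pd.DataFrame(
        {
            "sample_id": ["s1"] * 10 + ["s2"] * 10,
            "field_index": list(range(10)) * 2,
            "blue_count": [65] * 10 + [90] * 10,
            "red_count": [35] * 10 + [45] * 10,
        }
    )
    out = score_counts(counts).set_index("sample_id")
    assert out.loc["s1", "wt_score"] == 40  # ten fields of score 4
    assert out.loc["s2", "wt_score"] == 50  # ten fields of score 5
    assert out.loc["s1", "tr_score"] == 40
    assert out.loc["s2", "tr_score"] == 50
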