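"""Pathway weights, the one-sample t summary and the drug-efficiency index."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cdei.errors import DegenerateStatisticError, UsageError
from cdei.expression import SampleDesign
from cdei.scoring import (
    CdeiResult,
    cdei_score,
    one_sample_t,
    pathway_weight,
    rank_drugs,
    round_half_away,
    student_t_pvalue,
    summarize_dataset,
    summarize_pathways,
    weighted_mean,
)

finite_t = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


class TestPathwayWeight:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([2.0, 1.0, -1.0], 2 / 3),  # positive mean -> positive fraction
            ([-2.0, -1.0, 1.0], 2 / 3),  # negative mean -> negative fraction
            ([1.0, 2.0, 3.0], 1.0),
            ([-1.0, -2.0], 1.0),
            ([0.0, 0.0], 0.0),  # zeros count toward neither branch
            ([1.0, -1.0], 0.5),  # zero mean uses the positive branch
        ],
    )
    def test_sign_consistency_fraction(self, scores, expected):
        assert pathway_weight(scores) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            pathway_weight([])

    def test_weight_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            scores = rng.normal(size=rng.integers(1, 8))
            assert 0.0 <= pathway_weight(scores) <= 1.0


class TestWeightedMean:
    def test_hand_example(self):
        # mean 2/3, weight 2/3 -> 4/9
        assert weighted_mean([2.0, 1.0, -1.0]) == pytest.approx(4 / 9)

    def test_all_zero(self):
        assert weighted_mean([0.0, 0.0]) == 0.0

    def test_single_positive_score_passes_through(self):
        assert weighted_mean([3.5]) == pytest.approx(3.5)

    def test_sign_matches_mean(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            scores = rng.normal(size=rng.integers(1, 8))
            mu = weighted_mean(scores)
            assert mu == 0.0 or math.copysign(1, mu) == math.copysign(
                1, np.mean(scores)
            )


class TestOneSampleT:
    def test_matches_scipy_ttest_1samp(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0.2, 1.0, size=50)
        stat = one_sample_t(values)
        ref = sps.ttest_1samp(values, 0.0)
        assert stat.t == pytest.approx(ref.statistic)
        assert stat.p == pytest.approx(ref.pvalue)
        assert stat.df == 49

    def test_zero_mean_vector(self):
        stat = one_sample_t([1.0, -1.0])
        assert stat.t == 0.0
        assert stat.p == 1.0

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            one_sample_t([2.0, 2.0, 2.0])

    def test_single_value_rejected(self):
        with pytest.raises(UsageError):
            one_sample_t([1.0])


class TestCdeiScore:
    def test_published_benchmark_values(self):
        assert round_half_away(cdei_score(1.04, 0.67)) == pytest.approx(0.22)
        assert round_half_away(cdei_score(1.04, 2.06)) == pytest.approx(-0.33)

    def test_equal_magnitudes_give_zero(self):
        assert cdei_score(1.04, -1.04) == 0.0

    def test_perfect_restoration(self):
        assert cdei_score(2.78, 0.0) == 1.0

    def test_double_zero_defined_as_zero(self):
        assert cdei_score(0.0, 0.0) == 0.0

    @given(tu=finite_t, tt=finite_t)
    @settings(max_examples=300, deadline=None)
    def test_bounded_in_unit_interval(self, tu, tt):
        assert -1.0 <= cdei_score(tu, tt) <= 1.0

    @given(tu=finite_t, tt=finite_t)
    @settings(max_examples=300, deadline=None)
    def test_antisymmetric_under_swap(self, tu, tt):
        assert cdei_score(tu, tt) == pytest.approx(-cdei_score(tt, tu), abs=1e-12)

    @given(tu=st.floats(min_value=0.01, max_value=100), sign=st.sampled_from([-1, 1]))
    @settings(max_examples=100, deadline=None)
    def test_sign_invariance(self, tu, sign):
        """Only magnitudes matter; t signs are dropped."""
        assert cdei_score(sign * tu, 0.5) == cdei_score(tu, 0.5)

    def test_strictly_decreasing_in_treated_t(self):
        tu = 1.04
        values = [cdei_score(tu, tt) for tt in np.linspace(0, 5, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestStudentTPvalue:
    def test_symmetric_in_t(self):
        assert student_t_pvalue(2.43, 240) == student_t_pvalue(-2.43, 240)

    def test_zero_t_gives_one(self):
        assert student_t_pvalue(0.0, 240) == 1.0


class TestRankDrugs:
    def test_descending_with_lexicographic_ties(self):
        results = [
            CdeiResult(drug="b", abs_t_untreated=1, abs_t_treated=1, cdei=0.0),
            CdeiResult(drug="a", abs_t_untreated=1, abs_t_treated=1, cdei=0.0),
            CdeiResult(drug="c", abs_t_untreated=1, abs_t_treated=0.1, cdei=0.8),
        ]
        ranked = rank_drugs(results)
        assert [r.drug for r in ranked] == ["c", "a", "b"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_single_drug(self):
        (r,) = rank_drugs(
            [CdeiResult(drug="only", abs_t_untreated=1, abs_t_treated=0, cdei=1.0)]
        )
        assert r.rank == 1

    def test_empty_rejected(self):
        with pytest.raises(UsageError):
            rank_drugs([])


class TestSummarizeDataset:
    @staticmethod
    def design():
        return SampleDesign(
            conditions={
                "c1": "control", "c2": "control",
                "u1": "untreated", "u2": "untreated", "u3": "untreated",
            },
            drug_of={},
        )

    def test_symmetric_spia_mu_gives_t_zero(self):
        # two pathways, scores chosen so SPIA_mu = (+a, -a)
        scores = pd.DataFrame(
            {"u1": [1.0, -1.0], "u2": [1.0, -1.0], "u3": [1.0, -1.0]},
            index=["P1", "P2"],
        )
        stat = summarize_dataset(scores, self.design(), "untreated")
        assert stat.t == 0.0
        assert stat.df == 1

    def test_all_zero_scores_degenerate(self):
        scores = pd.DataFrame(
            {"u1": [0.0, 0.0], "u2": [0.0, 0.0], "u3": [0.0, 0.0]},
            index=["P1", "P2"],
        )
        with pytest.raises(DegenerateStatisticError):
            summarize_dataset(scores, self.design(), "untreated")

    def test_positive_shift_recovered(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            rng.normal(0.5, 1.0, size=(60, 3)),
            index=[f"P{i}" for i in range(60)],
            columns=["u1", "u2", "u3"],
        )
        stat = summarize_dataset(scores, self.design(), "untreated")
        assert stat.t > 0
        assert stat.df == 59

    def test_control_condition_rejected(self):
        scores = pd.DataFrame({"u1": [1.0]}, index=["P1"])
        with pytest.raises(UsageError):
            summarize_dataset(scores, self.design(), "control")

    def test_summaries_weighting(self):
        scores = pd.DataFrame(
            {"u1": [2.0], "u2": [1.0], "u3": [-1.0]}, index=["P1"]
        )
        (summary,) = summarize_pathways(scores, ["u1", "u2", "u3"], "U")
        assert summary.weight == pytest.approx(2 / 3)
        assert summary.spia_mu == pytest.approx(4 / 9)


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.005, 0.01), (-0.005, -0.01), (0.2249, 0.22), (0.225, 0.23), (1.0, 1.0)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x, 2) == pytest.approx(expected)
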