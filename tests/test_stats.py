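"""Evaluation statistics: confusion-matrix measures, margin of error,
sample size, coverage rate, agreement, tallies."""

import pytest
from hypothesis import given, settings, strategies as st

from teocde import (
    AgreementSummary,
    CIParams,
    ConfusionCounts,
    CoverageCounts,
    coverage_rate,
    margin_of_error,
    required_sample_size,
    sensitivity,
    specificity,
    summarize_agreement,
    tally_categories,
)
from teocde.cadsr import AnnotationCategory, AnnotationRecord
from teocde.errors import AnnotationError, TeoCdeError, UndefinedStatisticError

# Pilot-set annotation results: (tp, fn, reported sensitivity at 3 dp,
# reported margin of error at 3 dp), three annotators x three sets.
PILOT_ROWS = [
    (85, 2, 0.977, 0.032),
    (82, 5, 0.943, 0.050),
    (83, 9, 0.902, 0.064),
    (86, 5, 0.945, 0.048),
    (82, 7, 0.921, 0.058),
    (77, 11, 0.875, 0.074),
    (89, 3, 0.967, 0.037),
    (84, 8, 0.913, 0.060),
    (83, 9, 0.900, 0.064),
]


class TestSensitivitySpecificity:
    @pytest.mark.parametrize(
        "tp, fn, expected",
        [(398, 17, 0.959036), (397, 7, 0.982673), (5, 0, 1.0)],
    )
    def test_sensitivity(self, tp, fn, expected):
        cc = ConfusionCounts(tp=tp, tn=0, fp=0, fn=fn)
        assert round(sensitivity(cc), 6) == expected

    @pytest.mark.parametrize(
        "tn, fp, expected",
        [(408, 27, 0.937931), (412, 33, 0.925843), (5, 0, 1.0)],
    )
    def test_specificity(self, tn, fp, expected):
        cc = ConfusionCounts(tp=0, tn=tn, fp=fp, fn=0)
        assert round(specificity(cc), 6) == expected

    def test_undefined_denominators(self):
        with pytest.raises(UndefinedStatisticError):
            sensitivity(ConfusionCounts(0, 1, 1, 0))
        with pytest.raises(UndefinedStatisticError):
            specificity(ConfusionCounts(1, 0, 0, 1))

    @settings(deadline=None, derandomize=True)
    @given(
        st.integers(1, 200), st.integers(1, 200), st.integers(0, 200),
        st.integers(0, 200), st.integers(2, 5),
    )
    def test_scale_invariance(self, tp, tn, fp, fn, k):
        a = ConfusionCounts(tp, tn, fp, fn)
        b = ConfusionCounts(tp * k, tn * k, fp * k, fn * k)
        assert sensitivity(a) == pytest.approx(sensitivity(b))
        assert specificity(a) == pytest.approx(specificity(b))

    def test_negative_counts_rejected(self):
        with pytest.raises(TeoCdeError):
            ConfusionCounts(-1, 0, 0, 0)


class TestMarginOfError:
    @pytest.mark.parametrize("tp, fn, _sens, expected", PILOT_ROWS)
    def test_reproduces_all_pilot_margins(self, tp, fn, _sens, expected):
        p_hat = tp / (tp + fn)
        assert round(margin_of_error(p_hat, tp), 3) == expected

    def test_certain_proportion_has_zero_margin(self):
        assert margin_of_error(1.0, 50) == 0.0

    def test_maximized_at_half(self):
        at_half = margin_of_error(0.5, 100)
        assert at_half > margin_of_error(0.3, 100)
        assert at_half > margin_of_error(0.7, 100)

    def test_decreasing_in_tp(self):
        assert margin_of_error(0.9, 50) > margin_of_error(0.9, 100)

    def test_zero_tp_rejected(self):
        with pytest.raises(TeoCdeError):
            margin_of_error(0.5, 0)


class TestRequiredSampleSize:
    def test_study_sample_size(self):
        # lowest pilot sensitivity 0.875 at margin 0.032 -> n = 410
        assert required_sample_size(0.875, 0.032) == 410

    def test_worst_case_proportion(self):
        # exact arithmetic: 3.8416 * 0.25 / 0.001024 = 937.9 -> 938
        assert required_sample_size(0.5, 0.032) == 938

    def test_halving_margin_quadruples_size(self):
        n1 = 1.96**2 * 0.8 * 0.2 / 0.04**2
        n2 = 1.96**2 * 0.8 * 0.2 / 0.02**2
        assert n2 == pytest.approx(4 * n1)
        assert required_sample_size(0.8, 0.02) >= 4 * required_sample_size(0.8, 0.04) - 2

    def test_ceil_variant(self):
        assert required_sample_size(0.875, 0.032, ceil=True) == 411

    def test_invalid_margin_rejected(self):
        with pytest.raises(TeoCdeError):
            required_sample_size(0.5, 0.0)

    @pytest.mark.parametrize("tp, fn, _sens, _moe", PILOT_ROWS)
    def test_margin_and_size_mutual_inverses(self, tp, fn, _sens, _moe):
        # running the sample-size formula on each row's (sensitivity,
        # margin) pair recovers that row's TP count
        p_hat = tp / (tp + fn)
        d = margin_of_error(p_hat, tp)
        assert required_sample_size(p_hat, d) == tp


class TestCoverageRate:
    def test_observing_set_rate(self):
        cv = CoverageCounts(existing=263, new=9, not_time_related=20,
                            cannot_represent=8)
        assert coverage_rate(cv) == pytest.approx(272 / 280)

    def test_full_coverage(self):
        cv = CoverageCounts(existing=5, new=1, not_time_related=3,
                            cannot_represent=0)
        assert coverage_rate(cv) == 1.0

    def test_all_denominator_convention(self):
        cv = CoverageCounts(existing=263, new=9, not_time_related=20,
                            cannot_represent=8)
        assert coverage_rate(cv, denominator="all") == pytest.approx(272 / 300)

    def test_mean_of_test_set_rates(self):
        rates = [0.950, 0.940, 0.949, 0.913, 0.964, 0.935]
        assert round(100 * sum(rates) / len(rates), 1) == 94.2

    def test_empty_denominator_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            coverage_rate(CoverageCounts(0, 0, 5, 0))


def triple(public_id, patterns):
    return [
        AnnotationRecord(public_id, f"A{i + 1}",
                         AnnotationCategory.EXISTING_PATTERN, p)
        for i, p in enumerate(patterns)
    ]


class TestSummarizeAgreement:
    def test_all_identical(self):
        recs = triple("1", ["P1", "P1", "P1"]) + triple("2", ["P4", "P4", "P4"])
        summary = summarize_agreement(recs)
        assert summary.no_difference == 2
        assert summary.consensus == {"1": "P1", "2": "P4"}
        assert summary.unresolved == set()

    def test_majority_vote(self):
        summary = summarize_agreement(triple("1", ["P1", "P1", "P3"]))
        assert summary.one_difference == 1
        assert summary.consensus["1"] == "P1"

    def test_all_different_unresolved(self):
        summary = summarize_agreement(triple("1", ["P1", "P2", "P3"]))
        assert summary.all_different == 1
        assert summary.unresolved == {"1"}

    def test_counts_sum_to_ids(self):
        recs = (triple("1", ["P1", "P1", "P1"]) + triple("2", ["P1", "P2", "P1"])
                + triple("3", ["P1", "P2", "P3"]))
        summary = summarize_agreement(recs)
        assert summary.total == 3

    def test_missing_annotator_rejected(self):
        with pytest.raises(AnnotationError, match="1"):
            summarize_agreement(triple("1", ["P1", "P2"]))

    def test_custom_equivalence_relation(self):
        # an equivalence that merges P1 with P1b turns one-difference
        # into no-difference
        recs = triple("1", ["P1", "P1b", "P1"])
        strict = summarize_agreement(recs)
        assert strict.one_difference == 1
        merged = summarize_agreement(
            recs, equivalence=lambda a, b: a.rstrip("b") == b.rstrip("b"))
        assert merged.no_difference == 1

    def test_non_pattern_categories_compare_by_category(self):
        recs = [
            AnnotationRecord("1", "A1", AnnotationCategory.NOT_TIME_RELATED),
            AnnotationRecord("1", "A2", AnnotationCategory.NOT_TIME_RELATED),
            AnnotationRecord("1", "A3", AnnotationCategory.CANNOT_REPRESENT),
        ]
        summary = summarize_agreement(recs)
        assert summary.one_difference == 1
        assert summary.consensus["1"] == "not_time_related"


class TestTallyCategories:
    @staticmethod
    def build(existing, new, not_related, cannot):
        recs = []
        i = 0
        for n, cat, pattern in (
            (existing, AnnotationCategory.EXISTING_PATTERN, "P1"),
            (new, AnnotationCategory.NEW_PATTERN, "N1"),
            (not_related, AnnotationCategory.NOT_TIME_RELATED, None),
            (cannot, AnnotationCategory.CANNOT_REPRESENT, None),
        ):
            for _ in range(n):
                recs.append(AnnotationRecord(str(i), "A1", cat, pattern))
                i += 1
        return recs

    def test_observing_set_tallies(self):
        cv, pct = tally_categories(self.build(263, 9, 20, 8))
        assert (cv.existing, cv.new, cv.not_time_related, cv.cannot_represent) == (
            263, 9, 20, 8)
        assert pct["existing_pattern"] == 87.7
        assert cv.total == 300

    def test_empty_set(self):
        cv, pct = tally_categories([])
        assert cv.total == 0 and all(v == 0.0 for v in pct.values())

    def test_chains_to_coverage_rate(self):
        cv, _ = tally_categories(self.build(263, 9, 20, 8))
        assert coverage_rate(cv) == pytest.approx(0.9714, abs=5e-5)


class TestCIParams:
    def test_defaults_are_95ci(self):
        assert CIParams().z_value == 1.96

    def test_invalid_proportion_rejected(self):
        with pytest.raises(TeoCdeError):
            CIParams(p_hat=1.5)
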