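"""Diagnostic-accuracy panel: counting, rounding conventions, pairwise
differences, group comparisons and report rendering."""

import itertools

import pytest

from petriage import (CohortTable, ConfusionMatrix, build_confusion_matrix,
                      chi_square_from_counts, compare_groups, compute_metrics,
                      pairwise_difference, render_report, ttest_from_summary)
from petriage.accuracy import round_half_up
from petriage.rules import AlgorithmDecision, Verdict

from conftest import make_record


def decision(pid, imaging):
    verdict = Verdict.IMAGING_REQUIRED if imaging else Verdict.RULE_OUT
    return AlgorithmDecision(pid, "x", verdict, "")


class TestConfusionMatrix:
    def test_counts_match_brute_force_on_enumerated_lists(self):
        # all 16 (decision, truth) patterns of 2 patients plus larger mixes
        for imaging_flags, truth_flags in itertools.product(
                itertools.product([True, False], repeat=4), repeat=2):
            decs = [decision(f"p{i}", im) for i, im in enumerate(imaging_flags)]
            truth = {f"p{i}": t for i, t in enumerate(truth_flags)}
            cm = build_confusion_matrix(decs, truth)
            assert cm.tp == sum(i and t for i, t in zip(imaging_flags, truth_flags))
            assert cm.fp == sum(i and not t for i, t in zip(imaging_flags, truth_flags))
            assert cm.fn == sum(t and not i for i, t in zip(imaging_flags, truth_flags))
            assert cm.n == 4

    def test_one_patient_per_cell(self):
        decs = [decision("a", True), decision("b", True),
                decision("c", False), decision("d", False)]
        truth = {"a": True, "b": False, "c": True, "d": False}
        assert build_confusion_matrix(decs, truth) == ConfusionMatrix(1, 1, 1, 1)

    def test_all_rule_out_all_positive(self):
        decs = [decision(f"p{i}", False) for i in range(3)]
        cm = build_confusion_matrix(decs, {f"p{i}": True for i in range(3)})
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 3, 0)

    def test_missing_truth_and_duplicates_rejected(self):
        with pytest.raises(ValueError, match="p0"):
            build_confusion_matrix([decision("p0", True)], {})
        with pytest.raises(ValueError, match="duplicate"):
            build_confusion_matrix([decision("p0", True)] * 2, {"p0": True})

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(10, 0, 0, 10))
        assert (m.sensitivity, m.specificity) == (100.0, 100.0)
        assert m.youden == 1.0 and m.nlr == 0.0 and m.plr is None  # 1/0 undefined

    def test_published_convention_uses_rounded_proportions(self):
        # sens 150/210 = 0.714286 -> 0.714; spec 726/948 -> 0.766
        m = compute_metrics(ConfusionMatrix(150, 222, 60, 726))
        assert m.plr == round_half_up(0.714 / (1 - 0.766), 3) == 3.051
        assert m.nlr == round_half_up((1 - 0.714) / 0.766, 3) == 0.373
        assert m.youden == 0.480

    def test_exact_convention_bayes_consistency(self):
        cm = ConfusionMatrix(186, 183, 24, 765)
        m = compute_metrics(cm, rounding="exact")
        prevalence = (cm.tp + cm.fn) / cm.n
        ppv = m.ppv / 100.0
        assert ppv / (1 - ppv) == pytest.approx(m.plr * prevalence / (1 - prevalence),
                                                abs=1e-9)

    def test_identity_chain(self):
        cm = ConfusionMatrix(7, 3, 2, 8)
        m = compute_metrics(cm, rounding="exact")
        assert m.accuracy == pytest.approx(100 * (cm.tp + cm.tn) / cm.n)
        assert m.youden == pytest.approx(m.sensitivity / 100 + m.specificity / 100 - 1)
        assert m.imaging_count + (cm.fn + cm.tn) == cm.n

    def test_exhaustive_imaging_masks_all_but_ppv(self):
        m = compute_metrics(ConfusionMatrix(210, 948, 0, 0))
        assert m.ppv == 18.1
        assert m.sensitivity is None and m.specificity is None
        assert m.missed_count is None and m.imaging_count == 1158
        full = compute_metrics(ConfusionMatrix(210, 948, 0, 0), exhaustive_na=False)
        assert full.sensitivity == 100.0 and full.specificity == 0.0

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="rounding"):
            compute_metrics(ConfusionMatrix(1, 1, 1, 1), rounding="banker")


class TestPairwise:
    def test_identity_comparison_is_zero(self):
        m = compute_metrics(ConfusionMatrix(5, 5, 5, 5))
        c = pairwise_difference(m, m, 20)
        assert (c.imaging_diff, c.imaging_diff_pct, c.missed_diff, c.missed_diff_pct) \
            == (0, 0.0, 0, 0.0)

    def test_missed_flagged_na_against_exhaustive_strategy(self):
        peged = compute_metrics(ConfusionMatrix(186, 183, 24, 765))
        standard = compute_metrics(ConfusionMatrix(210, 948, 0, 0))
        c = pairwise_difference(peged, standard, 1158)
        assert (c.imaging_diff, c.imaging_diff_pct) == (-789, -68.1)
        assert c.not_applicable_missed and c.missed_diff is None

    def test_half_up_percentage(self):
        # -729/1158 = -62.95...% -> -63.0 under half-up
        a = compute_metrics(ConfusionMatrix(165, 246, 45, 702))
        b = compute_metrics(ConfusionMatrix(207, 933, 3, 15))
        assert pairwise_difference(a, b, 1158).imaging_diff_pct == -63.0

    def test_invalid_n(self):
        m = compute_metrics(ConfusionMatrix(1, 1, 1, 1))
        with pytest.raises(ValueError):
            pairwise_difference(m, m, 0)


class TestGroupComparison:
    def build_cohort(self, n_pos=6, n_neg=8):
        records = []
        for i in range(n_neg):
            records.append(make_record(patient_id=f"n{i}", confirmed_pe=False,
                                       d_dimer=400.0 + 10 * i, dvt_signs=False))
        for i in range(n_pos):
            records.append(make_record(patient_id=f"p{i}", confirmed_pe=True,
                                       d_dimer=2000.0 + 10 * i, dvt_signs=(i % 2 == 0)))
        return CohortTable(records)

    def test_shapes_and_separated_d_dimer(self):
        table = compare_groups(self.build_cohort())
        row = table[table.variable == "d_dimer"].iloc[0]
        assert row.test == "t-test" and row.p_value < 1e-6
        assert set(table.kind) == {"continuous", "boolean"}

    def test_identical_proportions_give_p_one(self):
        records = [make_record(patient_id=f"n{i}", confirmed_pe=False,
                               hemoptysis=i < 2) for i in range(4)]
        records += [make_record(patient_id=f"p{i}", confirmed_pe=True,
                                hemoptysis=i < 2) for i in range(4)]
        table = compare_groups(CohortTable(records))
        row = table[table.variable == "hemoptysis"].iloc[0]
        assert row.p_value == pytest.approx(1.0)
        assert row.statistic == pytest.approx(0.0)

    def test_summary_stat_helpers(self):
        _, p = chi_square_from_counts(275, 948, 78, 210)
        assert round(p, 3) == 0.021
        _, p = ttest_from_summary(1191, 676, 948, 3118, 1635, 210)
        assert p < 0.001


class TestRenderReport:
    def metrics(self):
        return {"peged": compute_metrics(ConfusionMatrix(186, 183, 24, 765),
                                         algorithm="peged")}

    def test_byte_stable_and_formats(self):
        m = self.metrics()
        for fmt in ("markdown", "tsv", "json"):
            assert render_report(m, fmt=fmt) == render_report(m, fmt=fmt)
        assert "| Metric | peged |" in render_report(m, fmt="markdown")
        assert render_report(m, fmt="tsv").startswith("metric\tpeged")

    def test_header_round_trip_and_errors(self):
        doc = render_report(self.metrics(), fmt="markdown",
                            header={"rounding convention": "published"})
        assert "published" in doc
        with pytest.raises(ValueError, match="format"):
            render_report(self.metrics(), fmt="pdf")
        with pytest.raises(ValueError):
            render_report({})
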