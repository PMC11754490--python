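"""Agreement statistics against hand tallies and library oracles."""

import math

import numpy as np
import pytest

from chestcac.ct_io import BinaryMask
from chestcac.metrics import (ConfusionMatrix5, agreement_summary,
                              bootstrap_kappa, build_eval_report, cohen_kappa,
                              confusion, dice, per_category_metrics,
                              presence_metrics)


def _cm(counts):
    full = np.zeros((5, 5), np.int64)
    a = np.asarray(counts)
    full[: a.shape[0], : a.shape[1]] = a
    return ConfusionMatrix5(full)


class TestDice:
    def test_identical_nonempty_masks(self):
        bits = np.zeros((6, 6, 2), bool)
        bits[1:4, 1:4, 0] = True
        m = BinaryMask(bits, (1, 1, 1))
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 1), bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = True
        b[5, 5, 0] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_by_hand(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros_like(a)
        a[0, :, 0] = True          # |A| = 4
        b[:2, :2, 0] = True        # |B| = 4, overlap 2
        assert dice(a, b) == 0.5

    def test_both_empty_defined_as_one(self):
        e = np.zeros((3, 3, 1), bool)
        assert dice(e, e) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            dice(np.zeros((3, 3, 1), bool), np.zeros((4, 4, 1), bool))


class TestConfusion:
    def test_single_cell(self):
        cm = confusion([2] * 10, [2] * 10)
        assert cm.counts[2, 2] == 10 and cm.n == 10

    def test_direct_tally(self):
        cm = confusion([0, 0, 4], [0, 1, 3])
        assert cm.counts[0, 0] == 1 and cm.counts[0, 1] == 1 and cm.counts[4, 3] == 1
        assert cm.n == 3

    def test_row_sums_are_reference_frequencies(self):
        rng = np.random.default_rng(5)
        ref = rng.integers(0, 5, 100)
        pred = rng.integers(0, 5, 100)
        cm = confusion(ref, pred)
        np.testing.assert_array_equal(cm.counts.sum(axis=1), np.bincount(ref, minlength=5))

    def test_out_of_range_grade_rejected(self):
        with pytest.raises(ValueError, match="grades outside"):
            confusion([0, 5], [0, 0])


class TestCohenKappa:
    def test_perfect_diagonal_is_one(self):
        assert cohen_kappa(_cm(np.diag([3, 4, 5, 6, 7]))).kappa == pytest.approx(1.0)

    def test_uniform_2x2_is_zero(self):
        assert cohen_kappa(_cm([[10, 10], [10, 10]])).kappa == pytest.approx(0.0)

    def test_worked_example_kappa_0_6(self):
        # p_o = 0.80, p_e = 0.5 -> (0.80-0.50)/0.50 = 0.6
        assert cohen_kappa(_cm([[45, 5], [15, 35]])).kappa == pytest.approx(0.6)

    def test_degenerate_marginals_raise(self):
        with pytest.raises(ValueError, match="undefined"):
            cohen_kappa(_cm([[50]]))

    def test_se_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa
        rng = np.random.default_rng(2)
        for _ in range(20):
            counts = rng.integers(0, 30, (5, 5))
            mine = cohen_kappa(ConfusionMatrix5(counts))
            ref = cohens_kappa(counts, return_results=True)
            assert mine.kappa == pytest.approx(float(ref.kappa), abs=1e-12)
            assert mine.se == pytest.approx(float(ref.var_kappa) ** 0.5, abs=1e-12)

    def test_bootstrap_ci_brackets_asymptotic(self):
        rng = np.random.default_rng(9)
        ref = rng.integers(0, 5, 300)
        pred = np.where(rng.random(300) < 0.7, ref, rng.integers(0, 5, 300))
        asym = cohen_kappa(confusion(ref, pred))
        boot = bootstrap_kappa(ref, pred, n_boot=500, seed=1)
        assert boot.ci_low == pytest.approx(asym.ci_low, abs=0.05)
        assert boot.ci_high == pytest.approx(asym.ci_high, abs=0.05)

    def test_kappa_never_exceeds_one(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            counts = rng.integers(0, 25, (5, 5))
            cm = ConfusionMatrix5(counts)
            assert cohen_kappa(cm).kappa <= 1.0


class TestPerCategoryMetrics:
    def test_perfect_diagonal_all_ones(self):
        table = per_category_metrics(_cm(np.diag([2, 3, 4, 5, 6])))
        assert (table.to_numpy() == 1.0).all()

    def test_absent_grade_sensitivity_unavailable_specificity_one(self):
        table = per_category_metrics(_cm(np.diag([5, 5, 5, 5, 0])))
        row = table.loc["IV"]
        assert math.isnan(row["sensitivity"])
        assert row["specificity"] == 1.0

    def test_hand_built_three_grade_example(self):
        table = per_category_metrics(_cm([[8, 2, 0], [1, 6, 3], [0, 2, 8]]))
        row = table.loc["0"]
        assert row["sensitivity"] == pytest.approx(0.8)
        assert row["ppv"] == pytest.approx(8 / 9)
        assert row["f1"] == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))


class TestAgreementSummary:
    def test_perfect_diagonal(self):
        s = agreement_summary(_cm(np.diag([1, 2, 3, 4, 5])))
        assert s["exact"] == 1.0 and s["within_one"] == 0.0 and s["beyond_one"] == 0.0

    def test_uniform_overestimation_by_one(self):
        counts = np.zeros((5, 5), int)
        for g in range(4):
            counts[g, g + 1] = 5
        s = agreement_summary(ConfusionMatrix5(counts))
        assert s["within_one"] == 1.0 and s["over_estimated"] == 1.0

    def test_embedded_2x2_tally(self):
        s = agreement_summary(_cm([[3, 1], [1, 3]]))
        assert s["exact"] == pytest.approx(0.75)
        assert s["within_one"] == pytest.approx(0.25)

    def test_fractions_partition_unity(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            s = agreement_summary(ConfusionMatrix5(rng.integers(0, 20, (5, 5))))
            assert s["exact"] + s["within_one"] + s["beyond_one"] == pytest.approx(1.0)


class TestPresenceMetrics:
    def test_perfect_predictions(self):
        assert presence_metrics([0, 5, 10], [0, 5, 10]) == (1.0, 1.0)

    def test_all_zero_reference_sensitivity_unavailable(self):
        sens, spec = presence_metrics([0, 0], [0, 0])
        assert math.isnan(sens) and spec == 1.0

    def test_hand_tally(self):
        sens, spec = presence_metrics([0, 0, 5, 10], [0, 3, 5, 0])
        assert sens == 0.5 and spec == 0.5


class TestEvalReport:
    def test_report_bundles_consistent_numbers(self):
        ref = [0, 0, 50, 150, 600, 1200, 90, 0]
        pred = [0, 10, 50, 180, 500, 1500, 90, 0]
        rep = build_eval_report(ref, pred)
        d = rep.to_dict()
        assert d["n"] == 8
        assert d["agreement"]["exact"] == pytest.approx(
            np.trace(rep.confusion_matrix.counts) / 8)
        assert d["presence"]["specificity"] == pytest.approx(2 / 3)

    def test_degenerate_kappa_noted_not_raised(self):
        rep = build_eval_report([0, 0, 0], [0, 0, 0])
        assert rep.kappa is None
        assert any("kappa" in n for n in rep.notes)
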