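"""Accuracy/PPV identity, top-fraction curves, O/E propensity tables."""

import math

import numpy as np
import pytest

from cdpred.constraints import PairPrediction
from cdpred.evaluation import (
    StructureEvaluation,
    _pair_type_fractions,
    accuracy,
    positive_predictive_value,
    propensity,
    rank_predictions,
    topk_curve,
)


def _preds(pairs, bin_name="contact", scores=None):
    scores = scores or [0.9] * len(pairs)
    return [PairPrediction(i, j, bin_name, s) for (i, j), s in zip(pairs, scores)]


class TestAccuracy:
    def test_seven_of_ten(self):
        pairs = [(1, 10 + k) for k in range(10)]
        truth = {p: ("contact" if k < 7 else "8-13") for k, p in enumerate(pairs)}
        rep = accuracy(_preds(pairs), truth)
        assert rep.n_predictions == 10 and rep.n_correct == 7
        assert rep.accuracy_percent == pytest.approx(70.0)

    def test_all_correct(self):
        pairs = [(1, 8), (2, 12)]
        rep = accuracy(_preds(pairs), {p: "contact" for p in pairs})
        assert rep.accuracy_percent == 100.0

    def test_equals_ppv(self, rng):
        # no negative predictions are ever emitted, so accuracy == PPV
        pairs = [(int(i), int(i) + 7) for i in rng.integers(1, 50, 30)]
        pairs = list(dict.fromkeys(pairs))
        truth = {
            p: ("contact" if rng.random() < 0.5 else "13-18") for p in pairs
        }
        preds = _preds(pairs)
        rep = accuracy(preds, truth)
        assert rep.accuracy_percent / 100 == pytest.approx(
            positive_predictive_value(preds, truth)
        )

    def test_unknown_labels_excluded(self):
        pairs = [(1, 10), (2, 11), (3, 12)]
        truth = {(1, 10): "contact", (2, 11): "unknown", (3, 12): "contact"}
        rep = accuracy(_preds(pairs), truth)
        assert rep.n_predictions == 2 and rep.n_correct == 2

    def test_empty_report_flagged_not_zero(self):
        rep = accuracy([], {})
        assert rep.empty
        with pytest.raises(ValueError):
            _ = rep.accuracy_percent


class TestTopkCurve:
    def test_perfect_ranking_constant_100(self):
        pairs = [(1, 10 + k) for k in range(30)]
        scores = list(np.linspace(1.0, 0.5, 30))
        truth = {p: "contact" for p in pairs}
        points = topk_curve(_preds(pairs, scores=scores), truth, L=20)
        for pt in points:
            assert pt.report.accuracy_percent == 100.0

    def test_hand_built_example_brute_force(self):
        # 12 scored pairs, truth known; L = 10
        pairs = [(1, 7 + k) for k in range(12)]
        scores = [0.95, 0.9, 0.85, 0.8, 0.75, 0.7, 0.65, 0.6, 0.55, 0.5, 0.45, 0.4]
        correct = [True, False, True, True, True, False, True, False, True, True, False, True]
        truth = {p: ("contact" if c else "8-13") for p, c in zip(pairs, correct)}
        points = topk_curve(
            _preds(pairs, scores=scores), truth, L=10, fractions=(0.2, 0.5, 1.0)
        )
        # brute force: top floor(f*10) of the score-ordered list
        for pt, f in zip(points, (0.2, 0.5, 1.0)):
            k = math.floor(f * 10)
            expected = 100.0 * sum(correct[:k]) / k
            assert pt.report.accuracy_percent == pytest.approx(expected)

    def test_prefix_consistency(self, rng):
        pairs = [(1, 8 + k) for k in range(40)]
        scores = list(rng.random(40))
        truth = {p: ("contact" if rng.random() < 0.5 else "8-13") for p in pairs}
        preds = _preds(pairs, scores=scores)
        pts = topk_curve(preds, truth, L=20, fractions=(0.5, 1.0, 1.5))
        ranked = rank_predictions(preds)
        for pt in pts:
            subset = ranked[: pt.k]
            rep = accuracy(subset, truth)
            assert rep.n_correct == pt.report.n_correct

    def test_truncation_flagged(self):
        pairs = [(1, 8)]
        truth = {(1, 8): "contact"}
        pts = topk_curve(_preds(pairs), truth, L=20, fractions=(1.5,))
        assert pts[0].truncated and pts[0].k == 1

    def test_random_scores_near_base_rate(self, rng):
        # Monte-Carlo: with random scores the curve hovers at the base rate
        pairs = [(1, 8 + k) for k in range(100)]
        labels = ["contact"] * 50 + ["8-13"] * 50
        truth = dict(zip(pairs, labels))
        accs = []
        for _ in range(50):
            scores = list(rng.random(100))
            pts = topk_curve(_preds(pairs, scores=scores), truth, L=40,
                             fractions=(1.0,))
            accs.append(pts[0].report.accuracy_percent)
        assert abs(np.mean(accs) - 50.0) < 5.0


def _structure_eval(sequence, truth_pairs, correct_pairs, wrong_pairs, bin_name):
    truth = {p: bin_name for p in truth_pairs}
    for p in wrong_pairs:
        truth.setdefault(p, "none-bin")
    preds = _preds(correct_pairs + wrong_pairs, bin_name, [0.9] * (len(correct_pairs) + len(wrong_pairs)))
    return StructureEvaluation(sequence=sequence, truth=truth, predictions=preds)


class TestPropensity:
    def test_fraction_tables_normalised(self, rng):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        pairs = [(int(i), int(i) + 7) for i in rng.integers(1, 50, 40)]
        fracs = _pair_type_fractions(pairs, seq)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_predictions_give_unit_oe(self):
        # every truth pair correctly predicted -> O == E -> O/E == 1
        seq = "AVLIFWAVLIFWAVLIFWAV" * 2
        truth_pairs = [(i, i + 8) for i in range(1, 25)]
        s = _structure_eval(seq, truth_pairs, truth_pairs, [], "8-13")
        table = propensity([s], "8-13", threshold=0.7)
        vals = table.oe_mean[~np.isnan(table.oe_mean)]
        np.testing.assert_allclose(vals, 1.0, atol=1e-12)
        logs = table.log2_oe[~np.isnan(table.log2_oe)]
        np.testing.assert_allclose(logs, 0.0, atol=1e-12)

    def test_single_type_structure(self):
        seq = "A" * 20 + "V" * 20
        # all truth pairs are (A, V) and all correctly predicted
        truth_pairs = [(i, i + 25) for i in range(1, 14)]
        s = _structure_eval(seq, truth_pairs, truth_pairs, [], "13-18")
        table = propensity([s], "13-18", threshold=0.7)
        a, v = 0, 17  # alphabet indices of A and V
        assert table.oe_mean[a, v] == pytest.approx(1.0)

    def test_two_structure_counting_oracle(self):
        # structure 1: types AA and AV in truth; only AA correctly predicted
        seq1 = "A" * 30 + "V" * 10
        t1 = [(1, 10), (2, 12), (3, 35)]     # AA, AA, AV
        c1 = [(1, 10)]                        # one AA correct
        s1 = _structure_eval(seq1, t1, c1, [], "contact")
        # structure 2: all AV pairs, all correct
        seq2 = "A" * 20 + "V" * 20
        t2 = [(1, 25), (2, 30)]
        s2 = _structure_eval(seq2, t2, t2, [], "contact")
        table = propensity([s1, s2], "contact", threshold=0.7)
        a, v = 0, 17
        # brute force: s1 E_AA=2/3, O_AA=1 -> 1.5 ; s2 has no AA truth
        assert table.oe_mean[a, a] == pytest.approx(1.5)
        # AA wrong in s1 contributes E_AV=1/3, O_AV=0 -> 0; s2 gives 1.0
        assert table.oe_mean[a, v] == pytest.approx((0.0 + 1.0) / 2)
        assert table.n_structures[a, v] == 2

    def test_skips_structures_without_correct_predictions(self):
        seq = "A" * 40
        t = [(1, 10), (2, 12)]
        s = _structure_eval(seq, t, [], [(5, 20)], "contact")
        table = propensity([s], "contact", threshold=0.7)
        assert table.skipped_structures == [0]

    def test_threshold_filters_predictions(self):
        seq = "A" * 40
        t = [(1, 10)]
        preds = [PairPrediction(1, 10, "contact", 0.65)]  # below 0.7
        s = StructureEvaluation(seq, {p: "contact" for p in t}, preds)
        table = propensity([s], "contact", threshold=0.7)
        assert table.skipped_structures == [0]

    def test_type_exchange_symmetry(self):
        seq = "A" * 20 + "V" * 20
        t = [(1, 25), (2, 30)]
        s = _structure_eval(seq, t, t, [], "contact")
        table = propensity([s], "contact")
        np.testing.assert_array_equal(
            np.nan_to_num(table.oe_mean), np.nan_to_num(table.oe_mean.T)
        )

    def test_precision_per_pair_type(self):
        seq = "A" * 40
        t = [(1, 10), (2, 12)]
        s = _structure_eval(seq, t, [(1, 10)], [(5, 20)], "contact")
        table = propensity([s], "contact", threshold=0.7)
        assert table.precision[0, 0] == pytest.approx(0.5)  # 1 correct of 2 AA preds

    def test_pooled_variant_runs(self):
        seq = "A" * 20 + "V" * 20
        t = [(1, 25), (2, 30)]
        s = _structure_eval(seq, t, t, [], "contact")
        table = propensity([s], "contact", pooled=True)
        a, v = 0, 17
        assert table.oe_mean[a, v] == pytest.approx(1.0)
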