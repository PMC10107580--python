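"""Pair-level evaluation: classification rules, metrics, edge cases."""

import numpy as np
import pytest

from acqsar.mmp import AC, NON_AC
from acqsar.models import OracleModel
from acqsar.paireval import (
    AggregateMetric,
    PairClassifierConfig,
    aggregate,
    classify_pair_both_unknown,
    classify_pair_one_known,
    classify_pd,
    score_trial,
)
from acqsar.splitting import CrossValidationPlan, make_split_instances


@pytest.fixture(scope="module")
def split_and_labels(small_noise_free_run):
    run = small_noise_free_run
    instances = make_split_instances(run.compounds, run.mmps, CrossValidationPlan(m=1, k=2, seeds=(0,)))
    return run, instances


class TestClassificationRules:
    @pytest.mark.parametrize("diff,expected", [(1.4, NON_AC), (1.5, NON_AC), (1.5000001, AC), (2.7, AC)])
    def test_one_known_threshold(self, diff, expected):
        assert classify_pair_one_known(5.0, 5.0 + diff) == expected
        assert classify_pair_one_known(5.0 + diff, 5.0) == expected

    @pytest.mark.parametrize("p1,p2,expected", [(5.0, 5.0, NON_AC), (4.0, 6.0, AC), (0.0, 1.5, NON_AC)])
    def test_both_unknown_threshold(self, p1, p2, expected):
        assert classify_pair_both_unknown(p1, p2) == expected
        assert classify_pair_both_unknown(p2, p1) == expected  # symmetry

    def test_boundary_is_non_ac_in_both_modes(self):
        cfg = PairClassifierConfig(d_crit=1.5)
        assert classify_pair_one_known(0.0, 1.5, cfg) == NON_AC
        assert classify_pair_both_unknown(0.0, 1.5, cfg) == NON_AC

    def test_custom_threshold(self):
        cfg = PairClassifierConfig(d_crit=0.5)
        assert classify_pair_both_unknown(0.0, 0.6, cfg) == AC

    def test_pd_larger_prediction_wins(self):
        assert classify_pd("a", "b", 7.1, 6.9) == "a"
        assert classify_pd("a", "b", 6.9, 7.1) == "b"

    def test_pd_tie_is_undefined(self):
        assert classify_pd("a", "b", 1.0, 1.0) is None


class TestScoreTrial:
    def test_oracle_reaches_degenerate_optimum(self, toy_split):
        labels, inst = toy_split
        preds = dict(labels)  # pass-through: predictions equal true labels
        rep = score_trial(preds, labels, inst)
        assert rep.qsar_mae == 0.0
        for tag in ("inter", "test", "cores"):
            ms = rep.pair_sets[tag]
            assert ms.n_pairs > 0
            assert ms.mcc == pytest.approx(1.0)
            assert ms.sensitivity == pytest.approx(1.0)
            assert ms.precision == pytest.approx(1.0)
            assert ms.pd_accuracy == pytest.approx(1.0)
            assert ms.pd_accuracy_predicted_ac == pytest.approx(1.0)

    def test_all_negative_predictor_edge_case(self, toy_split):
        """A constant predictor makes no positive AC calls: MCC is recorded
        as 0 and the ill-defined precision as missing."""
        labels, inst = toy_split
        # predictions stay within d_crit of every known label and of each
        # other, so no pair in any set is called an AC
        preds = {"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4, "e": 0.5, "f": 2.0, "g": 2.5, "h": 2.0}
        rep = score_trial(preds, labels, inst)
        for tag in ("inter", "test", "cores"):
            ms = rep.pair_sets[tag]
            assert ms.mcc == 0.0
            assert ms.precision is None
            assert ms.sensitivity == 0.0

    def test_mcc_against_hand_expanded_formula(self):
        """Confusion counts TP=2 FP=1 FN=3 TN=14, expanded by hand."""
        from sklearn.metrics import matthews_corrcoef

        y_true = [1] * 2 + [0] * 1 + [1] * 3 + [0] * 14
        y_pred = [1] * 2 + [1] * 1 + [0] * 3 + [0] * 14
        tp, fp, fn, tn = 2, 1, 3, 14
        expected = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert matthews_corrcoef(y_true, y_pred) == pytest.approx(expected)

    def test_missing_test_predictions_rejected(self, split_and_labels):
        run, instances = split_and_labels
        labels = run.compounds.labels()
        inst = instances[0]
        incomplete = {c: labels[c] for c in sorted(inst.d_test)[1:]}
        with pytest.raises(KeyError):
            score_trial(incomplete, labels, inst)

    def test_known_label_pd_variant(self, toy_split):
        labels, inst = toy_split
        preds = dict(labels)
        literal = score_trial(preds, labels, inst, PairClassifierConfig(use_known_label_for_pd=False))
        known = score_trial(preds, labels, inst, PairClassifierConfig(use_known_label_for_pd=True))
        # with oracle predictions the two variants coincide
        assert literal.pair_sets["inter"].pd_accuracy == known.pair_sets["inter"].pd_accuracy


class TestAggregate:
    def _trial(self, run, inst, preds, labels):
        return score_trial(preds, labels, inst)

    def test_identical_trials_have_zero_std(self, toy_split):
        labels, inst = toy_split
        preds = dict(labels)
        reports = [score_trial(preds, labels, inst)] * 3
        agg = aggregate(reports)
        assert agg.qsar_mae.mean == 0.0 and agg.qsar_mae.std == 0.0
        assert agg.n_trials == 3

    def test_mean_of_two_values(self):
        from acqsar.paireval import _aggregate

        m = _aggregate([0.2, 0.4])
        assert m.mean == pytest.approx(0.3)
        assert m.n == 2

    def test_missing_values_excluded_but_counted(self):
        from acqsar.paireval import _aggregate

        m = _aggregate([0.5, None, 0.7, None])
        assert m.mean == pytest.approx(0.6)
        assert m.n == 2
        empty = _aggregate([None, None])
        assert empty.mean is None and empty.n == 0

    def test_error_bar_convention_is_one_std_half_width(self):
        m = AggregateMetric(mean=0.5, std=0.1, n=6)
        assert m.error_bar == 0.1
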