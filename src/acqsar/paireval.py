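"""Pair-level activity-cliff and potency-direction classification metrics.

Any QSAR model f can be repurposed as a pair classifier: predict the
activity labels of both compounds of a matched pair and threshold the
absolute predicted difference at ``d_crit`` (default 1.5 log10 units, the
midpoint between the non-AC interval [0, 1] and the AC interval [2, inf)).
On pairs with one compound in the training set (``M_inter``) the known label
replaces that compound's prediction in the AC rule; on fully held-out pairs
both labels are predicted. A difference exactly equal to ``d_crit`` is
classified non-AC in both modes.

Per (seed, fold) trial the report carries: the regression MAE over the whole
compound test set; AC classification (positive class = AC) as Matthews
correlation coefficient, sensitivity and precision per pair set; and
potency-direction accuracy on the full pair set and on the subset the same
model predicted to be ACs. Edge cases follow the conventions for imbalanced
pair classification: with no positive predictions the MCC is recorded as 0
and the ill-defined precision as missing, and missing values are excluded
from (but counted alongside) the aggregate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, matthews_corrcoef

from .curation import CompoundSet
from .mmp import AC, NON_AC, MMPSet
from .splitting import SplitInstance

D_CRIT_DEFAULT = 1.5

PAIR_SET_TAGS = ("inter", "test", "cores")


@dataclass(frozen=True)
class PairClassifierConfig:
    """Threshold configuration for AC classification from predicted labels."""

    d_crit: float = D_CRIT_DEFAULT
    use_known_label_for_pd: bool = False  # literal rule: PD always compares predictions

    def __post_init__(self) -> None:
        if self.d_crit <= 0:
            raise ValueError("d_crit must be positive")


@dataclass(frozen=True)
class PairPrediction:
    id_1: str
    id_2: str
    mmp_set_tag: str
    predicted_class: str
    predicted_direction: str | None  # None encodes an exact tie (scored incorrect)
    true_class: str
    true_direction: str | None


def classify_pair_one_known(a_known: float, f_pred: float, config: PairClassifierConfig = PairClassifierConfig()) -> str:
    """AC iff |a_known - f_pred| > d_crit (boundary -> non-AC)."""
    return AC if abs(a_known - f_pred) > config.d_crit else NON_AC


def classify_pair_both_unknown(f_pred1: float, f_pred2: float, config: PairClassifierConfig = PairClassifierConfig()) -> str:
    """AC iff |f_pred1 - f_pred2| > d_crit; symmetric in its arguments."""
    return AC if abs(f_pred1 - f_pred2) > config.d_crit else NON_AC


def classify_pd(id_1: str, id_2: str, pred1: float, pred2: float) -> str | None:
    """The compound with the larger predicted label; exact tie -> None."""
    if pred1 == pred2:
        return None
    return id_1 if pred1 > pred2 else id_2


def predict_pairs(
    predictions: dict[str, float],
    labels: dict[str, float],
    split: SplitInstance,
    config: PairClassifierConfig = PairClassifierConfig(),
) -> list[PairPrediction]:
    """Classify every pair of M_inter, M_test and M_cores.

    ``predictions`` maps compound_id -> f(compound); ``labels`` maps
    compound_id -> true activity label. On M_inter the known (training-side)
    label enters the AC rule in place of that compound's prediction.
    """
    out: list[PairPrediction] = []
    for tag, mset in (("inter", split.m_inter), ("test", split.m_test), ("cores", split.m_cores)):
        for r in mset:
            p1, p2 = predictions[r.id_1], predictions[r.id_2]
            if tag == "inter":
                if r.id_1 in split.d_train:
                    known_id, unknown_id = r.id_1, r.id_2
                else:
                    known_id, unknown_id = r.id_2, r.id_1
                cls = classify_pair_one_known(labels[known_id], predictions[unknown_id], config)
                if config.use_known_label_for_pd:
                    pd_pred = classify_pd(
                        known_id, unknown_id, labels[known_id], predictions[unknown_id]
                    )
                else:
                    pd_pred = classify_pd(r.id_1, r.id_2, p1, p2)
            else:
                cls = classify_pair_both_unknown(p1, p2, config)
                pd_pred = classify_pd(r.id_1, r.id_2, p1, p2)
            out.append(
                PairPrediction(
                    id_1=r.id_1,
                    id_2=r.id_2,
                    mmp_set_tag=tag,
                    predicted_class=cls,
                    predicted_direction=pd_pred,
                    true_class=r.ac_class,
                    true_direction=r.pd_label,
                )
            )
    return out


@dataclass
class PairSetMetrics:
    """AC- and PD-metrics on one pair set of one trial."""

    n_pairs: int
    mcc: float | None
    sensitivity: float | None
    precision: float | None          # None when ill-defined (no positive predictions)
    pd_accuracy: float | None
    pd_accuracy_predicted_ac: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrialReport:
    """All metrics of one (seed, fold) trial."""

    seed_index: int
    fold_index: int
    qsar_mae: float
    pair_sets: dict[str, PairSetMetrics]


def _ac_metrics(y_true: list[str], y_pred: list[str]) -> tuple[float, float | None, float | None]:
    """(MCC, sensitivity, precision) with AC as the positive class.

    No positive predictions -> MCC recorded as 0, precision as missing.
    No actual positives -> sensitivity missing.
    """
    yt = np.array([c == AC for c in y_true])
    yp = np.array([c == AC for c in y_pred])
    if yp.sum() == 0:
        mcc = 0.0
        precision = None
    else:
        mcc = float(matthews_corrcoef(yt, yp))
        tp = int(np.sum(yt & yp))
        precision = tp / int(yp.sum())
    sensitivity = float(np.sum(yt & yp) / yt.sum()) if yt.sum() > 0 else None
    return mcc, sensitivity, precision


def _pd_accuracy(preds: list[PairPrediction]) -> float | None:
    """Fraction of pairs whose predicted direction matches the true one.

    Predicted ties count as incorrect; pairs with an undefined true
    direction (tied true labels) are excluded."""
    scored = [p for p in preds if p.true_direction is not None]
    if not scored:
        return None
    correct = sum(1 for p in scored if p.predicted_direction == p.true_direction)
    return correct / len(scored)


def score_pair_set(preds: list[PairPrediction]) -> PairSetMetrics:
    if not preds:
        return PairSetMetrics(0, None, None, None, None, None)
    mcc, sens, prec = _ac_metrics([p.true_class for p in preds], [p.predicted_class for p in preds])
    predicted_acs = [p for p in preds if p.predicted_class == AC]
    return PairSetMetrics(
        n_pairs=len(preds),
        mcc=mcc,
        sensitivity=sens,
        precision=prec,
        pd_accuracy=_pd_accuracy(preds),
        pd_accuracy_predicted_ac=_pd_accuracy(predicted_acs) if predicted_acs else None,
    )


def score_trial(
    predictions: dict[str, float],
    labels: dict[str, float],
    split: SplitInstance,
    config: PairClassifierConfig = PairClassifierConfig(),
) -> TrialReport:
    """Score one trained model on one SplitInstance.

    The MAE is measured over ALL compounds of the test set, not only those
    involved in MMPs."""
    missing = split.d_test - predictions.keys()
    if missing:
        raise KeyError(f"predictions must cover d_test; missing {len(missing)} compounds")
    mae = float(
        np.mean([abs(predictions[cid] - labels[cid]) for cid in sorted(split.d_test)])
    )
    pair_preds = predict_pairs(predictions, labels, split, config)
    report = TrialReport(
        seed_index=split.seed_index,
        fold_index=split.fold_index,
        qsar_mae=mae,
        pair_sets={
            tag: score_pair_set([p for p in pair_preds if p.mmp_set_tag == tag])
            for tag in PAIR_SET_TAGS
        },
    )
    return report


@dataclass
class AggregateMetric:
    """Mean/std of one metric over the trials where it was defined."""

    mean: float | None
    std: float | None
    n: int

    @property
    def error_bar(self) -> float | None:
        """Half-width convention: the total bar length is 2 * std."""
        return self.std if self.std is not None else None


@dataclass
class AggregateReport:
    """Mean and standard deviation per metric over the m*k trials.

    Missing per-trial values (ill-defined precisions, empty pair sets) are
    excluded from the averages; ``n`` makes the exclusions auditable.
    """

    n_trials: int
    qsar_mae: AggregateMetric
    pair_sets: dict[str, dict[str, AggregateMetric]]


def _aggregate(values: list[float | None]) -> AggregateMetric:
    present = [v for v in values if v is not None]
    if not present:
        return AggregateMetric(mean=None, std=None, n=0)
    arr = np.array(present, dtype=float)
    std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return AggregateMetric(mean=float(arr.mean()), std=std, n=len(arr))


def aggregate(reports: list[TrialReport]) -> AggregateReport:
    if not reports:
        raise ValueError("need at least one trial report")
    metric_names = ("mcc", "sensitivity", "precision", "pd_accuracy", "pd_accuracy_predicted_ac")
    pair_sets = {
        tag: {
            name: _aggregate([getattr(r.pair_sets[tag], name) for r in reports])
            for name in metric_names
        }
        for tag in PAIR_SET_TAGS
    }
    return AggregateReport(
        n_trials=len(reports),
        qsar_mae=_aggregate([r.qsar_mae for r in reports]),
        pair_sets=pair_sets,
    )


def reports_to_frame(reports: list[TrialReport], model_tag: str = "") -> pd.DataFrame:
    """Tidy long-format table: one row per (trial, pair set, metric)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "model_tag": model_tag,
                "pair_set": "compounds",
                "metric": "qsar_mae",
                "trial_n": r.seed_index,
                "trial_l": r.fold_index,
                "value": r.qsar_mae,
            }
        )
        for tag, ms in r.pair_sets.items():
            for name, value in ms.as_dict().items():
                if name == "n_pairs":
                    continue
                rows.append(
                    {
                        "model_tag": model_tag,
                        "pair_set": tag,
                        "metric": name,
                        "trial_n": r.seed_index,
                        "trial_l": r.fold_index,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
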