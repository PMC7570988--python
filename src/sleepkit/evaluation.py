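"""Per-stage agreement between predicted and reference hypnograms.

Each stage is evaluated one-vs-rest: the stage is the positive class and the
other three are pooled as negative, giving TP/FP/FN/TN counts per stage and
the derived accuracy, precision, recall and F1 (all in percent). One-vs-rest
is the only framing in which a per-stage *accuracy* with a TN term is
coherent. Ratios with a zero denominator are reported as NaN (missing), never
as 0, so averages are not silently deflated.

Reference records may contain movement ("M") or unscored ("?") epochs; those
are dropped pairwise (the predicted epoch at the same position is discarded
too) before counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan
from typing import NamedTuple

import numpy as np
import pandas as pd

from .stages import Hypnogram, Stage, merge_reference_stages

__all__ = [
    "ConfusionCounts",
    "StageMetrics",
    "confusion_counts",
    "stage_metrics",
    "evaluation_report",
    "f1_from_precision_recall",
    "filter_unscored",
]

#: reference labels excluded pairwise before evaluation
UNSCORED_LABELS = {"M", "?", "MOVEMENT TIME", "SLEEP STAGE ?"}


class ConfusionCounts(NamedTuple):
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class StageMetrics:
    """One-vs-rest counts and percent metrics for a single stage."""

    stage: Stage
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float


def confusion_counts(pred: Hypnogram, truth: Hypnogram, stage: Stage) -> ConfusionCounts:
    """One-vs-rest confusion counts treating ``stage`` as the positive class."""
    if len(pred) != len(truth):
        raise ValueError(
            f"length mismatch: predicted {len(pred)} vs reference {len(truth)} epochs"
        )
    p = pred.stages == int(stage)
    t = truth.stages == int(stage)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def stage_metrics(counts: ConfusionCounts, stage: Stage = Stage.WAKE) -> StageMetrics:
    """Accuracy/precision/recall/F1 (percent) from one-vs-rest counts."""
    tp, fp, fn, tn = counts
    total = tp + fp + fn + tn
    if total <= 0:
        raise ValueError("confusion counts sum to zero")
    accuracy = 100.0 * (tp + tn) / total
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else nan
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else nan
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        f1 = nan
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return StageMetrics(stage, tp, fp, fn, tn, accuracy, precision, recall, f1)


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (inputs and output in percent)."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return nan
    return 2.0 * precision * recall / (precision + recall)


def filter_unscored(pred_stages, truth_labels) -> tuple[np.ndarray, list]:
    """Drop positions whose reference label is movement/unscored, pairwise."""
    pred_arr = np.asarray(pred_stages)
    labels = list(truth_labels)
    if pred_arr.size != len(labels):
        raise ValueError("predicted and reference sequences differ in length")
    keep = [str(lab).strip().upper() not in UNSCORED_LABELS for lab in labels]
    keep_arr = np.asarray(keep, dtype=bool)
    return pred_arr[keep_arr], [lab for lab, k in zip(labels, keep) if k]


def evaluation_report(pred: Hypnogram, truth) -> pd.DataFrame:
    """Four metrics × four stages table for one predicted/reference pair.

    ``truth`` may be a four-stage ``Hypnogram`` or a raw R&K/AASM label
    sequence (possibly with movement/unscored epochs, which are removed
    pairwise and the remainder merged to four stages).
    """
    if isinstance(truth, Hypnogram):
        truth_hyp, pred_hyp = truth, pred
    else:
        kept_pred, kept_labels = filter_unscored(pred.stages, truth)
        if len(kept_labels) == 0:
            raise ValueError("no scorable epochs after removing movement/unscored")
        truth_hyp = merge_reference_stages(kept_labels, epoch_seconds=pred.epoch_seconds)
        pred_hyp = Hypnogram(kept_pred, epoch_seconds=pred.epoch_seconds)
    rows = {}
    for stage in Stage:
        m = stage_metrics(confusion_counts(pred_hyp, truth_hyp, stage), stage)
        rows[stage.name.capitalize()] = {
            "accuracy": m.accuracy,
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
        }
    return pd.DataFrame(rows).reindex(["accuracy", "precision", "recall", "f1"])
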