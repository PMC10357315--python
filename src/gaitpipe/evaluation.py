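"""Evaluation statistics: classification, segmentation and parameter error.

Three evaluation layers, mirroring the stages of the pipeline:

* per-frame classification — a 5x5 confusion matrix, one-vs-rest
  precision / recall / F1 per class, and support-weighted aggregates;
* event localization — the fraction of true gait-semantic events matched by
  a predicted event of the same type within a frame tolerance ``t``
  (inclusive, |j - j'| <= t; greedy in-order matching per event type, each
  prediction consumed at most once);
* parameter accuracy — per-parameter relative error in percent,
  |V_pred - V_true| / V_true * 100, with its mean and population SD over
  the parameter set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gait_parameters import PARAMETER_NAMES, GaitParameters
from .semantics_gpm import EventType, GaitSemanticEvent
from .skeleton_io import FrameLabel

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "SegmentationScore",
    "ParameterErrorReport",
    "classification_report",
    "segmentation_accuracy",
    "parameter_error",
]

log = logging.getLogger(__name__)

_CLASSES: tuple[FrameLabel, ...] = tuple(FrameLabel)


@dataclass
class ConfusionMatrix:
    """Counts indexed (true, predicted) in FrameLabel order S, L, D, R, T."""

    counts: np.ndarray
    classes: tuple[FrameLabel, ...] = _CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be a nonnegative k x k count table")


@dataclass
class ClassificationReport:
    confusion: ConfusionMatrix
    precision: dict[FrameLabel, float]
    recall: dict[FrameLabel, float]
    f1: dict[FrameLabel, float]
    support: dict[FrameLabel, int]
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float


def classification_report(
    true_labels: Sequence[FrameLabel], predicted_labels: Sequence[FrameLabel]
) -> ClassificationReport:
    """One-vs-rest metrics per class plus support-weighted aggregates.

    Classes absent from the truth get support 0 and weight 0; a class with
    no predicted positives gets precision 0 (and analogously recall).
    """
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label streams differ in length")
    if len(true_labels) == 0:
        raise ValueError("empty label streams")
    index = {c: i for i, c in enumerate(_CLASSES)}
    counts = np.zeros((len(_CLASSES), len(_CLASSES)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    cm = ConfusionMatrix(counts)

    precision: dict[FrameLabel, float] = {}
    recall: dict[FrameLabel, float] = {}
    f1: dict[FrameLabel, float] = {}
    support: dict[FrameLabel, int] = {}
    for c, i in index.items():
        tp = counts[i, i]
        fp = counts[:, i].sum() - tp
        fn = counts[i, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        precision[c] = float(p)
        recall[c] = float(r)
        f1[c] = float(2 * p * r / (p + r)) if p + r > 0 else 0.0
        support[c] = int(counts[i, :].sum())

    total = sum(support.values())
    wp = sum(precision[c] * support[c] for c in _CLASSES) / total
    wr = sum(recall[c] * support[c] for c in _CLASSES) / total
    wf = sum(f1[c] * support[c] for c in _CLASSES) / total
    return ClassificationReport(
        confusion=cm,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        weighted_precision=float(wp),
        weighted_recall=float(wr),
        weighted_f1=float(wf),
    )


@dataclass
class SegmentationScore:
    K: int
    matched: int
    t: int
    accuracy: float


def segmentation_accuracy(
    true_events: Sequence[GaitSemanticEvent],
    predicted_events: Sequence[GaitSemanticEvent],
    t: int = 2,
) -> SegmentationScore:
    """Fraction of true events matched within ``t`` frames, per event type.

    Matching is greedy in temporal order within each type: each true event
    takes the earliest unconsumed prediction of its type within tolerance.
    Surplus predictions are ignored; unmatched true events count as misses.
    """
    K = len(true_events)
    if K == 0:
        raise ValueError("segmentation accuracy is undefined without true events")
    matched = 0
    for etype in EventType:
        truths = sorted(e.frame for e in true_events if e.type is etype)
        preds = sorted(e.frame for e in predicted_events if e.type is etype)
        used = [False] * len(preds)
        for j_true in truths:
            for k, j_pred in enumerate(preds):
                if not used[k] and abs(j_pred - j_true) <= t:
                    used[k] = True
                    matched += 1
                    break
    return SegmentationScore(K=K, matched=matched, t=t, accuracy=matched / K)


@dataclass
class ParameterErrorReport:
    N: int
    errors: dict[str, float]  # percent, per parameter
    mean_error: float
    sd_error: float
    excluded: list[str] = field(default_factory=list)


def parameter_error(
    predicted: GaitParameters, truth: GaitParameters
) -> ParameterErrorReport:
    """Relative errors in percent with mean and population SD.

    Parameters whose true value is zero are excluded with a log notice.
    """
    pred = predicted.as_dict()
    true = truth.as_dict()
    errors: dict[str, float] = {}
    excluded: list[str] = []
    for name in PARAMETER_NAMES:
        vg = true[name]
        if vg == 0:
            log.info("excluding parameter %s: zero true value", name)
            excluded.append(name)
            continue
        errors[name] = abs(pred[name] - vg) / abs(vg) * 100.0
    if not errors:
        raise ValueError("no parameters with nonzero truth to evaluate")
    vals = np.array(list(errors.values()))
    return ParameterErrorReport(
        N=len(errors),
        errors=errors,
        mean_error=float(vals.mean()),
        sd_error=float(vals.std()),  # population SD
        excluded=excluded,
    )
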