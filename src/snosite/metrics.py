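"""Sn/Sp/Acc/MCC in both of their equivalent parameterizations.

Performance is book-kept two ways and required to agree:

* miscount form — per-class totals ``N+``, ``N-`` and the miscounts
  ``miss_pos`` (true positives called negative) and ``miss_neg`` (true
  negatives called positive):

      Sn  = 1 - miss_pos / N+
      Sp  = 1 - miss_neg / N-
      Acc = 1 - (miss_pos + miss_neg) / (N+ + N-)
      MCC = (1 - (miss_pos/N+ + miss_neg/N-))
            / sqrt((1 + (miss_neg - miss_pos)/N+) (1 + (miss_pos - miss_neg)/N-))

* confusion form — TP/TN/FP/FN with TP = N+ - miss_pos, FN = miss_pos,
  TN = N- - miss_neg, FP = miss_neg, and the textbook formulas
  Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
  MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

The two are algebraically identical; :func:`dual_check` verifies the identity
numerically.  When an MCC denominator factor is zero (every window called the
same class) the coefficient is defined as 0 — the "no better than random"
limit — in both forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ParameterError, UndefinedMetricError

_POSITIVE_LABELS = frozenset({"positive", "SNO", True, 1})
_NEGATIVE_LABELS = frozenset({"negative", "non-SNO", False, 0})


def _as_bool(label) -> bool:
    if label in _POSITIVE_LABELS:
        return True
    if label in _NEGATIVE_LABELS:
        return False
    raise ParameterError(f"unrecognized class label {label!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    """Class totals and miscounts, with the confusion cells derived."""

    n_pos: int
    n_neg: int
    miss_pos: int
    miss_neg: int

    def __post_init__(self) -> None:
        if not (0 <= self.miss_pos <= self.n_pos and 0 <= self.miss_neg <= self.n_neg):
            raise ParameterError(
                f"miscounts out of range: {self.miss_pos}/{self.n_pos} positive, "
                f"{self.miss_neg}/{self.n_neg} negative"
            )

    @property
    def tp(self) -> int:
        return self.n_pos - self.miss_pos

    @property
    def fn(self) -> int:
        return self.miss_pos

    @property
    def tn(self) -> int:
        return self.n_neg - self.miss_neg

    @property
    def fp(self) -> int:
        return self.miss_neg


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy (all in [0,1]) and MCC in [-1,1]."""

    sn: float
    sp: float
    acc: float
    mcc: float


def from_predictions(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionCounts:
    """Tally miscounts from parallel truth/prediction label lists."""
    if len(true_labels) != len(predicted_labels):
        raise ParameterError(
            f"label lists differ in length: {len(true_labels)} vs {len(predicted_labels)}"
        )
    n_pos = n_neg = miss_pos = miss_neg = 0
    for truth, pred in zip(true_labels, predicted_labels):
        t, p = _as_bool(truth), _as_bool(pred)
        if t:
            n_pos += 1
            miss_pos += not p
        else:
            n_neg += 1
            miss_neg += p
    return ConfusionCounts(n_pos=n_pos, n_neg=n_neg, miss_pos=miss_pos, miss_neg=miss_neg)


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Evaluate the miscount-form metrics (canonical route)."""
    if counts.n_pos == 0 or counts.n_neg == 0:
        raise UndefinedMetricError(
            f"Sn/Sp undefined with class totals n_pos={counts.n_pos}, n_neg={counts.n_neg}"
        )
    npos, nneg = counts.n_pos, counts.n_neg
    mp, mn = counts.miss_pos, counts.miss_neg
    sn = 1.0 - mp / npos
    sp = 1.0 - mn / nneg
    acc = 1.0 - (mp + mn) / (npos + nneg)
    d1 = 1.0 + (mn - mp) / npos
    d2 = 1.0 + (mp - mn) / nneg
    if d1 <= 0.0 or d2 <= 0.0:
        mcc = 0.0
    else:
        mcc = (1.0 - (mp / npos + mn / nneg)) / math.sqrt(d1 * d2)
        mcc = max(-1.0, min(1.0, mcc))  # guard against float overshoot
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def _metrics_from_confusion(counts: ConfusionCounts) -> MetricSet:
    """Evaluate the TP/TN/FP/FN-form metrics (cross-check route)."""
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("Sn/Sp undefined when a class is empty")
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / (tp + fn + tn + fp)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    mcc = max(-1.0, min(1.0, mcc))
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def dual_check(counts: ConfusionCounts, tol: float = 1e-12) -> bool:
    """True iff the two parameterizations agree to ``tol`` on all four metrics."""
    a = compute_metrics(counts)
    b = _metrics_from_confusion(counts)
    return (
        abs(a.sn - b.sn) <= tol
        and abs(a.sp - b.sp) <= tol
        and abs(a.acc - b.acc) <= tol
        and abs(a.mcc - b.mcc) <= tol
    )


def format_report(rows: Sequence[tuple[str, MetricSet]]) -> str:
    """Benchmark-style comparison table: Sn(%), Sp(%), Acc(%), MCC."""
    header = f"{'Predictor':<24}{'Sn(%)':>8}{'Sp(%)':>8}{'Acc(%)':>8}{'MCC':>9}"
    lines = [header]
    for name, m in rows:
        lines.append(
            f"{name:<24}{m.sn * 100:>8.2f}{m.sp * 100:>8.2f}{m.acc * 100:>8.2f}{m.mcc:>9.4f}"
        )
    return "\n".join(lines)
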