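"""Cross-validation, jackknife, and protein-level nitrosylation calls.

Every fold refits the complete pipeline — propensity matrix, scorer and
decision threshold — on the training windows only, so no information from the
held-out fold leaks into the features or the threshold.  Per repeat, held-out
predictions are pooled across the k folds before metrics are computed
(pooling keeps MCC well defined even when a single fold degenerates);
averaging per-fold metrics instead is available behind ``pool_folds=False``.

Repeat ``r`` shuffles with derived seed ``plan.seed + r``, so "k-fold
repeated R times with different subsampling combinations" is reproducible
from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import SplitError
from .metrics import MetricSet, compute_metrics, from_predictions
from .model import (
    SNO,
    ScorerConfig,
    TrainedModel,
    predict_many,
    score_many,
    train,
    tune_threshold,
)
from .windowing import PeptideWindow, ProteinRecord, extract_windows

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVPlan:
    """Shape of the repeated k-fold protocol."""

    k: int = 10
    repeats: int = 50
    seed: int = 42
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass(frozen=True)
class FoldRecord:
    """Held-out metrics and training provenance of one (repeat, fold)."""

    repeat: int
    fold: int
    metrics: MetricSet
    n_train_pos: int
    n_train_neg: int
    n_test: int


@dataclass(frozen=True)
class CVResult:
    """Per-fold and per-repeat metrics with their aggregate."""

    folds: tuple[FoldRecord, ...]
    repeat_metrics: tuple[MetricSet, ...]
    mean: MetricSet
    std: MetricSet
    pooled: bool


def _split_by_label(
    windows: Sequence[PeptideWindow],
) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    pos = [w for w in windows if w.label == "positive"]
    neg = [w for w in windows if w.label == "negative"]
    return pos, neg


def kfold_split(
    windows: Sequence[PeptideWindow], plan: CVPlan, repeat_index: int = 0
) -> list[list[int]]:
    """k disjoint held-out index lists, stratified by label.

    Deterministic given ``(plan.seed, repeat_index)``.
    """
    labels = [w.label for w in windows]
    n_pos = labels.count("positive")
    n_neg = labels.count("negative")
    if min(n_pos, n_neg) < plan.k:
        raise SplitError(
            f"each class needs >= k={plan.k} members (got {n_pos} positive, "
            f"{n_neg} negative)"
        )
    rs = plan.seed + repeat_index
    if plan.stratified:
        splitter = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=rs)
    else:
        splitter = KFold(n_splits=plan.k, shuffle=True, random_state=rs)
    dummy = np.zeros(len(windows))
    return [test.tolist() for _, test in splitter.split(dummy, labels)]


def _mean_std(metric_sets: Sequence[MetricSet]) -> tuple[MetricSet, MetricSet]:
    arr = np.array([[m.sn, m.sp, m.acc, m.mcc] for m in metric_sets])
    mean = arr.mean(axis=0)
    std = arr.std(axis=0)  # population std; a single repeat gives 0
    return MetricSet(*mean.tolist()), MetricSet(*std.tolist())


def cross_validate(
    windows: Sequence[PeptideWindow],
    plan: CVPlan = CVPlan(),
    config: ScorerConfig = ScorerConfig(),
    functional: str = "difference",
    pseudocount: float | None = None,
    pool_folds: bool = True,
    global_threshold: bool = False,
) -> CVResult:
    """Repeated stratified k-fold evaluation of the full pipeline.

    ``global_threshold=True`` re-tunes the decision threshold of each
    fold's model on the scores of the *whole* dataset (the global-threshold
    variant; it leaks the held-out labels into the threshold and is provided
    only for comparison).
    """
    windows = list(windows)
    fold_records: list[FoldRecord] = []
    repeat_metrics: list[MetricSet] = []
    all_labels = [w.label for w in windows]

    for r in range(plan.repeats):
        folds = kfold_split(windows, plan, repeat_index=r)
        pooled_truth: list[str] = []
        pooled_pred: list[str] = []
        per_fold_metrics: list[MetricSet] = []
        for f, test_idx in enumerate(folds):
            test_set = set(test_idx)
            train_windows = [w for i, w in enumerate(windows) if i not in test_set]
            test_windows = [windows[i] for i in test_idx]
            tr_pos, tr_neg = _split_by_label(train_windows)
            try:
                fitted = train(
                    tr_pos, tr_neg, config, functional=functional, pseudocount=pseudocount
                )
            except Exception as exc:
                raise type(exc)(f"repeat {r}, fold {f}: {exc}") from exc
            if global_threshold:
                global_scores = score_many(windows, fitted)
                from dataclasses import replace

                fitted = replace(fitted, delta=tune_threshold(global_scores, all_labels))
            preds = predict_many(test_windows, fitted)
            truth = [w.label for w in test_windows]
            pooled_truth += truth
            pooled_pred += preds
            fold_m = compute_metrics(from_predictions(truth, preds))
            per_fold_metrics.append(fold_m)
            fold_records.append(
                FoldRecord(
                    repeat=r,
                    fold=f,
                    metrics=fold_m,
                    n_train_pos=len(tr_pos),
                    n_train_neg=len(tr_neg),
                    n_test=len(test_windows),
                )
            )
        if pool_folds:
            repeat_metrics.append(compute_metrics(from_predictions(pooled_truth, pooled_pred)))
        else:
            repeat_metrics.append(_mean_std(per_fold_metrics)[0])

    mean, std = _mean_std(repeat_metrics)
    return CVResult(
        folds=tuple(fold_records),
        repeat_metrics=tuple(repeat_metrics),
        mean=mean,
        std=std,
        pooled=pool_folds,
    )


def jackknife(
    windows: Sequence[PeptideWindow],
    config: ScorerConfig = ScorerConfig(),
    functional: str = "difference",
    pseudocount: float | None = None,
) -> MetricSet:
    """Leave-one-out evaluation; unique for a fixed dataset.

    Every window is held out once, the pipeline is refit on the remainder,
    and pooled held-out predictions give the metrics.  With a deterministic
    scorer fit the result does not depend on any seed.
    """
    windows = list(windows)
    pos, neg = _split_by_label(windows)
    if len(pos) < 3 or len(neg) < 3:
        raise SplitError(
            f"jackknife needs >= 3 windows per class (got {len(pos)}, {len(neg)})"
        )
    truth: list[str] = []
    preds: list[str] = []
    for i, held_out in enumerate(windows):
        rest = windows[:i] + windows[i + 1 :]
        tr_pos, tr_neg = _split_by_label(rest)
        fitted = train(tr_pos, tr_neg, config, functional=functional, pseudocount=pseudocount)
        preds += predict_many([held_out], fitted)
        truth.append(held_out.label)
    return compute_metrics(from_predictions(truth, preds))


# --- protein-level calls ---------------------------------------------------


@dataclass(frozen=True)
class SiteCall:
    """One scored cysteine of a query protein."""

    site: int
    peptide: str
    score: float
    call: str


@dataclass(frozen=True)
class ProteinReport:
    """All cysteine calls of one protein plus the protein-level label.

    A protein is called nitrosylated iff at least one site is called SNO.
    """

    protein_id: str
    sites: tuple[SiteCall, ...]
    nitrosylated: bool
    flags: tuple[str, ...] = ()


def predict_protein(protein: ProteinRecord, model: TrainedModel) -> ProteinReport:
    """Score every cysteine of a sanitized protein and call the protein."""
    windows = extract_windows(protein, xi=model.xi)
    if not windows:
        logger.info("protein %r contains no cysteine", protein.id)
        return ProteinReport(
            protein_id=protein.id, sites=(), nitrosylated=False, flags=("no cysteine",)
        )
    scores = score_many(windows, model)
    calls = tuple(
        SiteCall(
            site=w.site,
            peptide=w.residues,
            score=float(s),
            call=SNO if s >= model.delta else "non-SNO",
        )
        for w, s in zip(windows, scores)
    )
    return ProteinReport(
        protein_id=protein.id,
        sites=calls,
        nitrosylated=any(c.call == SNO for c in calls),
    )


def protein_success_rate(reports: Sequence[ProteinReport]) -> float:
    """Fraction of proteins called nitrosylated."""
    if not reports:
        raise SplitError("no protein reports to summarize")
    return sum(r.nitrosylated for r in reports) / len(reports)


def serialize_cv_result(result: CVResult) -> str:
    """TSV: one row per (repeat, fold), per-repeat rows, then the aggregate."""
    lines = ["kind\trepeat\tfold\tsn\tsp\tacc\tmcc"]

    def row(kind: str, repeat, fold, m: MetricSet) -> str:
        return f"{kind}\t{repeat}\t{fold}\t{m.sn!r}\t{m.sp!r}\t{m.acc!r}\t{m.mcc!r}"

    for rec in result.folds:
        lines.append(row("fold", rec.repeat, rec.fold, rec.metrics))
    for r, m in enumerate(result.repeat_metrics):
        lines.append(row("repeat", r, "-", m))
    lines.append(row("mean", "-", "-", result.mean))
    lines.append(row("std", "-", "-", result.std))
    return "\n".join(lines) + "\n"
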