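"""Discriminative scorer and decision threshold for SNO-site calls.

The canonical scorer is an L2-regularized logistic model on the 2*xi
propensity components: a discriminative probabilistic classifier that is the
single-clique degenerate case of a conditional random field on the fixed-
length window.  An alternative two-state chain scorer is available behind
``scorer_kind="chain_crf"``: each flank position carries a state from
{flank-of-positive, flank-of-negative} with tied per-position potentials, and
the window score is the posterior of the all-positive chain.  With tied
potentials and only the two pure chains admissible, that posterior collapses
analytically to a logistic response on the *summed* propensity feature, which
is exactly how it is implemented.

After the scorer is fitted, the decision threshold ``delta`` is set by
maximizing overall accuracy on the training scores; a window is called SNO
iff its score is >= delta (ties at delta are SNO).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import FormatError, ShapeError, ThresholdError, TrainingError
from .psaap import PSAAPMatrix, build_psaap, encode_many, load_psaap, save_psaap
from .windowing import PeptideWindow

logger = logging.getLogger(__name__)

SNO = "SNO"
NON_SNO = "non-SNO"

_ARCHIVE_MAGIC = "#snosite-model\tv1"


@dataclass(frozen=True)
class ScorerConfig:
    """Hyperparameters of the scorer fit.

    ``regularization`` is the L2 penalty strength lambda (the sklearn ``C``
    is its inverse).  The seed only matters for tie-breaking inside the
    optimizer; the fit itself is deterministic given the data.
    """

    scorer_kind: Literal["logistic", "chain_crf"] = "logistic"
    regularization: float = 1.0
    max_iter: int = 1000
    tol: float = 1e-8
    seed: int = 42

    def __post_init__(self) -> None:
        if self.regularization <= 0:
            raise ValueError("regularization strength must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")
        if self.scorer_kind not in ("logistic", "chain_crf"):
            raise ValueError(f"unknown scorer_kind {self.scorer_kind!r}")


@dataclass(frozen=True)
class TrainedModel:
    """Fitted scorer weights, decision threshold, and the PSAAP used."""

    psaap: PSAAPMatrix
    weights: np.ndarray  # length 2*xi (logistic) or 1 (chain_crf, summed feature)
    intercept: float
    delta: float
    config: ScorerConfig
    n_pos: int
    n_neg: int

    @property
    def xi(self) -> int:
        return self.psaap.xi


def _features(windows: Sequence[PeptideWindow], psaap: PSAAPMatrix) -> np.ndarray:
    return encode_many(windows, psaap)


def _score_features(features: np.ndarray, model: TrainedModel) -> np.ndarray:
    """Sigmoid of the linear response; features shape (n, 2*xi)."""
    if model.config.scorer_kind == "chain_crf":
        z = features.sum(axis=1) * model.weights[0] + model.intercept
    else:
        z = features @ model.weights + model.intercept
    return 1.0 / (1.0 + np.exp(-z))


def tune_threshold(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Accuracy-maximizing threshold over the natural candidate set.

    Candidates are 0, 1 and the midpoints of adjacent distinct sorted scores;
    within a candidate interval the induced predictions (score >= delta) are
    constant, so this set contains an exact maximizer of overall accuracy.
    Among equally accurate candidates the smallest is returned.
    """
    scores_arr = np.asarray(scores, dtype=float)
    is_pos = np.array([lbl in ("positive", SNO, True, 1) for lbl in labels])
    if scores_arr.shape[0] != is_pos.shape[0]:
        raise ThresholdError("scores and labels differ in length")
    n_pos = int(is_pos.sum())
    n = scores_arr.shape[0]
    if n_pos == 0 or n_pos == n:
        raise ThresholdError("threshold tuning needs at least one score per class")

    order = np.argsort(scores_arr, kind="mergesort")
    s = scores_arr[order]
    p = is_pos[order].astype(int)
    cum_pos = np.concatenate([[0], np.cumsum(p)])  # positives among the first i items

    # cut i: the first i (lowest) scores predicted non-SNO, the rest SNO
    cuts = [0]
    cuts += [i for i in range(1, n) if s[i - 1] < s[i]]
    if s[-1] < 1.0:
        cuts.append(n)

    best_delta = None
    best_correct = -1
    for i in cuts:
        correct = (n_pos - cum_pos[i]) + (i - cum_pos[i])
        if i == 0:
            delta = 0.0
        elif i == n:
            delta = 1.0
        else:
            delta = 0.5 * (s[i - 1] + s[i])
        if correct > best_correct or (correct == best_correct and delta < best_delta):
            best_correct = correct
            best_delta = delta
    return float(best_delta)


def train(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    config: ScorerConfig = ScorerConfig(),
    functional: str = "difference",
    pseudocount: float | None = None,
) -> TrainedModel:
    """Fit PSAAP + scorer + threshold from labeled windows only.

    The propensity matrix, the scorer weights and ``delta`` are all derived
    from the given windows, so the pipeline can be refit per cross-validation
    fold without leakage.  A no-signal training set (all feature vectors
    identical, e.g. identical class compositions) degrades gracefully to an
    intercept-only fit whose score is the class prior; this is logged.
    """
    positives, negatives = list(positives), list(negatives)
    if not positives or not negatives:
        raise TrainingError(
            f"both classes must be non-empty (got {len(positives)} positive, "
            f"{len(negatives)} negative)"
        )
    psaap = build_psaap(positives, negatives, functional=functional, pseudocount=pseudocount)
    X = np.vstack([_features(positives, psaap), _features(negatives, psaap)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(negatives))])

    if np.allclose(X, X[0], atol=0.0):
        logger.warning(
            "train: all feature vectors are identical across classes "
            "(no positional signal); fitting an intercept-only scorer"
        )

    design = X.sum(axis=1, keepdims=True) if config.scorer_kind == "chain_crf" else X
    clf = LogisticRegression(
        C=1.0 / config.regularization,
        tol=config.tol,
        max_iter=config.max_iter,
        solver="lbfgs",
        random_state=config.seed,
    )
    clf.fit(design, y)
    weights = clf.coef_[0].copy()
    intercept = float(clf.intercept_[0])

    model = TrainedModel(
        psaap=psaap,
        weights=weights,
        intercept=intercept,
        delta=0.5,  # placeholder until tuned below
        config=config,
        n_pos=len(positives),
        n_neg=len(negatives),
    )
    scores = _score_features(X, model)
    labels = ["positive"] * len(positives) + ["negative"] * len(negatives)
    delta = tune_threshold(scores, labels)
    return TrainedModel(
        psaap=psaap,
        weights=weights,
        intercept=intercept,
        delta=delta,
        config=config,
        n_pos=len(positives),
        n_neg=len(negatives),
    )


def score(window: PeptideWindow, model: TrainedModel) -> float:
    """Probability-like score in [0, 1] for one window."""
    if window.xi != model.xi:
        raise ShapeError(f"window xi={window.xi} does not match model xi={model.xi}")
    return float(_score_features(_features([window], model.psaap), model)[0])


def score_many(windows: Sequence[PeptideWindow], model: TrainedModel) -> np.ndarray:
    """Vectorized :func:`score`."""
    if not windows:
        return np.zeros(0)
    return _score_features(_features(windows, model.psaap), model)


def predict(window: PeptideWindow, model: TrainedModel) -> str:
    """Binary call: SNO iff score >= delta (ties at delta are SNO)."""
    return SNO if score(window, model) >= model.delta else NON_SNO


def predict_many(windows: Sequence[PeptideWindow], model: TrainedModel) -> list[str]:
    return [SNO if s >= model.delta else NON_SNO for s in score_many(windows, model)]


# --- model archive: single text file, versioned header ---------------------


def serialize_model(model: TrainedModel) -> str:
    """Render the whole model (config, threshold, weights, PSAAP) as text."""
    cfg = model.config
    lines = [
        _ARCHIVE_MAGIC,
        "[config]",
        f"scorer_kind={cfg.scorer_kind}",
        f"regularization={cfg.regularization!r}",
        f"max_iter={cfg.max_iter}",
        f"tol={cfg.tol!r}",
        f"seed={cfg.seed}",
        "[threshold]",
        f"delta={model.delta!r}",
        "[provenance]",
        f"n_pos={model.n_pos}",
        f"n_neg={model.n_neg}",
        "[weights]",
        f"intercept={model.intercept!r}",
        "w\t" + "\t".join(repr(v) for v in model.weights.tolist()),
        "[psaap]",
    ]
    return "\n".join(lines) + "\n" + save_psaap(model.psaap)


def deserialize_model(text: str) -> TrainedModel:
    """Parse the archive produced by :func:`serialize_model`."""
    if not text.startswith(_ARCHIVE_MAGIC):
        raise FormatError("not a snosite model archive (bad magic line)")
    try:
        head, psaap_text = text.split("[psaap]\n", 1)
    except ValueError as exc:
        raise FormatError("model archive lacks a [psaap] section") from exc
    kv: dict[str, str] = {}
    weights = None
    for line in head.splitlines():
        if line.startswith("#") or line.startswith("[") or not line.strip():
            continue
        if line.startswith("w\t"):
            weights = np.array([float(v) for v in line.split("\t")[1:]])
        elif "=" in line:
            key, val = line.split("=", 1)
            kv[key] = val
    if weights is None:
        raise FormatError("model archive lacks a weight row")
    try:
        config = ScorerConfig(
            scorer_kind=kv["scorer_kind"],  # type: ignore[arg-type]
            regularization=float(kv["regularization"]),
            max_iter=int(kv["max_iter"]),
            tol=float(kv["tol"]),
            seed=int(kv["seed"]),
        )
        return TrainedModel(
            psaap=load_psaap(psaap_text),
            weights=weights,
            intercept=float(kv["intercept"]),
            delta=float(kv["delta"]),
            config=config,
            n_pos=int(kv["n_pos"]),
            n_neg=int(kv["n_neg"]),
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"incomplete or malformed model archive: {exc}") from exc


def save_model(model: TrainedModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_model(model))


def load_model(path) -> TrainedModel:
    with open(path, "r", encoding="utf-8") as fh:
        return deserialize_model(fh.read())
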