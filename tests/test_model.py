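import dataclasses

import numpy as np
import pytest

from snosite import ScorerConfig, predict, score, train, tune_threshold
from snosite.errors import ShapeError, ThresholdError, TrainingError
from snosite.model import (
    NON_SNO,
    SNO,
    deserialize_model,
    score_many,
    serialize_model,
)
from snosite.synthetic import SyntheticSpec, generate_benchmark


def brute_force_best_accuracy(scores, is_pos, grid_step=1e-3):
    scores = np.asarray(scores)
    is_pos = np.asarray(is_pos, dtype=bool)
    best = 0.0
    for delta in np.arange(0.0, 1.0 + grid_step / 2, grid_step):
        preds = scores >= delta
        best = max(best, float((preds == is_pos).mean()))
    return best


def accuracy_at(scores, is_pos, delta):
    preds = np.asarray(scores) >= delta
    return float((preds == np.asarray(is_pos, dtype=bool)).mean())


class TestTuneThreshold:
    def test_separated_scores(self):
        delta = tune_threshold([0.9, 0.8, 0.1, 0.2], ["positive"] * 2 + ["negative"] * 2)
        assert delta == pytest.approx(0.5)
        assert accuracy_at([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], delta) == 1.0

    def test_indistinguishable_scores_return_smallest_candidate(self):
        delta = tune_threshold([0.6, 0.6], ["positive", "negative"])
        assert delta == 0.0
        assert accuracy_at([0.6, 0.6], [1, 0], delta) == 0.5

    def test_inverted_labels_hit_half_accuracy(self):
        scores = [0.1, 0.2, 0.9, 0.8]
        labels = ["positive", "positive", "negative", "negative"]
        delta = tune_threshold(scores, labels)
        acc = accuracy_at(scores, [1, 1, 0, 0], delta)
        assert acc == pytest.approx(0.5)
        assert acc == pytest.approx(brute_force_best_accuracy(scores, [1, 1, 0, 0]))

    def test_single_class_raises(self):
        with pytest.raises(ThresholdError):
            tune_threshold([0.5, 0.6], ["positive", "positive"])

    def test_never_beaten_by_grid(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 40))
            scores = rng.random(n)
            is_pos = rng.integers(0, 2, size=n).astype(bool)
            if is_pos.all() or not is_pos.any():
                continue
            labels = ["positive" if p else "negative" for p in is_pos]
            delta = tune_threshold(scores, labels)
            assert accuracy_at(scores, is_pos, delta) >= brute_force_best_accuracy(
                scores, is_pos
            ) - 1e-12


class TestTrain:
    def test_empty_class_raises(self, mk):
        with pytest.raises(TrainingError):
            train([mk("ACA", "positive")], [])

    def test_linearly_separable_training_accuracy_is_one(self, mk):
        pos = [mk("KCK", "positive"), mk("KCR", "positive"), mk("RCK", "positive")]
        neg = [mk("GCG", "negative"), mk("GCA", "negative"), mk("ACG", "negative")]
        m = train(pos, neg)
        calls = [predict(w, m) for w in pos + neg]
        assert calls == [SNO] * 3 + [NON_SNO] * 3

    def test_strong_synthetic_classes_fully_separated(self):
        """Planted effect 0.9 at five offsets: tuned model is exact on training."""
        enr = tuple((o, r, 0.9) for o, r in ((-4, "K"), (-2, "E"), (-1, "D"), (1, "E"), (3, "R")))
        spec = SyntheticSpec(n_pos=200, n_neg=200, enrichments=enr, seed=1)
        pos, neg = generate_benchmark(spec)
        m = train(pos, neg, ScorerConfig(seed=1))
        scores = np.concatenate([score_many(pos, m), score_many(neg, m)])
        preds = scores >= m.delta
        truth = np.array([True] * 200 + [False] * 200)
        assert (preds == truth).mean() == 1.0

    def test_archetype_scores_are_extreme(self, mk):
        """The pure positive motif scores high, the pure background window low."""
        enr = tuple((o, r, 0.9) for o, r in ((-4, "K"), (-2, "E"), (-1, "D"), (1, "E"), (3, "R")))
        spec = SyntheticSpec(n_pos=200, n_neg=200, enrichments=enr, seed=1)
        pos, neg = generate_benchmark(spec)
        m = train(pos, neg, ScorerConfig(seed=1))
        arch = mk("AAAAAAKAEDCEARAAAAAAA", "unknown")
        bland = mk("AAAAAAAAAACAAAAAAAAAA", "unknown")
        assert score(arch, m) > 0.9
        assert score(bland, m) < 0.1

    def test_identical_classes_degrade_to_prior(self, mk):
        ws_pos = [mk("ACA", "positive"), mk("GCG", "positive")]
        ws_neg = [mk("ACA", "negative"), mk("GCG", "negative")]
        m = train(ws_pos, ws_neg)
        scores = score_many(ws_pos + ws_neg, m)
        assert np.allclose(scores, scores[0], atol=1e-9)
        assert abs(scores[0] - 0.5) < 0.05  # balanced prior
        preds = scores >= m.delta
        truth = np.array([True, True, False, False])
        assert (preds == truth).mean() == pytest.approx(0.5)

    def test_determinism_same_seed_identical_archives(self, strong_benchmark):
        pos, neg = strong_benchmark
        cfg = ScorerConfig(seed=11)
        a = serialize_model(train(pos, neg, cfg))
        b = serialize_model(train(pos, neg, cfg))
        assert a == b

    def test_chain_crf_scorer_satisfies_score_contract(self, strong_benchmark):
        pos, neg = strong_benchmark
        m = train(pos, neg, ScorerConfig(scorer_kind="chain_crf", seed=1))
        s = score_many(pos + neg, m)
        assert np.all((0.0 <= s) & (s <= 1.0))
        # the summed-propensity chain still separates a strong motif well
        truth = np.array([True] * len(pos) + [False] * len(neg))
        assert ((s >= m.delta) == truth).mean() > 0.8


class TestScorePredict:
    def test_predict_threshold_rule(self, strong_model, strong_benchmark):
        pos, _ = strong_benchmark
        w = pos[0]
        s = score(w, strong_model)
        at_delta = dataclasses.replace(strong_model, delta=s)
        assert predict(w, at_delta) == SNO  # tie at delta is SNO
        above = dataclasses.replace(strong_model, delta=min(1.0, s + 1e-9))
        if s + 1e-9 <= 1.0 and s + 1e-9 > s:
            assert predict(w, above) == NON_SNO

    def test_xi_mismatch_raises(self, strong_model, mk):
        with pytest.raises(ShapeError):
            score(mk("ACA"), strong_model)

    def test_monotone_in_positive_weight_feature(self, strong_model):
        from snosite.model import _score_features

        w = strong_model.weights
        j = int(np.argmax(w))
        assert w[j] > 0
        base = np.zeros((1, w.shape[0]))
        bumped = base.copy()
        bumped[0, j] += 0.5
        assert _score_features(bumped, strong_model)[0] > _score_features(base, strong_model)[0]


class TestArchive:
    def test_round_trip(self, strong_model):
        text = serialize_model(strong_model)
        loaded = deserialize_model(text)
        assert serialize_model(loaded) == text
        np.testing.assert_array_equal(loaded.weights, strong_model.weights)
        assert loaded.delta == strong_model.delta
        assert loaded.config == strong_model.config

    def test_bad_magic_raises(self):
        from snosite.errors import FormatError

        with pytest.raises(FormatError):
            deserialize_model("nonsense")
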