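"""Loss, metrics, curves and the training loop."""

import numpy as np
import pytest

from msres.model.config import MsResConfig
from msres.model.network import build_model
from msres.preprocess import SegmentSet
from msres.train import (
    ConfusionMatrix,
    TrainConfig,
    bce_loss,
    confusion,
    cross_validate,
    curves,
    evaluate_model,
    metrics,
    train_model,
)


class TestBCE:
    def test_half_probability_gives_ln2(self):
        assert bce_loss(np.array([1.0]), np.array([0.5])) == pytest.approx(np.log(2))

    def test_perfect_prediction_is_at_most_clip_epsilon(self):
        y = np.array([0.0, 1.0, 1.0])
        assert bce_loss(y, y) <= -np.log(1 - 1e-7) + 1e-12

    def test_matches_elementwise_summation_oracle(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        p = rng.uniform(1e-6, 1 - 1e-6, 200)
        manual = -sum(
            yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for yi, pi in zip(y, p)
        ) / 200
        assert bce_loss(y, p) == pytest.approx(manual, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros(3), np.zeros(4))


class TestConfusion:
    def test_hand_counted_example(self):
        cm = confusion(np.array([1, 1, 1, 0, 0]), np.array([1, 0, 1, 1, 0]))
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 1)

    def test_all_correct_has_no_errors(self):
        y = np.array([0, 1, 0, 1])
        cm = confusion(y, y)
        assert cm.fp == cm.fn == 0 and cm.tp == 2 and cm.tn == 2

    def test_label_swap_symmetry(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        a = confusion(y, p)
        b = confusion(1 - y, 1 - p)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tn, b.fn, b.fp, b.tp)

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([0, 2]), np.array([0, 1]))


class TestMetrics:
    def test_hand_computed_example(self):
        m = metrics(ConfusionMatrix(tp=8, fp=2, fn=1, tn=9))
        assert m["precision"] == pytest.approx(0.800)
        assert m["recall"] == pytest.approx(8 / 9)
        assert m["accuracy"] == pytest.approx(0.850)
        assert m["f1"] == pytest.approx(2 * 0.8 * (8 / 9) / (0.8 + 8 / 9))

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=10, fp=0, fn=0, tn=0))
        assert m["precision"] == m["recall"] == m["accuracy"] == m["f1"] == 1.0

    def test_degenerate_denominators_flagged_not_raised(self):
        m = metrics(ConfusionMatrix(tp=0, fp=3, fn=0, tn=7))
        assert m["precision"] == 0.0
        assert "recall_undefined" in m["flags"]


class TestCurves:
    def test_perfect_separation_gives_auc_one(self):
        y = np.array([0, 0, 1, 1])
        _, _, auc = curves(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc == pytest.approx(1.0)

    def test_matches_exhaustive_threshold_sweep(self, rng):
        y = rng.integers(0, 2, 30)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, 30)
        s = rng.random(30)
        pr, roc, auc = curves(y, s)
        # brute force: every unique score as threshold (predict score >= thr)
        pts = {(0.0, 0.0)}
        n_pos, n_neg = np.sum(y == 1), np.sum(y == 0)
        for thr in np.unique(s):
            pred = (s >= thr).astype(int)
            tp = np.sum((y == 1) & (pred == 1))
            fp = np.sum((y == 0) & (pred == 1))
            pts.add((fp / n_neg, tp / n_pos))
        assert {(round(a, 12), round(b, 12)) for a, b in roc} == \
               {(round(a, 12), round(b, 12)) for a, b in pts}

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        y = np.r_[np.zeros(40, int), np.ones(40, int)]
        s = rng.random(80) + 0.3 * y
        _, _, auc = curves(y, s)
        assert auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_score_reversal_flips_auc(self, rng):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        _, _, auc = curves(y, s)
        _, _, auc_rev = curves(y, 1 - s)
        assert auc + auc_rev == pytest.approx(1.0, abs=1e-12)

    def test_roc_endpoints(self, rng):
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        _, roc, _ = curves(y, rng.random(20))
        np.testing.assert_allclose(roc[0], [0, 0])
        np.testing.assert_allclose(roc[-1], [1, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            curves(np.ones(5, int), np.linspace(0, 1, 5))


TINY = MsResConfig(kernel_sizes=(3,), n_blocks=1, filters=4, dense_units=(8,),
                   input_len=60, dropout=0.0)


def _toy_data(n=128, seed=0):
    """1-D segments whose mean level separates the classes linearly."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(0.3, 0.05, (n, 60)) + 0.4 * y[:, None]
    return X.astype(np.float32), y


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        X, y = _toy_data(256)
        model = build_model(TINY, seed=0)
        history = train_model(model, X, y, TrainConfig(epochs=10, seed=0))
        assert history[-1]["loss"] < history[0]["loss"]
        assert len(history) == 10

    def test_one_step_per_epoch_bookkeeping(self):
        X, y = _toy_data(128)
        model = build_model(TINY, seed=0)
        history = train_model(model, X, y, TrainConfig(epochs=1, batch_size=128, seed=0))
        assert len(history) == 1
        assert set(history[0]) == {"epoch", "loss", "accuracy"}

    def test_fixed_seed_reproducible_history(self):
        X, y = _toy_data(200)
        h1 = train_model(build_model(TINY, seed=1), X, y, TrainConfig(epochs=3, seed=5))
        h2 = train_model(build_model(TINY, seed=1), X, y, TrainConfig(epochs=3, seed=5))
        assert h1 == h2

    @pytest.mark.parametrize("optimizer", ["adam", "adagrad", "adadelta"])
    def test_all_optimizers_step(self, optimizer):
        X, y = _toy_data(128)
        model = build_model(TINY, seed=0)
        before = [p.data.copy() for p in model.parameters()]
        train_model(model, X, y, TrainConfig(epochs=1, optimizer=optimizer, seed=0))
        assert any(not np.array_equal(b, p.data)
                   for b, p in zip(before, model.parameters()))

    def test_validation_history_entries(self):
        X, y = _toy_data(200)
        model = build_model(TINY, seed=0)
        history = train_model(model, X, y,
                              TrainConfig(epochs=2, seed=0, validation_fraction=0.2))
        assert "val_loss" in history[0] and "val_accuracy" in history[0]

    def test_evaluate_model_report(self):
        X, y = _toy_data(300, seed=1)
        model = build_model(TINY, seed=0)
        train_model(model, X[:200], y[:200],
                    TrainConfig(epochs=20, learning_rate=0.01, seed=0))
        report = evaluate_model(model, X[200:], y[200:])
        assert report.confusion.total == 100
        assert 0 <= report.f1 <= 1 and 0 <= report.auc <= 1
        assert report.f1 > 0.9  # easily separable toy task


class TestCrossValidation:
    def test_five_reports_each_fold_held_out_once(self):
        X, y = _toy_data(500, seed=2)
        segset = SegmentSet(X, y, np.array([f"r{i}" for i in range(500)], dtype=object))
        result = cross_validate(segset, k=5, model_config=TINY,
                                train_config=TrainConfig(epochs=4, seed=0), seed=0)
        assert len(result.fold_reports) == 5
        assert sum(r.confusion.total for r in result.fold_reports) == 500
        assert all(r.confusion.total == 100 for r in result.fold_reports)

    def test_mean_is_hand_average_of_folds(self):
        X, y = _toy_data(250, seed=3)
        segset = SegmentSet(X, y, np.array(["r"] * 250, dtype=object))
        result = cross_validate(segset, k=5, model_config=TINY,
                                train_config=TrainConfig(epochs=3, seed=0), seed=1)
        assert result.mean["f1"] == pytest.approx(
            np.mean([r.f1 for r in result.fold_reports])
        )


class TestDifficultyRecovery:
    def test_f1_increases_with_class_separation(self):
        """Holdout F1 ranks easy >= medium >= hard generator settings."""
        from msres.balance import BalanceConfig, balance_training_set
        from msres.dataio import record_from_synthetic
        from msres.preprocess import segment_records, stratified_split
        from msres.synth import DEFAULT_BEAT_MODEL, af_spec, generate_dataset, normal_spec

        # both classes rendered without a P wave so that the RR spread and
        # the f-wave are the only class cues being dialed
        no_p = DEFAULT_BEAT_MODEL.without_p()

        def run(af_kwargs):
            recs = generate_dataset(
                20, 40, seed=77,
                normal=normal_spec(mean_hr=80.0, beat_model=no_p),
                af=af_spec(mean_hr=80.0, **af_kwargs),
                duration=27.0,
            )
            records = [record_from_synthetic(r) for r in recs]
            labels = {r.name: r.label for r in recs}
            segset = segment_records(records, labels)
            train, test = stratified_split(segset, 0.3, seed=0)
            X, y = balance_training_set(train.matrix, train.labels,
                                        BalanceConfig("smote", seed=0))
            cfg = MsResConfig(kernel_sizes=(5, 7, 9), n_blocks=7, input_len=2700)
            model = build_model(cfg, seed=0)
            # small batches buy enough optimizer steps at this data scale
            train_model(model, X, y,
                        TrainConfig(epochs=25, batch_size=16, seed=0))
            return evaluate_model(model, test.matrix, test.labels).f1

        easy = run(dict(rr_cv=0.25, fwave_amp=0.08))
        medium = run(dict(rr_cv=0.15, fwave_amp=0.04))
        hard = run(dict(rr_cv=0.055, fwave_amp=0.0))
        assert easy >= medium >= hard
        assert easy > hard  # the ranking is strict end to end
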