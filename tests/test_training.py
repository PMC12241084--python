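"""Training loop contracts, checkpointing, MC-dropout uncertainty and the
estimator API."""

import numpy as np
import pytest
from sklearn.base import clone

from ranet.estimator import RaNetSegmenter
from ranet.model import thin_ranet
from ranet.optim import Adam, ReduceLROnPlateau
from ranet.training import (TrainConfig, evaluate, fit_model,
                            mc_dropout_predict, predict_proba)


@pytest.fixture(scope="module")
def tiny_stack(small_params):
    from ranet.phantom import generate_phantom, PhantomParams
    params = PhantomParams.small(32)
    pairs = [generate_phantom(params, seed=50 + i) for i in range(4)]
    X = np.stack([p.image.pixels for p in pairs])
    y = np.stack([p.mask.labels for p in pairs])
    return X, y


class TestScheduler:
    def test_reduces_after_exactly_patience_bad_epochs(self):
        opt = Adam([], lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=3)
        sched.step(1.0)  # establishes the best
        for _ in range(3):
            assert not sched.step(1.0)
            assert opt.lr == 1e-3
        assert sched.step(1.0)  # 4th bad epoch triggers
        assert opt.lr == pytest.approx(1e-4)

    def test_improvement_resets_the_counter(self):
        opt = Adam([], lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=2)
        sched.step(1.0)
        sched.step(1.0)
        sched.step(0.5)  # improvement
        sched.step(0.6)
        sched.step(0.6)
        assert opt.lr == 1e-3  # counter was reset, not yet exceeded

    def test_min_lr_floor(self):
        opt = Adam([], lr=1e-6)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=0, min_lr=1e-7)
        sched.step(1.0)
        sched.step(1.0)
        sched.step(1.0)
        assert opt.lr >= 1e-7


class TestFitModel:
    def test_same_seed_gives_identical_loss_traces(self, tiny_stack):
        X, y = tiny_stack
        histories = []
        for _ in range(2):
            model = thin_ranet(seed=3)
            cfg = TrainConfig(batch_size=2, max_epochs=2, seed=3)
            histories.append(fit_model(model, X, y, X, y, cfg))
        assert histories[0].trace("train_loss") == histories[1].trace("train_loss")
        assert histories[0].trace("val_loss") == histories[1].trace("val_loss")

    def test_learning_rate_trace_is_nonincreasing(self, tiny_stack):
        X, y = tiny_stack
        model = thin_ranet(seed=0)
        cfg = TrainConfig(batch_size=2, max_epochs=4, scheduler_patience=1,
                          seed=0)
        history = fit_model(model, X, y, X, y, cfg)
        lrs = history.trace("lr")
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_best_epoch_never_after_last_improvement(self, tiny_stack):
        X, y = tiny_stack
        model = thin_ranet(seed=1)
        cfg = TrainConfig(batch_size=2, max_epochs=3, seed=1)
        history = fit_model(model, X, y, X, y, cfg)
        vals = history.trace("val_loss")
        assert history.best_epoch == int(np.argmin(vals))

    def test_max_steps_caps_the_run(self, tiny_stack):
        X, y = tiny_stack
        model = thin_ranet(seed=0)
        cfg = TrainConfig(batch_size=2, max_epochs=50, max_steps=3, seed=0)
        history = fit_model(model, X, y, X, y, cfg)
        assert history.epochs[-1]["steps"] == 3
        assert history.stop_reason == "max_steps"

    def test_empty_dataset_rejected(self, tiny_stack):
        X, y = tiny_stack
        with pytest.raises(ValueError):
            fit_model(thin_ranet(seed=0), X[:0], y[:0], X, y, TrainConfig())

    def test_history_csv(self, tiny_stack, tmp_path):
        X, y = tiny_stack
        model = thin_ranet(seed=0)
        history = fit_model(model, X, y, X, y,
                            TrainConfig(batch_size=4, max_epochs=1))
        path = history.to_csv(tmp_path / "h.csv")
        header = path.read_text().splitlines()[0]
        for col in ("train_loss", "val_loss", "val_dsc", "lr",
                    "train_dice", "train_wce", "train_boundary"):
            assert col in header


class TestEvaluatePredict:
    def test_evaluate_twice_is_identical(self, tiny_stack):
        X, y = tiny_stack
        model = thin_ranet(seed=0)
        a = evaluate(model, X, y)
        b = evaluate(model, X, y)
        assert a.per_item == b.per_item

    def test_predict_proba_in_unit_interval(self, tiny_stack):
        X, _ = tiny_stack
        probs = predict_proba(thin_ranet(seed=0), X)
        assert probs.shape == X.shape
        assert 0 < probs.min() and probs.max() < 1


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path, tiny_stack):
        X, _ = tiny_stack
        model = thin_ranet(seed=4)
        path = tmp_path / "ckpt.npz"
        model.save_checkpoint(path)
        clone_model = thin_ranet(seed=99)
        clone_model.load_checkpoint(path)
        assert np.array_equal(predict_proba(model, X),
                              predict_proba(clone_model, X))

    def test_architecture_mismatch_reported(self, tmp_path):
        model = thin_ranet(seed=0)
        path = tmp_path / "ckpt.npz"
        model.save_checkpoint(path)
        other = thin_ranet(seed=0, dilation_rate=3)
        with pytest.raises(ValueError, match="mismatch"):
            other.load_checkpoint(path)


class TestMCDropout:
    def test_single_sample_has_zero_variance(self, tiny_stack):
        X, _ = tiny_stack
        _, var = mc_dropout_predict(thin_ranet(seed=0), X[0], T=1, seed=0)
        assert np.array_equal(var, np.zeros_like(var))

    def test_keep_all_has_zero_variance(self, tiny_stack):
        X, _ = tiny_stack
        model = thin_ranet(seed=0, keep_prob=1.0)
        _, var = mc_dropout_predict(model, X[0], T=5, seed=0)
        assert np.array_equal(var, np.zeros_like(var))

    def test_active_dropout_gives_positive_variance(self, tiny_stack):
        X, _ = tiny_stack
        _, var = mc_dropout_predict(thin_ranet(seed=0), X[0], T=5, seed=0)
        assert var.mean() > 0

    def test_seeded_repeatability(self, tiny_stack):
        X, _ = tiny_stack
        model = thin_ranet(seed=0)
        a = mc_dropout_predict(model, X[0], T=3, seed=9)
        b = mc_dropout_predict(model, X[0], T=3, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_invalid_sample_count_rejected(self, tiny_stack):
        X, _ = tiny_stack
        with pytest.raises(ValueError):
            mc_dropout_predict(thin_ranet(seed=0), X[0], T=0)


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        seg = RaNetSegmenter(learning_rate=5e-4, dilation_rate=3)
        params = seg.get_params()
        assert params["learning_rate"] == 5e-4
        cloned = clone(seg)
        assert cloned.get_params() == params

    def test_fit_predict_shapes_and_score(self, tiny_stack):
        X, y = tiny_stack
        seg = RaNetSegmenter(batch_size=2, max_epochs=2,
                             validation_fraction=0.25, random_state=0)
        seg.fit(X, y)
        assert seg.n_iter_ == 2
        assert seg.predict(X).shape == X.shape
        assert seg.predict_proba(X).shape == X.shape
        assert 0 <= seg.score(X, y) <= 1
        assert seg.input_shape_ == (32, 32)

    def test_unfitted_predict_rejected(self, tiny_stack):
        X, _ = tiny_stack
        with pytest.raises(AttributeError, match="not fitted"):
            RaNetSegmenter().predict(X)

    def test_explicit_validation_data(self, tiny_stack):
        X, y = tiny_stack
        seg = RaNetSegmenter(batch_size=2, max_epochs=1, random_state=0)
        seg.fit(X[:3], y[:3], validation_data=(X[3:], y[3:]))
        assert hasattr(seg, "history_")

    def test_mismatched_stacks_rejected(self, tiny_stack):
        X, y = tiny_stack
        with pytest.raises(ValueError):
            RaNetSegmenter().fit(X, y[:2])
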