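"""Two-component minibatch training loop: batching, equivalences, stopping."""

import numpy as np
import pytest

from popdann.model import NetworkSpec, build_network, predict_values
from popdann.train import (
    TrainingConfig,
    _CycledStream,
    make_minibatch,
    minibatch_stream,
    train_domain_adaptive,
    train_standard,
)
from tests.conftest import synthetic_genealogy_bundle

LN2 = np.log(2.0)


def _spec(task="sweep_classification", m=8):
    return NetworkSpec(task=task, input_shape=(m, m, 3), width=4, feature_dim=8, w_scale=1.0)


class TestMinibatches:
    def test_default_mixture_is_32_plus_32_at_batch_64(self, rng):
        cfg = TrainingConfig(batch_size=64)
        b = make_minibatch(
            _CycledStream(500, rng),
            _CycledStream(500, rng),
            _CycledStream(100, rng),
            cfg,
        )
        assert len(b.labeled_source) == 64
        assert len(b.domain_source) == 32
        assert len(b.domain_target) == 32

    def test_source_only_mixture(self, rng):
        cfg = TrainingConfig(batch_size=64, domain_mix_fraction=1.0)
        b = make_minibatch(
            _CycledStream(500, rng), _CycledStream(500, rng), _CycledStream(10, rng), cfg
        )
        assert len(b.domain_source) == 64 and len(b.domain_target) == 0

    def test_missing_target_stream_rejected(self, rng):
        with pytest.raises(ValueError):
            make_minibatch(
                _CycledStream(10, rng), _CycledStream(10, rng), None, TrainingConfig()
            )

    def test_each_source_example_labeled_exactly_once_per_epoch(self, rng):
        cfg = TrainingConfig(batch_size=16)
        n_source = 160
        seen = []
        for b in minibatch_stream(n_source, 40, cfg, rng, np.random.default_rng(5)):
            seen.extend(b.labeled_source.tolist())
        assert sorted(seen) == list(range(n_source))

    def test_small_target_pool_is_cycled_with_reshuffling(self, rng):
        cfg = TrainingConfig(batch_size=16)
        stream = _CycledStream(5, rng)
        took = stream.take(20)
        assert len(took) == 20
        assert set(took) == set(range(5))


class TestStandardTraining:
    def test_constant_label_regression_converges(self):
        bundle = synthetic_genealogy_bundle(
            task="s_regression", constant_label=-2.5, n_examples=192, seed=1
        )
        model = build_network(_spec("s_regression"), seed=0)
        cfg = TrainingConfig(
            batch_size=32, max_epochs=100, patience=100, seed=0, learning_rate=3e-3
        )
        train_standard(model, bundle, cfg)
        X, y = bundle.source_test
        preds = np.log10(predict_values(model, X))
        assert np.abs(preds - (-2.5)).mean() < 0.05 * 2.5

    def test_seeded_rerun_reproduces_validation_loss(self):
        bundle = synthetic_genealogy_bundle(seed=2)
        cfg = TrainingConfig(batch_size=32, max_epochs=4, patience=4, seed=7)
        h1 = train_standard(build_network(_spec(), seed=7), bundle, cfg)
        h2 = train_standard(build_network(_spec(), seed=7), bundle, cfg)
        assert h1.label_val_loss == h2.label_val_loss

    def test_early_stopping_restores_best_label_checkpoint(self):
        bundle = synthetic_genealogy_bundle(seed=3)
        model = build_network(_spec(), seed=1)
        cfg = TrainingConfig(batch_size=32, max_epochs=40, patience=3, seed=1)
        hist = train_standard(model, bundle, cfg)
        assert hist.best_epoch == int(np.argmin(hist.label_val_loss))
        assert hist.n_epochs <= hist.best_epoch + 1 + cfg.patience


class TestDomainAdaptiveTraining:
    def test_lambda_zero_trajectory_equals_standard(self):
        """With lambda=0 the domain branch contributes no FE gradient: the
        feature-extractor + label-predictor trajectory matches standard
        training exactly under identical seeds and batch order."""
        bundle = synthetic_genealogy_bundle(seed=4, target_shift=1.0)
        cfg = TrainingConfig(batch_size=32, max_epochs=5, patience=5, seed=3, grl_lambda=0.0)
        m_std = build_network(_spec(), seed=3)
        h_std = train_standard(m_std, bundle, cfg)
        m_da = build_network(_spec(), seed=3)
        h_da = train_domain_adaptive(m_da, bundle, cfg)
        assert h_std.label_val_loss == h_da.label_val_loss
        for pa, pb in zip(
            m_std.feature_extractor.params() + m_std.label_predictor.params(),
            m_da.feature_extractor.params() + m_da.label_predictor.params(),
        ):
            assert np.array_equal(pa.value, pb.value)

    def test_combined_gradient_identity(self):
        """One step accumulates label grad minus lambda times domain grad."""
        from popdann.model import batch_input
        from popdann.nn import softmax_cross_entropy
        from popdann.train import _backprop_domain, _backprop_label, _domain_loss_grad, _label_loss_grad

        bundle = synthetic_genealogy_bundle(seed=5)
        spec = _spec()
        Xs, ys = bundle.source_train
        x = batch_input(spec, Xs, np.arange(16))
        xt = batch_input(spec, bundle.target_train, np.arange(16))
        xd = np.concatenate([x, xt])
        d = np.r_[np.zeros(16, int), np.ones(16, int)]
        lam = 0.6

        def fe_grads(label_w, domain_w, lam_):
            model = build_network(
                NetworkSpec(task=spec.task, input_shape=spec.input_shape, width=4,
                            feature_dim=8, w_scale=1.0, grl_lambda=lam_),
                seed=11,
            )
            for p in model.trainable_params(True):
                p.grad[...] = 0
            if label_w:
                _, dout, caches = _label_loss_grad(model, x, ys[:16])
                _backprop_label(model, caches, dout)
            if domain_w:
                _, ddout, dcaches = _domain_loss_grad(model, xd, d)
                _backprop_domain(model, dcaches, ddout)
            return [p.grad.copy() for p in model.feature_extractor.params()]

        combined = fe_grads(True, True, lam)
        label_only = fe_grads(True, False, lam)
        domain_only_unrev = fe_grads(False, True, 0.0)  # lambda=0 -> zero
        domain_only = fe_grads(False, True, 1.0)
        for gc, gl, gd, gz in zip(combined, label_only, domain_only, domain_only_unrev):
            assert np.allclose(gc, gl + lam * gd, rtol=1e-5, atol=1e-7)
            assert np.all(gz == 0)

    def test_domain_loss_near_chance_without_shift(self):
        bundle = synthetic_genealogy_bundle(seed=6, target_shift=0.0)
        model = build_network(_spec(), seed=2)
        cfg = TrainingConfig(batch_size=32, max_epochs=8, patience=8, seed=2)
        hist = train_domain_adaptive(model, bundle, cfg)
        assert np.abs(np.array(hist.domain_val_loss) - LN2).max() < 0.1 * LN2

    def test_domain_loss_starts_low_then_rises_under_shift(self):
        bundle = synthetic_genealogy_bundle(seed=7, target_shift=3.0)
        model = build_network(_spec(), seed=2)
        cfg = TrainingConfig(
            batch_size=32, max_epochs=40, patience=40, seed=2, learning_rate=3e-3
        )
        hist = train_domain_adaptive(model, bundle, cfg)
        dl = np.array(hist.domain_val_loss)
        assert dl.min() < 0.8 * LN2  # the shift is learnable at first
        # adversarial feature invariance drives the loss back up afterwards
        assert dl[dl.argmin() :].max() > dl.min() + 0.1

    def test_requires_target_data(self):
        bundle = synthetic_genealogy_bundle(seed=8)
        bundle.target_train = bundle.target_train[:0]
        with pytest.raises(ValueError):
            train_domain_adaptive(
                build_network(_spec(), seed=0), bundle, TrainingConfig(batch_size=32)
            )

    def test_divergence_aborts_with_diagnostic(self):
        bundle = synthetic_genealogy_bundle(task="s_regression", seed=9)
        model = build_network(_spec("s_regression"), seed=0)
        cfg = TrainingConfig(batch_size=32, max_epochs=3, patience=3, seed=0, learning_rate=1e6)
        with np.errstate(all="ignore"), pytest.raises(RuntimeError, match="diverged"):
            train_standard(model, bundle, cfg)
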