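import dataclasses

import numpy as np
import pytest

from ddecnn import (
    ArchitectureSpec,
    TrainingConfig,
    build_model,
    load_model,
    predict_label,
    predict_proba,
    save_model,
    shape_trace,
    total_param_count,
    train,
)
from ddecnn.cnn import CNNClassifier, flatten_size, layer_param_count, param_trace
from ddecnn.errors import (
    ConfigurationError,
    IncompatibleModelError,
)
from tests.conftest import TINY_SPEC

DEFAULT = ArchitectureSpec()


class TestShapeTrace:
    def test_default_widths_follow_ceil_mode_pooling(self):
        widths = [
            shape[1]
            for name, shape in shape_trace(DEFAULT)
            if name.startswith(("input", "max_pooling"))
        ]
        assert widths == [20, 10, 5, 3]

    def test_default_flatten_size(self):
        assert flatten_size(DEFAULT) == 1 * 3 * 128 == 384

    def test_single_block_flatten(self):
        spec = ArchitectureSpec(conv_filters=(32,), dropout_rates=(0.4, 0.4))
        assert flatten_size(spec) == 1 * 10 * 32 == 320

    def test_width_one_is_preserved_by_ceil_pooling(self):
        spec = ArchitectureSpec(conv_filters=(4,) * 8, dropout_rates=(0.0,) * 9)
        last_pool = [s for name, s in shape_trace(spec) if name.startswith("max_pooling")][-1]
        assert last_pool[1] == 1  # ceil-mode keeps width 1 alive

    def test_realized_forward_shapes_match_trace(self):
        from ddecnn.cnn import _MaxPoolWidth2

        model = CNNClassifier(DEFAULT, TrainingConfig(seed=0))
        out = np.zeros((2, 20, 1, 20))
        pooled_widths = []
        for layer in model.layers:
            out = layer.forward(out)
            if isinstance(layer, _MaxPoolWidth2):
                pooled_widths.append(out.shape[3])
        assert pooled_widths == [10, 5, 3]
        assert out.shape == (2, 2)


class TestParamCounts:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(kind="conv", filters=32, in_channels=20), 5_792),
            (dict(kind="conv", filters=64, in_channels=32), 18_496),
            (dict(kind="conv", filters=128, in_channels=64), 73_856),
            (dict(kind="dense", units=128, inputs=384), 49_280),
            (dict(kind="dense", units=2, inputs=128), 258),
            (dict(kind="dropout"), 0),
            (dict(kind="pool"), 0),
        ],
    )
    def test_layer_counts(self, kwargs, expected):
        assert layer_param_count(**kwargs) == expected

    def test_default_total(self):
        assert total_param_count(DEFAULT) == 147_682

    def test_dense_only_architecture(self):
        spec = ArchitectureSpec(conv_filters=(), dropout_rates=(0.4,))
        assert flatten_size(spec) == 400
        assert total_param_count(spec) == 128 * 401 + 2 * 129 == 51_586

    def test_three_class_head(self):
        spec = ArchitectureSpec(n_classes=3)
        assert param_trace(spec)[-1][1] == 3 * 129 == 387

    def test_doubling_dense_units_doubles_dense_counts(self):
        base = dict(param_trace(DEFAULT))
        doubled = dict(param_trace(ArchitectureSpec(dense_units=256)))
        assert doubled["dense_1"] == 2 * base["dense_1"]
        assert doubled["dense_2"] == 2 * (256 + 1)

    def test_analytic_count_matches_realized_weights_for_random_specs(self):
        """Dual route: the declarative trace vs. the instantiated arrays."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_blocks = int(rng.integers(0, 4))
            spec = ArchitectureSpec(
                conv_filters=tuple(int(f) for f in rng.integers(1, 64, n_blocks)),
                kernel=(1 + 2 * int(rng.integers(0, 3)),) * 2,
                dense_units=int(rng.integers(1, 200)),
                n_classes=int(rng.integers(2, 6)),
                dropout_rates=(0.3,) * (n_blocks + 1),
                input_width=int(rng.integers(4, 30)),
                input_channels=int(rng.integers(1, 30)),
            )
            model = CNNClassifier(spec, TrainingConfig(seed=0))
            assert model.trainable_parameter_count == total_param_count(spec)


class TestSpecValidation:
    def test_bad_dropout(self):
        with pytest.raises(ConfigurationError):
            ArchitectureSpec(dropout_rates=(0.4, 0.4, 0.4, 1.0))

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            ArchitectureSpec(kernel=(2, 2))

    def test_bad_optimizer(self):
        with pytest.raises(ConfigurationError):
            TrainingConfig(optimizer="sgdm")

    def test_nonpositive_learning_rate(self):
        with pytest.raises(ConfigurationError):
            TrainingConfig(learning_rate=0.0)


class TestBuild:
    def test_same_seed_identical_initial_weights(self):
        cfg = TrainingConfig(seed=5)
        a = build_model(DEFAULT, cfg)
        b = build_model(DEFAULT, cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_different_seed_differs(self):
        a = build_model(TINY_SPEC, TrainingConfig(seed=0))
        b = build_model(TINY_SPEC, TrainingConfig(seed=1))
        assert any(
            not np.array_equal(pa, pb)
            for pa, pb in zip(a.parameters(), b.parameters())
        )


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients of the full stack against central differences."""
        spec = ArchitectureSpec(
            conv_filters=(3,),
            dense_units=5,
            dropout_rates=(0.0, 0.0),
            input_width=6,
            input_channels=4,
        )
        model = CNNClassifier(spec, TrainingConfig(seed=1))
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 4, 1, 6))
        y = np.array([0, 1, 1, 0])

        logits = model.forward(x, training=False)
        _, grad = model.loss_and_grad(logits, y)
        model.backward(grad)
        analytic = [g.copy() for g in model.gradients()]

        eps = 1e-6
        for p, g in zip(model.parameters(), analytic):
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(10, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = model.loss_and_grad(model.forward(x), y)
                flat[idx] = orig - eps
                lm, _ = model.loss_and_grad(model.forward(x), y)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g.reshape(-1)[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_history_length_and_finite_loss(self, small_tensors):
        x, y = small_tensors
        cfg = TrainingConfig(epochs=3, seed=0)
        trained = train(build_model(TINY_SPEC, cfg), x[:64], y[:64])
        assert list(trained.history["epoch"]) == [1, 2, 3]
        assert np.isfinite(trained.history["train_loss"]).all()

    def test_weights_move_away_from_initialization(self, tiny_trained):
        model = tiny_trained.model
        assert any(
            not np.array_equal(p, q)
            for p, q in zip(model.parameters(), model._init_snapshot)
        )

    def test_single_class_degenerate_optimum(self, small_tensors):
        x, _ = small_tensors
        y = np.ones(40, dtype=int)
        cfg = TrainingConfig(epochs=10, seed=0)
        trained = train(build_model(TINY_SPEC, cfg), x[:40], y)
        assert (predict_label(trained, x[:40]) == 1).all()

    def test_separable_set_is_learned(self, tiny_trained, small_tensors):
        x, y = small_tensors
        acc = (predict_label(tiny_trained, x) == y).mean()
        assert acc >= 0.95

    def test_same_seed_reproduces_final_loss(self, small_tensors):
        x, y = small_tensors
        losses = []
        for _ in range(2):
            cfg = TrainingConfig(epochs=3, seed=9)
            trained = train(build_model(TINY_SPEC, cfg), x[:64], y[:64])
            losses.append(trained.history["train_loss"].iloc[-1])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_shape_mismatch_rejected(self, small_tensors):
        x, y = small_tensors
        model = build_model(TINY_SPEC, TrainingConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            model.fit(x[:, :, :, :10], y)

    def test_loss_nonincreasing_on_separable_toy_set(self, small_tensors):
        """First-to-last epoch loss decreases in >= 95% of seeded runs."""
        x, y = small_tensors
        wins = 0
        for seed in range(20):
            cfg = TrainingConfig(epochs=4, seed=seed, batch_size=16)
            trained = train(build_model(TINY_SPEC, cfg), x[:96], y[:96])
            loss = trained.history["train_loss"]
            wins += loss.iloc[-1] < loss.iloc[0]
        assert wins >= 19


class TestPredict:
    def test_probability_rows_sum_to_one(self, tiny_trained, small_tensors):
        x, _ = small_tensors
        proba = predict_proba(tiny_trained, x[:16])
        assert (proba >= 0).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_head_gives_uniform_probabilities(self, small_tensors):
        x, _ = small_tensors
        model = build_model(TINY_SPEC, TrainingConfig(seed=0))
        head = model.layers[-1]
        head.w[...] = 0.0
        head.b[...] = 0.0
        proba = model.predict_proba(x[:8])
        np.testing.assert_allclose(proba, 0.5, atol=1e-12)

    def test_argmax_consistency(self, tiny_trained, small_tensors):
        x, _ = small_tensors
        np.testing.assert_array_equal(
            predict_proba(tiny_trained, x).argmax(axis=1),
            predict_label(tiny_trained, x),
        )


class TestPersistence:
    def test_round_trip_predictions(self, tiny_trained, small_tensors, tmp_path):
        x, _ = small_tensors
        save_model(tiny_trained, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        np.testing.assert_allclose(
            predict_proba(loaded, x[:20]),
            predict_proba(tiny_trained, x[:20]),
            atol=1e-6,
        )
        assert loaded.feature_meta == {"denominator": "sqrt"}
        assert loaded.train_ids == tiny_trained.train_ids

    def test_missing_directory(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "absent")

    def test_mismatched_spec_detected(self, tiny_trained, tmp_path):
        import json

        save_model(tiny_trained, tmp_path / "model")
        meta_file = tmp_path / "model" / "model.json"
        meta = json.loads(meta_file.read_text())
        meta["architecture"]["dense_units"] = 999
        meta_file.write_text(json.dumps(meta))
        with pytest.raises(IncompatibleModelError):
            load_model(tmp_path / "model")
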