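import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arborview._nn import softmax
from arborview.cnn_classifier import (
    CNNConfig,
    build_model,
    encode_labels,
    images_to_array,
    load_weights,
    predict,
    save_weights,
    train,
)
from arborview.projection import GrayImage


def count_params_by_hand(input_hw, conv_filters, kernel, dense_units, n_classes):
    """Independent layer-shape arithmetic: same-padded convs, 2x2/2 pools."""
    h, w = input_hw
    c_in = 1
    total = 0
    for f in conv_filters:
        total += (kernel * kernel * c_in + 1) * f
        c_in = f
        h, w = h // 2, w // 2  # valid 2x2 pooling, stride 2
    flat = h * w * c_in
    total += (flat + 1) * dense_units
    total += (dense_units + 1) * n_classes
    return total


class TestBuildModel:
    def test_layer_inventory(self):
        model = build_model(CNNConfig())
        types = [row["type"] for row in model.summary()]
        assert types.count("conv2d") == 4
        assert types.count("maxpool2d") == 4
        assert types.count("dropout") == 2
        assert types.count("dense") == 2

    def test_output_layer_is_seven_unit_softmax(self):
        model = build_model(CNNConfig())
        last = model.summary()[-1]
        assert last["units"] == 7
        assert last["activation"] == "softmax"
        assert model.output_shape == (7,)

    def test_conv_filter_progression(self):
        model = build_model(CNNConfig())
        filters = [r["filters"] for r in model.summary() if r["type"] == "conv2d"]
        assert filters == [8, 16, 32, 64]

    @pytest.mark.parametrize(
        "config",
        [
            CNNConfig(),
            CNNConfig(input_shape=(32, 32, 1), n_classes=2),
        ],
        ids=["default_150x100", "reduced_32x32"],
    )
    def test_parameter_count_matches_arithmetic_oracle(self, config):
        model = build_model(config)
        expected = count_params_by_hand(
            config.input_shape[:2],
            config.conv_filters,
            config.kernel,
            config.dense_units,
            config.n_classes,
        )
        assert model.n_params == expected

    def test_input_too_small_for_four_pools_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            build_model(CNNConfig(input_shape=(8, 8, 1)))

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            CNNConfig(n_classes=1)
        with pytest.raises(ValueError):
            CNNConfig(dropout_after_dense=1.0)


def toy_dataset(n=20, size=32, seed=0):
    """Separable 2-class toy: dark half on the left vs. on the right."""
    rng = np.random.default_rng(seed)
    x = np.ones((n, size, size, 1), dtype=np.float32)
    y = np.zeros((n, 2), dtype=np.float32)
    half = size // 2
    for i in range(n):
        c = i % 2
        sl = slice(0, half) if c == 0 else slice(half, size)
        x[i, :, sl, 0] = rng.random((size, half)) * 0.3
        y[i, c] = 1.0
    return x, y


TOY_CONFIG = CNNConfig(input_shape=(32, 32, 1), n_classes=2, batch_size=8, seed=0)


class TestTrain:
    def test_overfits_separable_toy_data(self):
        x, y = toy_dataset()
        cfg = CNNConfig(**{**TOY_CONFIG.__dict__, "epochs": 30})
        model = build_model(cfg)
        result = train(model, x, y, cfg)
        assert result.history["accuracy"][-1] == 1.0
        assert result.history["loss"][-1] <= result.history["loss"][0]
        assert len(result.history["loss"]) == 30
        assert all(np.isfinite(result.history["loss"]))

    def test_zero_epochs_leaves_model_untouched(self):
        x, y = toy_dataset()
        cfg = CNNConfig(**{**TOY_CONFIG.__dict__, "epochs": 0})
        model = build_model(cfg)
        before = model.get_weights()
        result = train(model, x, y, cfg)
        assert result.history == {}
        for b, a in zip(before, model.get_weights()):
            np.testing.assert_array_equal(b, a)

    def test_label_shape_mismatch_rejected(self):
        x, y = toy_dataset()
        cfg = TOY_CONFIG
        model = build_model(cfg)
        with pytest.raises(ValueError, match="labels"):
            train(model, x, y[:, :1], cfg)

    def test_validation_history_recorded(self):
        x, y = toy_dataset()
        cfg = CNNConfig(**{**TOY_CONFIG.__dict__, "epochs": 2})
        model = build_model(cfg)
        result = train(model, x[:16], y[:16], cfg, validation=(x[16:], y[16:]))
        assert len(result.history["val_accuracy"]) == 2


class TestPredict:
    def test_probabilities_form_simplex(self):
        model = build_model(TOY_CONFIG)
        x = np.random.default_rng(1).random((5, 32, 32, 1), dtype=np.float32)
        probs, labels = predict(model, x)
        assert probs.shape == (5, 2)
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_seven_class_vector_length(self):
        model = build_model(CNNConfig())
        x = np.zeros((2, 150, 100, 1), dtype=np.float32)
        probs, _ = predict(model, x)
        assert probs.shape[1] == 7

    def test_hard_label_is_argmax(self):
        model = build_model(TOY_CONFIG)
        x = np.random.default_rng(2).random((8, 32, 32, 1), dtype=np.float32)
        probs, labels = predict(model, x)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))

    def test_label_order_mapping(self):
        model = build_model(TOY_CONFIG)
        x = np.zeros((3, 32, 32, 1), dtype=np.float32)
        _, labels = predict(model, x, label_order=["left", "right"])
        assert set(labels) <= {"left", "right"}

    def test_wrong_shape_rejected(self):
        model = build_model(TOY_CONFIG)
        with pytest.raises(ValueError, match="shape"):
            predict(model, np.zeros((2, 16, 16, 1), dtype=np.float32))

    def test_prediction_bit_stable_without_dropout_effect(self):
        # dropout is inference-inactive, so repeated predicts are identical
        model = build_model(TOY_CONFIG)
        x = np.random.default_rng(3).random((4, 32, 32, 1), dtype=np.float32)
        a, _ = predict(model, x)
        b, _ = predict(model, x)
        np.testing.assert_array_equal(a, b)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    logits=st.lists(
        st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=9),
        min_size=1,
        max_size=8,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1)
)
def test_softmax_is_probability_simplex(logits):
    arr = np.array(logits, dtype=np.float64)
    p = softmax(arr)
    assert (p >= 0).all()
    np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-9)


def test_weights_roundtrip(tmp_path):
    x, y = toy_dataset()
    cfg = CNNConfig(**{**TOY_CONFIG.__dict__, "epochs": 2})
    model = build_model(cfg)
    train(model, x, y, cfg)
    save_weights(model, tmp_path / "w.npz")
    clone = build_model(cfg)
    load_weights(clone, tmp_path / "w.npz")
    pa, _ = predict(model, x)
    pb, _ = predict(clone, x)
    np.testing.assert_array_equal(pa, pb)


def test_encode_labels_and_image_array():
    onehot = encode_labels(["b", "a", "b"], ["a", "b"])
    np.testing.assert_array_equal(onehot, [[0, 1], [1, 0], [0, 1]])
    with pytest.raises(ValueError, match="not in label set"):
        encode_labels(["c"], ["a", "b"])
    img = GrayImage(np.full((8, 8), 255, np.uint8), "t", 0)
    arr = images_to_array([img])
    assert arr.shape == (1, 8, 8, 1)
    assert arr.max() == 1.0
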