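"""CNN primitives vs loop oracles; extractor training behaviour."""

import numpy as np
import pytest

from dermoclass import synth
from dermoclass.features import (
    CompactCnnExtractor,
    ExtractorConfig,
    SgdConfig,
    conv2d_valid,
    extract_features,
    max_pool,
    sgd_step,
    train_extractor,
)


def conv_oracle(x, k, stride=1):
    kh, kw = k.shape
    oh = (x.shape[0] - kh) // stride + 1
    ow = (x.shape[1] - kw) // stride + 1
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            for a in range(kh):
                for b in range(kw):
                    out[i, j] += x[i * stride + a, j * stride + b] * k[a, b]
    return out


def pool_oracle(x, p):
    oh, ow = x.shape[0] // p, x.shape[1] // p
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            out[i, j] = x[i * p : (i + 1) * p, j * p : (j + 1) * p].max()
    return out


class TestConv:
    def test_identity_kernel(self, rng):
        x = rng.random((5, 5))
        np.testing.assert_array_equal(conv2d_valid(x, np.array([[1.0]])), x)

    def test_all_ones_with_stride(self):
        x = np.ones((4, 4))
        out = conv2d_valid(x, np.ones((2, 2)), stride=2)
        np.testing.assert_array_equal(out, np.full((2, 2), 4.0))

    def test_matches_loop_oracle(self, rng):
        x = rng.random((6, 6))
        k = rng.random((3, 3))
        np.testing.assert_allclose(
            conv2d_valid(x, k, stride=1), conv_oracle(x, k, 1), atol=1e-12
        )
        np.testing.assert_allclose(
            conv2d_valid(x, k, stride=2), conv_oracle(x, k, 2), atol=1e-12
        )

    def test_kernel_larger_than_input_rejected(self, rng):
        with pytest.raises(ValueError):
            conv2d_valid(rng.random((2, 2)), rng.random((3, 3)))


class TestPool:
    def test_constant_input(self):
        out = max_pool(np.full((6, 6), 0.4), 2)
        np.testing.assert_array_equal(out, np.full((3, 3), 0.4))

    def test_forced_two_by_two(self):
        out = max_pool(np.array([[1.0, 2.0], [3.0, 4.0]]), 2)
        np.testing.assert_array_equal(out, np.array([[4.0]]))

    def test_matches_loop_oracle(self, rng):
        x = rng.random((8, 8))
        np.testing.assert_allclose(max_pool(x, 2), pool_oracle(x, 2), atol=1e-12)

    def test_ragged_edges_padded(self, rng):
        x = rng.random((5, 5))
        out = max_pool(x, 2)
        assert out.shape == (3, 3)
        assert out[2, 2] == x[4, 4]  # single survivor of the padded window

    def test_bad_pool_size_rejected(self, rng):
        with pytest.raises(ValueError):
            max_pool(rng.random((4, 4)), 0)


def test_sgd_step_on_quadratic():
    # d/dw (w - 3)^2 at w=0 is -6; one step with lr 0.1 lands at 0.6
    w = np.array([0.0])
    grad = 2 * (w - 3.0)
    assert sgd_step(w, grad, 0.1)[0] == pytest.approx(0.6)


def _tiny_config(**kwargs):
    defaults = dict(
        conv_blocks=((4, 3, 1), (6, 3, 1)),
        feature_dim=6,
        input_size=32,
        sgd=SgdConfig(learning_rate=0.005, epochs=3, batch_size=4),
        seed=0,
    )
    defaults.update(kwargs)
    return ExtractorConfig(**defaults)


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, small_dataset):
        config = _tiny_config(
            sgd=SgdConfig(learning_rate=0.0, epochs=1, batch_size=4, momentum=0.0)
        )
        ex = CompactCnnExtractor(config)
        before = [layer.w.copy() for layer in ex.layers if hasattr(layer, "w")]
        head_before = ex.head_w.copy()
        masks = [it.truth_mask for it in small_dataset]
        x = np.stack(
            [ex.prepare_input(it.image, m) for it, m in zip(small_dataset, masks)]
        )
        y = np.array([1.0 if it.label == "melanoma" else 0.0 for it in small_dataset])
        ex.fit(x, y)
        after = [layer.w for layer in ex.layers if hasattr(layer, "w")]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)
        np.testing.assert_array_equal(head_before, ex.head_w)

    def test_training_reduces_loss(self, small_dataset):
        config = _tiny_config(sgd=SgdConfig(learning_rate=0.005, epochs=15, batch_size=4))
        masks = [it.truth_mask for it in small_dataset]
        ex = train_extractor(small_dataset, masks, config)
        assert ex.loss_history[-1] < ex.loss_history[0]

    def test_single_class_rejected(self, small_dataset):
        mel = [it for it in small_dataset if it.label == "melanoma"]
        with pytest.raises(ValueError):
            train_extractor(mel, [it.truth_mask for it in mel], _tiny_config())

    def test_deterministic_given_seed(self, small_dataset):
        masks = [it.truth_mask for it in small_dataset]
        ex1 = train_extractor(small_dataset, masks, _tiny_config())
        ex2 = train_extractor(small_dataset, masks, _tiny_config())
        f1 = extract_features(ex1, small_dataset[0].image, masks[0]).values
        f2 = extract_features(ex2, small_dataset[0].image, masks[0]).values
        np.testing.assert_array_equal(f1, f2)


class TestExtract:
    def test_untrained_extractor_rejected(self, small_dataset):
        ex = CompactCnnExtractor(_tiny_config())
        with pytest.raises(ValueError):
            extract_features(ex, small_dataset[0].image, small_dataset[0].truth_mask)

    def test_zero_network_maps_blank_input_to_zero_vector(self):
        # zero weights + zero biases + ReLU blocks: zeros propagate
        ex = CompactCnnExtractor(_tiny_config())
        for layer in ex.layers:
            if hasattr(layer, "w"):
                layer.w[:] = 0.0
                layer.b[:] = 0.0
        ex.trained = True
        blank = np.full((32, 32, 3), 0.5)  # centring maps 0.5 to exactly 0
        mask = np.ones((32, 32), dtype=bool)
        fv = extract_features(ex, blank, mask)
        np.testing.assert_array_equal(fv.values, np.zeros(6))

    def test_feature_length_fixed_across_image_sizes(self, small_dataset):
        masks = [it.truth_mask for it in small_dataset]
        ex = train_extractor(small_dataset, masks, _tiny_config())
        small = extract_features(ex, small_dataset[0].image, masks[0]).values
        big_img = np.tile(small_dataset[0].image, (2, 2, 1))
        big_mask = np.tile(masks[0], (2, 2))
        big = extract_features(ex, big_img, big_mask).values
        assert small.shape == big.shape == (6,)

    def test_same_image_twice_gives_identical_vectors(self, small_dataset):
        masks = [it.truth_mask for it in small_dataset]
        ex = train_extractor(small_dataset, masks, _tiny_config())
        a = extract_features(ex, small_dataset[0].image, masks[0]).values
        b = extract_features(ex, small_dataset[0].image, masks[0]).values
        np.testing.assert_array_equal(a, b)

    def test_classes_separate_in_feature_space(self):
        """Between-class centroid distance exceeds mean within-class
        distance after training on strongly contrasted classes."""
        config = synth.SynthConfig(n_per_class=12, seed=77)
        dataset = synth.generate_dataset(config)
        masks = [it.truth_mask for it in dataset]
        # full-size default extractor: the tiny test net underfits this
        ex = train_extractor(dataset, masks, ExtractorConfig(seed=0))
        feats = np.stack(
            [extract_features(ex, it.image, m).values for it, m in zip(dataset, masks)]
        )
        labels = np.array([it.label for it in dataset])
        mel = feats[labels == "melanoma"]
        ben = feats[labels == "benign"]
        between = np.linalg.norm(mel.mean(axis=0) - ben.mean(axis=0))
        within = np.mean(
            [np.linalg.norm(f - mel.mean(axis=0)) for f in mel]
            + [np.linalg.norm(f - ben.mean(axis=0)) for f in ben]
        )
        assert between > within


def test_config_invariants():
    with pytest.raises(ValueError):
        ExtractorConfig(conv_blocks=((4, 4, 1),), feature_dim=4)  # even kernel
    with pytest.raises(ValueError):
        ExtractorConfig(conv_blocks=((4, 3, 0),), feature_dim=4)  # zero stride
    with pytest.raises(ValueError):
        ExtractorConfig(feature_dim=16)  # mismatch with last block
    with pytest.raises(ValueError):
        ExtractorConfig(backend="resnet")


def test_checkpoint_round_trip(tmp_path, small_dataset):
    masks = [it.truth_mask for it in small_dataset]
    ex = train_extractor(small_dataset, masks, _tiny_config())
    path = tmp_path / "extractor.npz"
    ex.save(path)
    loaded = CompactCnnExtractor.load(path)
    a = extract_features(ex, small_dataset[0].image, masks[0]).values
    b = extract_features(loaded, small_dataset[0].image, masks[0]).values
    np.testing.assert_array_equal(a, b)
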