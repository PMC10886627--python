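"""Class weights, flip augmentation, model construction and training."""

import numpy as np
import pytest

from srshisto import nn
from srshisto.annotation import TissueClass
from srshisto.classifier import (
    ClassWeights,
    ModelConfig,
    augment_tile,
    build_model,
    compute_class_weights,
    predict_tiles,
    train,
    TrainedModel,
)


class TestClassWeights:
    def test_uniform_distribution_unit_weights(self):
        w = compute_class_weights(np.full(6, 1 / 6))
        assert all(v == pytest.approx(1.0) for v in w.weights.values())

    def test_three_class_hand_arithmetic(self):
        # K=3 toy: p = (0.5, 0.25, 0.25) -> w = (2/3, 4/3, 4/3), E[w] = 1
        p = np.array([0.5, 0.25, 0.25])
        w = 1.0 / (3 * p)
        assert w == pytest.approx([2 / 3, 4 / 3, 4 / 3])
        assert float(np.sum(p * w)) == pytest.approx(1.0)

    def test_expected_weight_is_one_for_random_distributions(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(6) * 0.8) + 1e-4
            p = p / p.sum()
            w = compute_class_weights(p).as_array()
            assert float(np.sum(p * w)) == pytest.approx(1.0, abs=1e-9)

    def test_zero_frequency_class_rejected(self):
        p = np.array([0.5, 0.5, 0.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="zero frequency"):
            compute_class_weights(p)


class TestAugmentTile:
    def test_double_horizontal_flip_is_identity(self, rng):
        tile = rng.random((8, 8, 3))
        assert np.array_equal(tile[:, ::-1, :][:, ::-1, :], tile)

    def test_seeded_rng_reproducible(self, rng):
        tile = rng.random((8, 8, 3))
        a = augment_tile(tile, np.random.default_rng(7))
        b = augment_tile(tile, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_marker_position_matches_index_arithmetic(self):
        # place a marker at (1, 2); flips map (i, j) -> (i | s-1-i, j | s-1-j)
        s = 6
        tile = np.zeros((s, s, 3))
        tile[1, 2, 0] = 1.0
        for seed in range(20):
            g1, g2 = np.random.default_rng(seed), np.random.default_rng(seed)
            out = augment_tile(tile, g1)
            flip_h = g2.random() < 0.5
            flip_v = g2.random() < 0.5
            i = s - 1 - 1 if flip_v else 1
            j = s - 1 - 2 if flip_h else 2
            assert out[i, j, 0] == 1.0 and out.sum() == 1.0

    def test_value_multiset_preserved(self, rng):
        tile = rng.random((8, 8, 3))
        out = augment_tile(tile, np.random.default_rng(3))
        assert np.array_equal(np.sort(out.ravel()), np.sort(tile.ravel()))


SMALL = ModelConfig(input_size=(16, 16, 3), backbone="small_cnn", epochs=2,
                    batch_size=10, seed=0)


class TestBuildModel:
    def test_output_shape_batch_by_six(self, rng):
        model = build_model(SMALL)
        out = model.forward(rng.random((4, 16, 16, 3)).astype(np.float32))
        assert out.shape == (4, 6)

    def test_softmax_rows_sum_to_one(self, rng):
        model = build_model(SMALL)
        probs = nn.softmax(model.forward(rng.random((5, 16, 16, 3)).astype(np.float32)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_identical_parameters(self):
        a = build_model(SMALL).state_dict()
        b = build_model(SMALL).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_incompatible_input_size_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            build_model(ModelConfig(input_size=(20, 20, 3), backbone="small_cnn"))

    def test_vgg19_backbone_has_sixteen_conv_layers(self):
        cfg = ModelConfig(input_size=(64, 64, 3), backbone="vgg19_full")
        model = build_model(cfg)
        convs = [l for l in model.layers if isinstance(l, nn.Conv2D)]
        assert len(convs) == 16
        assert model.forward(np.zeros((1, 64, 64, 3), dtype=np.float32)).shape == (1, 6)


def _separable_tiles(rng, n_per_class=10, size=16):
    """Each class gets a distinct constant intensity plus mild noise."""
    xs, ys = [], []
    for c in range(6):
        base = 0.1 + 0.15 * c
        for _ in range(n_per_class):
            xs.append(np.clip(base + rng.normal(0, 0.01, (size, size, 3)), 0, 1))
            ys.append(c)
    return np.stack(xs).astype(np.float32), np.array(ys)


class TestTraining:
    def test_overfits_separable_toy_set(self, rng):
        x, y = _separable_tiles(rng)
        cfg = ModelConfig(input_size=(16, 16, 3), backbone="small_cnn", epochs=25,
                          batch_size=10, learning_rate=1e-3, seed=1)
        tm = train(build_model(cfg), x, y, None, None, ClassWeights.uniform(), cfg)
        assert tm.history[-1]["train_acc"] == 1.0

    def test_loss_descends_on_separable_data(self, rng):
        x, y = _separable_tiles(rng, n_per_class=5)
        cfg = ModelConfig(input_size=(16, 16, 3), backbone="small_cnn", epochs=8,
                          batch_size=10, learning_rate=1e-3, seed=2)
        tm = train(build_model(cfg), x, y, None, None, ClassWeights.uniform(), cfg)
        assert tm.history[-1]["train_loss"] < tm.history[0]["train_loss"]

    def test_missing_class_rejected(self, rng):
        x, y = _separable_tiles(rng, n_per_class=2)
        keep = y != 3
        cfg = SMALL
        with pytest.raises(ValueError, match="muscle"):
            train(build_model(cfg), x[keep], y[keep], None, None,
                  ClassWeights.uniform(), cfg)

    def test_uniform_weights_equal_unweighted_loss(self, rng):
        logits = rng.normal(size=(10, 6))
        labels = rng.integers(0, 6, 10)
        lw, gw = nn.weighted_cross_entropy(logits, labels, np.ones(10))
        p = nn.softmax(logits)
        expected = float(np.mean(-np.log(p[np.arange(10), labels])))
        assert lw == pytest.approx(expected, abs=1e-9)

    def test_weighted_loss_matches_manual_expectation(self, rng):
        logits = rng.normal(size=(8, 6))
        labels = rng.integers(0, 6, 8)
        w = rng.uniform(0.5, 2.0, 8)
        lw, _ = nn.weighted_cross_entropy(logits, labels, w)
        p = nn.softmax(logits)
        manual = float(np.mean(w * -np.log(p[np.arange(8), labels])))
        assert lw == pytest.approx(manual, abs=1e-9)


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(99)
    x, y = _separable_tiles(rng, n_per_class=6)
    cfg = ModelConfig(input_size=(16, 16, 3), backbone="small_cnn", epochs=10,
                      batch_size=12, learning_rate=1e-3, seed=3)
    return train(build_model(cfg), x, y, None, None, ClassWeights.uniform(), cfg)


class TestPredict:

    def test_probabilities_sum_to_one(self, trained, rng):
        probs, _ = predict_tiles(trained, rng.random((3, 16, 16, 3)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicated_tile_identical_rows(self, trained, rng):
        tile = rng.random((16, 16, 3))
        probs, labels = predict_tiles(trained, np.stack([tile, tile, tile]))
        assert np.array_equal(probs[0], probs[1]) and np.array_equal(probs[1], probs[2])
        assert labels[0] == labels[1] == labels[2]

    def test_argmax_matches_max_scan(self, trained, rng):
        probs, labels = predict_tiles(trained, rng.random((6, 16, 16, 3)))
        for row, lab in zip(probs, labels):
            best = max(range(6), key=lambda i: (row[i], -i))
            assert lab == best

    def test_shape_mismatch_rejected(self, trained, rng):
        with pytest.raises(ValueError, match="shape"):
            predict_tiles(trained, rng.random((2, 8, 8, 3)))

    def test_save_load_round_trip(self, trained, tmp_path, rng):
        prefix = str(tmp_path / "model")
        trained.save(prefix)
        back = TrainedModel.load(prefix)
        x = rng.random((4, 16, 16, 3))
        pa, _ = predict_tiles(trained, x)
        pb, _ = predict_tiles(back, x)
        assert np.allclose(pa, pb, atol=1e-7)


def test_gradients_match_finite_differences(rng):
    """Backprop through conv/pool/dense agrees with numerical gradients."""
    model = nn.Sequential([
        nn.Conv2D(2, 3), nn.ReLU(), nn.MaxPool2(), nn.Flatten(), nn.Dense(12, 4),
    ])
    model.init(np.random.default_rng(0))
    x = rng.random((2, 4, 4, 2)).astype(np.float32)
    labels = np.array([1, 3])
    w = np.ones(2)

    def loss_at():
        return nn.weighted_cross_entropy(
            model.forward(x.copy(), training=True), labels, w
        )[0]

    loss, dlogits = nn.weighted_cross_entropy(model.forward(x, training=True), labels, w)
    model.backward(dlogits)
    eps = 1e-3
    for name, arr, grad in model.parameters():
        flat = arr.ravel()
        gflat = grad.ravel()
        for idx in rng.choice(flat.size, size=min(5, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss_at()
            flat[idx] = orig - eps
            down = loss_at()
            flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(gflat[idx], abs=2e-3), name
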