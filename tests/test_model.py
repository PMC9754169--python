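"""U-net construction, determinism, branch independence, training smoke."""

import numpy as np
import pytest

from ctdense import (UnetSpec, TrainConfig, UNet, build_unet, build_parallel,
                     build_multi_output, train_parallel, train_network,
                     predict_slices, save_model, load_model, PhantomConfig,
                     generate_dataset, make_grouping)
from ctdense.pipeline import assemble_training_arrays

TINY = UnetSpec(encoder_blocks=3, decoder_blocks=2, base_channels=4,
                dropout_rate=0.2, image_shape=(16, 16))


def _params_equal(a, b):
    pa, pb = a.parameters(), b.parameters()
    return len(pa) == len(pb) and all(
        np.array_equal(x.value, y.value) for x, y in zip(pa, pb))


class TestConstruction:
    def test_same_seed_same_parameters(self):
        assert _params_equal(build_unet(TINY, seed=5), build_unet(TINY, seed=5))
        assert not _params_equal(build_unet(TINY, seed=5), build_unet(TINY, seed=6))

    @pytest.mark.parametrize("shape", [(16, 16), (25, 30), (64, 64)])
    def test_output_matches_input_shape(self, shape, rng):
        spec = UnetSpec(encoder_blocks=3, decoder_blocks=2, base_channels=4,
                        image_shape=shape)
        net = build_unet(spec, seed=0)
        x = rng.random((1, 2) + shape).astype(np.float32)
        assert net.forward(x).shape == (1, 1) + shape

    def test_full_scale_shape_contract(self, rng):
        # the clinical geometry: 400 x 320 in, 400 x 320 out (narrow net)
        spec = UnetSpec(base_channels=2, max_channels=16, image_shape=(400, 320))
        net = build_unet(spec, seed=0)
        assert spec.effective_levels() == 8
        x = rng.random((1, 2, 400, 320)).astype(np.float32)
        assert net.forward(x).shape == (1, 1, 400, 320)

    def test_depth_autoreduces_for_small_images(self):
        spec = UnetSpec(base_channels=4, image_shape=(16, 16))
        assert spec.effective_levels() == 4
        assert UnetSpec(base_channels=4, image_shape=(64, 64)).effective_levels() == 6

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            UnetSpec(image_shape=(2, 2)).effective_levels()

    def test_mismatched_decoder_count_rejected(self):
        with pytest.raises(ValueError):
            UnetSpec(encoder_blocks=8, decoder_blocks=6)

    def test_untrained_residual_branch_is_linear_blend(self, rng):
        """Zero-initialized head + anchor: output is the fractional blend."""
        model = build_parallel(TINY, targets_per_gap=3, seed=0)
        left = rng.random((16, 16)).astype(np.float32)
        right = rng.random((16, 16)).astype(np.float32)
        out = predict_slices(model, left, right)
        for k, f in enumerate([0.25, 0.5, 0.75]):
            np.testing.assert_allclose(out[k], np.clip((1 - f) * left + f * right, 0, 1),
                                       atol=1e-6)


class TestParallel:
    def test_branch_count(self):
        assert build_parallel(TINY, 5, seed=0).targets_per_gap == 5
        assert build_parallel(TINY, 1, seed=0).targets_per_gap == 1

    def test_invalid_branch_count(self):
        with pytest.raises(ValueError):
            build_parallel(TINY, 0, seed=0)

    def test_branches_share_no_parameters(self):
        model = build_parallel(TINY, 3, seed=0)
        ids = [id(p) for net in model.branches for p in net.parameters()]
        assert len(ids) == len(set(ids))

    def test_branch_outputs_independent_of_siblings(self, rng):
        """Removing a branch leaves the other branches' outputs unchanged."""
        m5 = build_parallel(TINY, 5, seed=3)
        left = rng.random((16, 16)).astype(np.float32)
        right = rng.random((16, 16)).astype(np.float32)
        full = predict_slices(m5, left, right)
        del m5.branches[2]
        partial = np.stack([net.predict(np.stack([left, right])[None])[0, 0]
                            for net in m5.branches])
        np.testing.assert_array_equal(partial, full[[0, 1, 3, 4]])

    def test_predict_shape_and_clamp(self, rng):
        model = build_parallel(TINY, 3, seed=0)
        out = predict_slices(model, np.zeros((16, 16), np.float32),
                             np.zeros((16, 16), np.float32))
        assert out.shape == (3, 16, 16)
        assert np.isfinite(out).all()
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_multi_output_variant_shape(self, rng):
        net = build_multi_output(TINY, 3, seed=0)
        x = rng.random((2, 2, 16, 16)).astype(np.float32)
        assert net.forward(x).shape == (2, 3, 16, 16)


def _tiny_training_set():
    cfg = PhantomConfig(shape=(7, 16, 16), seed=11)
    train, _ = generate_dataset(cfg, n_volumes=6, master_seed=2)
    grouping = make_grouping(7, 2)
    return assemble_training_arrays(train, grouping)


class TestTraining:
    def test_training_reduces_validation_error(self):
        X, Y = _tiny_training_set()
        model = build_parallel(TINY, 1, seed=0)
        cfg = TrainConfig(learning_rate=3e-3, epochs=6, batch_size=4, seed=0,
                          validation_fraction=0.2)
        history = train_parallel(model, X, Y[:, :1], cfg)[0]
        assert history[-1]["val_mae"] <= history[0]["val_mae"]

    def test_training_is_deterministic(self):
        X, Y = _tiny_training_set()
        cfg = TrainConfig(learning_rate=3e-3, epochs=2, batch_size=4, seed=9)
        m1 = build_parallel(TINY, 2, seed=9)
        m2 = build_parallel(TINY, 2, seed=9)
        h1 = train_parallel(m1, X, Y[:, :2], cfg)
        h2 = train_parallel(m2, X, Y[:, :2], cfg)
        assert h1 == h2
        for a, b in zip(m1.branches, m2.branches):
            assert _params_equal(a, b)

    def test_branch_alone_equals_branch_in_parallel(self):
        """Branch k's training depends only on (seed, k), not on siblings."""
        X, Y = _tiny_training_set()
        cfg = TrainConfig(learning_rate=3e-3, epochs=2, batch_size=4, seed=4)
        parallel = build_parallel(TINY, 2, seed=4)
        train_parallel(parallel, X, Y[:, :2], cfg)

        from ctdense.model import _branch_seed
        alone = UNet(TINY, seed=_branch_seed(4, 1), anchor_weights=[2 / 3])
        rng = np.random.default_rng(np.random.SeedSequence((4, 1)))
        train_network(alone, X, Y[:, 1:2], cfg, rng=rng)
        assert _params_equal(alone, parallel.branches[1])

    def test_target_position_count_checked(self):
        X, Y = _tiny_training_set()
        model = build_parallel(TINY, 3, seed=0)
        cfg = TrainConfig(epochs=1, seed=0)
        with pytest.raises(ValueError, match="positions"):
            train_parallel(model, X, Y[:, :1], cfg)


def test_checkpoint_round_trip(tmp_path, rng):
    X, Y = _tiny_training_set()
    model = build_parallel(TINY, 2, seed=1)
    cfg = TrainConfig(learning_rate=3e-3, epochs=1, batch_size=4, seed=1)
    train_parallel(model, X, Y[:, :2], cfg)
    path = tmp_path / "model.npz"
    save_model(model, path)
    loaded = load_model(path)
    left = rng.random((16, 16)).astype(np.float32)
    right = rng.random((16, 16)).astype(np.float32)
    np.testing.assert_array_equal(predict_slices(loaded, left, right),
                                  predict_slices(model, left, right))
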