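"""Loss, augmentation, resizing, and training-loop behaviour."""

import dataclasses

import numpy as np
import pytest

from ctrseg import io
from ctrseg.ctr import compute_ctr
from ctrseg.errors import ParameterError
from ctrseg.model import ModelConfig
from ctrseg.phantom import PhantomParams, generate_dataset, sample_phantom
from ctrseg.train import (
    ALL_AUGMENTATIONS,
    AugmentConfig,
    NO_AUGMENT,
    TrainConfig,
    augment_pair,
    jaccard_loss,
    predict_mask,
    resize_image,
    resize_mask,
    soft_jaccard_with_grad,
    train,
)


class TestJaccardLoss:
    def test_one_hot_perfect_prediction_is_zero(self, rng):
        target = rng.integers(0, 3, (6, 6)).astype(np.uint8)
        probs = np.moveaxis(np.eye(3, dtype=np.float32)[target], -1, 0)
        assert jaccard_loss(probs, target) == pytest.approx(0.0, abs=1e-5)

    def test_single_pixel_uniform_probabilities(self):
        """One pixel, three classes, p = 1/3 everywhere: the true class
        contributes 1 - (1/3)/1 = 2/3, each wrong class 1 - 0/(1/3) = 1,
        so the class sum is 8/3."""
        probs = np.full((3, 1, 1), 1.0 / 3.0)
        target = np.array([[1]], dtype=np.uint8)
        assert jaccard_loss(probs, target, smooth_eps=1e-12) == pytest.approx(
            8.0 / 3.0, abs=1e-6)

    def test_bounded_by_n_classes(self, rng):
        for _ in range(200):
            h = int(rng.integers(1, 9))
            raw = rng.random((3, h, h))
            probs = raw / raw.sum(axis=0, keepdims=True)
            target = rng.integers(0, 3, (h, h)).astype(np.uint8)
            loss = jaccard_loss(probs, target)
            assert 0.0 <= loss <= 3.0

    def test_positive_unless_perfect(self, rng):
        target = rng.integers(0, 3, (4, 4)).astype(np.uint8)
        probs = np.moveaxis(np.eye(3)[target], -1, 0).astype(float)
        probs = 0.9 * probs + 0.1 / 3.0
        assert jaccard_loss(probs, target) > 1e-3

    def test_gradient_matches_finite_differences(self, rng):
        probs = rng.random((1, 3, 4, 4))
        probs /= probs.sum(axis=1, keepdims=True)
        target = rng.integers(0, 3, (1, 4, 4)).astype(np.uint8)
        loss, grad = soft_jaccard_with_grad(probs, target)
        eps = 1e-7
        for _ in range(10):
            i = tuple(rng.integers(0, s) for s in probs.shape)
            p2 = probs.copy()
            p2[i] += eps
            num = (soft_jaccard_with_grad(p2, target)[0] - loss) / eps
            assert num == pytest.approx(grad[i], rel=1e-3, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            jaccard_loss(np.zeros((3, 4, 4)), np.zeros((5, 5), np.uint8))


class TestAugmentPair:
    @pytest.fixture
    def pair(self, desk_params):
        s = sample_phantom(desk_params, seed=0)
        return s.image, s.mask

    def test_all_disabled_is_identity(self, pair):
        img, mask = augment_pair(*pair, NO_AUGMENT, seed=0)
        assert np.array_equal(img, pair[0])
        assert np.array_equal(mask, pair[1])

    def test_invert_flips_image_only(self, pair):
        cfg = AugmentConfig(enabled=frozenset({"invert"}), p_invert=1.0)
        img, mask = augment_pair(*pair, cfg, seed=0)
        assert np.allclose(img, 1.0 - pair[0])
        assert np.array_equal(mask, pair[1])

    def test_photometric_leaves_mask_untouched(self, pair):
        cfg = AugmentConfig(
            enabled=frozenset({"random_brightness_contrast", "invert"}),
            p_random_brightness_contrast=1.0, p_invert=1.0)
        _, mask = augment_pair(*pair, cfg, seed=3)
        assert np.array_equal(mask, pair[1])

    @pytest.mark.parametrize("name", sorted(ALL_AUGMENTATIONS))
    def test_each_transform_never_invents_labels(self, pair, name):
        cfg = AugmentConfig(enabled=frozenset({name}),
                            **{f"p_{name}": 1.0})
        for seed in range(10):
            _, mask = augment_pair(*pair, cfg, seed=seed)
            assert set(np.unique(mask)) <= set(np.unique(pair[1]))

    def test_full_battery_deterministic_under_seed(self, pair):
        cfg = AugmentConfig()
        a_img, a_mask = augment_pair(*pair, cfg, seed=77)
        b_img, b_mask = augment_pair(*pair, cfg, seed=77)
        assert np.array_equal(a_img, b_img)
        assert np.array_equal(a_mask, b_mask)

    def test_geometric_transform_moves_both(self, pair):
        cfg = AugmentConfig(enabled=frozenset({"shift_scale_rotate"}),
                            p_shift_scale_rotate=1.0)
        img, mask = augment_pair(*pair, cfg, seed=5)
        assert not np.array_equal(mask, pair[1])
        assert not np.array_equal(img, pair[0])

    def test_unknown_transform_rejected(self):
        with pytest.raises(ParameterError):
            AugmentConfig(enabled=frozenset({"mixup"}))


class TestResize:
    def test_mask_resize_preserves_label_set(self, desk_params):
        mask = sample_phantom(desk_params, seed=1).mask
        small = resize_mask(mask, (32, 32))
        assert set(np.unique(small)) <= set(np.unique(mask))

    def test_nearest_upscale_then_downscale_is_idempotent(self, rng):
        mask = rng.integers(0, 3, (16, 16)).astype(np.uint8)
        up = resize_mask(mask, (64, 64))
        back = resize_mask(up, (16, 16))
        assert np.array_equal(back, mask)

    def test_ctr_invariant_to_resize(self, desk_params):
        """CTR is a ratio of two horizontal spans, so resizing (even
        anisotropically) changes both spans equally."""
        big = dataclasses.replace(desk_params, width_px=128, height_px=128)
        for seed in range(10):
            mask = sample_phantom(big, seed).mask
            r0 = compute_ctr(mask).ctr
            for shape in ((64, 64), (512, 512), (256, 128)):
                r1 = compute_ctr(resize_mask(mask, shape)).ctr
                assert abs(r1 - r0) <= 2.0 / min(shape[1], mask.shape[1])

    def test_image_resize_range(self, desk_params):
        img = sample_phantom(desk_params, seed=0).image
        out = resize_image(img, (32, 32))
        assert out.shape == (32, 32)
        assert out.min() >= -1e-9 and out.max() <= 1 + 1e-9


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("tinydata")
    params = PhantomParams(width_px=64, height_px=64, jitter_sd=0.02)
    tr = generate_dataset(20, params, seed=100, out_dir=root / "train")
    va = generate_dataset(8, params, seed=101, out_dir=root / "val")
    return tr, va


class TestTrainLoop:
    def test_loss_decreases_across_seeds(self, tiny_dataset):
        """Two epochs on 20 phantoms: validation loss should not increase
        from epoch 1 to 2 in at least 8 of 10 seeds."""
        tr, va = tiny_dataset
        mc = ModelConfig(input_size_px=64, base_width=4,
                         encoder_depth=(1, 1, 1, 1))
        wins = 0
        for seed in range(10):
            tc = TrainConfig(epochs=2, batch_size=4, input_size_px=64,
                             seed=seed)
            _, hist = train(mc, tc, tr, va)
            wins += hist["val_loss"].iloc[1] <= hist["val_loss"].iloc[0]
        assert wins >= 8

    def test_same_seed_identical_history(self, tiny_dataset):
        tr, va = tiny_dataset
        mc = ModelConfig(input_size_px=64, base_width=4,
                         encoder_depth=(1, 1, 1, 1))
        tc = TrainConfig(epochs=2, batch_size=4, input_size_px=64, seed=5,
                         augment=AugmentConfig())
        _, h1 = train(mc, tc, tr, va)
        _, h2 = train(mc, tc, tr, va)
        assert h1.equals(h2)

    def test_history_schema(self, tiny_dataset):
        tr, va = tiny_dataset
        mc = ModelConfig(input_size_px=64, base_width=4,
                         encoder_depth=(1, 1, 1, 1))
        tc = TrainConfig(epochs=2, batch_size=8, input_size_px=64, seed=0)
        model, hist = train(mc, tc, tr, va)
        assert list(hist.columns) == ["epoch", "train_loss", "val_loss",
                                      "val_miou"]
        assert len(hist) == 2
        assert model.training_meta["best_epoch"] in (1, 2)

    def test_empty_manifest_rejected_before_training(self, tmp_path):
        bad = tmp_path / "empty.csv"
        bad.write_text("image_path,mask_path,true_ctr,seed\n")
        mc = ModelConfig(input_size_px=64, base_width=4)
        tc = TrainConfig(epochs=1, input_size_px=64)
        with pytest.raises(ParameterError):
            train(mc, tc, bad, bad)


class TestPredictMask:
    def test_returns_original_resolution_and_valid_labels(self, tiny_dataset):
        tr, va = tiny_dataset
        mc = ModelConfig(input_size_px=64, base_width=4,
                         encoder_depth=(1, 1, 1, 1))
        tc = TrainConfig(epochs=1, batch_size=8, input_size_px=64, seed=0)
        model, _ = train(mc, tc, tr, va)
        image = np.random.default_rng(0).random((96, 80))
        mask = predict_mask(model, image)
        assert mask.shape == (96, 80)
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_constant_image_returns_some_mask(self, tiny_dataset):
        tr, va = tiny_dataset
        mc = ModelConfig(input_size_px=64, base_width=4,
                         encoder_depth=(1, 1, 1, 1))
        tc = TrainConfig(epochs=1, batch_size=8, input_size_px=64, seed=0)
        model, _ = train(mc, tc, tr, va)
        mask = predict_mask(model, np.zeros((64, 64)))
        assert mask.shape == (64, 64)
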