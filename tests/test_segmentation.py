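"""Network architecture contracts, loss arithmetic, baseline and Dice."""

import numpy as np
import pytest

from mcsmdr.containers import SegMask
from mcsmdr.segmentation import (
    PNetConfig,
    baseline_segment,
    build_pnet,
    dice,
    load_model,
    save_model,
    segment,
    train_pnet,
    weighted_cross_entropy,
)
from mcsmdr.segmentation.pnet import dihedral_transforms
from mcsmdr.synthetic import SpheroidGeometry, make_segmentation_dataset, \
    make_spheroid_stack, PHENOTYPES


def small_config(**kw):
    args = dict(channels_per_block=4, input_size=64, max_epochs=2,
                dropout_rate=0.1, seed=0)
    args.update(kw)
    return PNetConfig(**args)


def analytic_param_count(c: int, n_classes: int = 2) -> int:
    """Hand-computed parameter count for the 13-conv + 2x1x1 design."""
    count = 3 * 3 * 1 * c + c            # first conv: 1 -> c
    count += 12 * (3 * 3 * c * c + c)    # remaining 12 convs: c -> c
    count += 5 * c * c + c               # 1x1 on the 5-block concat
    count += c * n_classes + n_classes   # final 1x1 classifier
    return count


class TestArchitecture:
    def test_parameter_count_matches_formula(self):
        for c in (4, 8):
            model = build_pnet(small_config(channels_per_block=c))
            assert model.n_parameters() == analytic_param_count(c)

    def test_resolution_preserved(self):
        model = build_pnet(small_config())
        x = np.zeros((1, 128, 128, 1), np.float32)
        scores = model.forward(x, training=False)
        assert scores.shape == (1, 128, 128, 2)

    def test_same_seed_identical_init(self):
        m1 = build_pnet(small_config(seed=42))
        m2 = build_pnet(small_config(seed=42))
        assert all(np.array_equal(a, b) for a, b in zip(m1.params(), m2.params()))

    def test_thirteen_conv_layers_in_five_blocks(self):
        model = build_pnet(small_config())
        n_convs = sum(sum(1 for l in blk.layers if hasattr(l, "W"))
                      for blk in model.blocks)
        assert n_convs == 13
        assert len(model.blocks) == 5

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PNetConfig(convs_per_block=(2, 2, 3, 3, 4))
        with pytest.raises(ValueError):
            PNetConfig(kernel_size=5)
        with pytest.raises(ValueError):
            PNetConfig(class_weights=(0.0, 10.0))
        with pytest.raises(ValueError):
            PNetConfig(dropout_rate=1.0)


class TestWeightedCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        truth = np.array([[0, 1], [1, 0]], np.uint8)
        scores = np.zeros((2, 2, 2), np.float32)
        scores[..., 1] = np.where(truth, 50.0, -50.0)
        assert weighted_cross_entropy(scores, truth) == pytest.approx(0.0, abs=1e-6)

    def test_single_foreground_pixel_weight_ten(self):
        # p(foreground) = exp(-1) at the only (foreground) pixel:
        # loss = 10 * -log(exp(-1)) = 10
        truth = np.ones((1, 1), np.uint8)
        p = np.exp(-1.0)
        scores = np.zeros((1, 1, 2), np.float32)
        scores[..., 1] = np.log(p)
        scores[..., 0] = np.log(1.0 - p)
        assert weighted_cross_entropy(scores, truth) == pytest.approx(10.0, rel=1e-5)

    def test_uniform_half_on_balanced_mask(self):
        # p = 0.5 everywhere, half foreground: mean{1, 10} * log 2 = 5.5 log 2
        truth = np.zeros((2, 2), np.uint8)
        truth[:, 1] = 1
        scores = np.zeros((2, 2, 2), np.float32)
        assert weighted_cross_entropy(scores, truth) == pytest.approx(
            5.5 * np.log(2.0), rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.zeros((2, 2, 2)), np.zeros((3, 3)))


class TestDice:
    def test_identical_masks(self):
        m = SegMask((np.arange(16).reshape(4, 4) % 3 == 0).astype(np.uint8))
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0, 0] = b[3, 3] = 1
        assert dice(a, b) == 0.0

    def test_half_overlap_squares(self):
        a = np.zeros((4, 4), np.uint8)
        b = np.zeros((4, 4), np.uint8)
        a[0:2, 0:2] = 1
        b[0:2, 1:3] = 1
        assert dice(a, b) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((4, 4), np.uint8)
        assert dice(z, z) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((3, 3), np.uint8), np.zeros((4, 4), np.uint8))


class TestAugmentation:
    def test_eight_transforms(self):
        img = np.arange(16.0).reshape(4, 4)
        outs = dihedral_transforms(img)
        assert len(outs) == 8
        flat = {tuple(o.ravel()) for o in outs}
        assert len(flat) == 8  # all distinct for an asymmetric image

    def test_image_and_mask_transform_consistently(self):
        rng = np.random.default_rng(0)
        img = rng.random((6, 6))
        mask = (img > 0.5).astype(np.uint8)
        for ti, tm in zip(dihedral_transforms(img), dihedral_transforms(mask)):
            assert np.array_equal((ti > 0.5).astype(np.uint8), tm)


class TestBaseline:
    def test_clean_disk_near_exact(self):
        geo = SpheroidGeometry(center=(64, 64), radius=40.0, boundary_softness=1.0,
                               inhomogeneity_amplitude=0.0, background_noise_sd=0.0)
        stack, gt = make_spheroid_stack(PHENOTYPES["sensitive"], geo, seed=0,
                                        image_size=128, duration_h=0.0)
        assert dice(baseline_segment(stack.phase[0]), gt[0]) >= 0.98

    def test_blank_frame_empty_mask(self):
        mask = baseline_segment(np.full((64, 64), 3.0))
        assert mask.is_empty()
        assert mask.empty_warning
        assert mask.source == "baseline"


class TestTraining:
    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_pnet([], [], small_config())

    def test_loss_decreases_over_three_seeds(self):
        frames, masks, _ = make_segmentation_dataset(4, seed=0, image_size=64)
        finals, firsts = [], []
        for seed in range(3):
            _, rep = train_pnet(frames, masks, small_config(max_epochs=3, seed=seed))
            firsts.append(rep.epoch_losses[0])
            finals.append(rep.epoch_losses[-1])
        assert np.median(finals) < np.median(firsts)

    def test_same_seed_same_final_loss(self):
        frames, masks, _ = make_segmentation_dataset(2, seed=1, image_size=64)
        cfg = small_config(max_epochs=2, seed=7)
        _, r1 = train_pnet(frames, masks, cfg)
        _, r2 = train_pnet(frames, masks, cfg)
        assert r1.epoch_losses == r2.epoch_losses

    def test_overfit_single_easy_image(self):
        geo = SpheroidGeometry(center=(32, 32), radius=20.0, boundary_softness=1.0,
                               inhomogeneity_amplitude=0.0, background_noise_sd=10.0)
        stack, gt = make_spheroid_stack(PHENOTYPES["sensitive"], geo, seed=0,
                                        image_size=64, duration_h=0.0)
        cfg = small_config(channels_per_block=8, input_size=64, max_epochs=120,
                           dropout_rate=0.0, seed=0)
        model, _ = train_pnet([stack.phase[0]], [gt[0]], cfg)
        pred = segment(model, stack.phase[0])
        assert dice(pred, gt[0]) >= 0.95

    def test_augmentation_expands_eightfold(self):
        frames, masks, _ = make_segmentation_dataset(2, seed=1, image_size=64)
        _, rep = train_pnet(frames, masks, small_config(max_epochs=1))
        assert rep.n_augmented == 16
        assert rep.n_training_pairs == 2


class TestSegment:
    def test_output_shape_matches_frame(self):
        model = build_pnet(small_config())
        frame = np.random.default_rng(0).random((100, 90)).astype(np.float32)
        mask = segment(model, frame)
        assert mask.pixels.shape == (100, 90)
        assert mask.source == "pnet"

    def test_all_background_scores_flagged_empty(self):
        model = build_pnet(small_config())

        class Stub:
            config = model.config

            def forward(self, x, training=False):
                scores = np.zeros(x.shape[:-1] + (2,), np.float32)
                scores[..., 0] = 10.0  # background wins everywhere
                return scores

        mask = segment(Stub(), np.zeros((64, 64), np.float32))
        assert mask.is_empty()
        assert mask.empty_warning

    def test_save_load_round_trip(self, tmp_path):
        model = build_pnet(small_config(seed=3))
        save_model(tmp_path / "m.npz", model)
        loaded = load_model(tmp_path / "m.npz")
        x = np.random.default_rng(1).random((1, 64, 64, 1)).astype(np.float32)
        assert np.allclose(model.forward(x, False), loaded.forward(x, False))
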