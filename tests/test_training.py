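"""Splitting, loss, schedule, curriculum, augmentation and the training loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardiomapseg import phantom, training as T
from cardiomapseg.network import ModelConfig, build_model


class TestSplitCases:
    def test_exact_division(self):
        ids = [f"c{i}" for i in range(100)]
        split = T.split_cases(ids, (0.65, 0.20, 0.15), seed=0)
        sizes = {p: len(split.cases(p)) for p in ("train", "val", "test")}
        assert sizes == {"train": 65, "val": 20, "test": 15}

    def test_same_seed_reproduces_assignment(self):
        ids = [f"c{i}" for i in range(37)]
        a = T.split_cases(ids, seed=9)
        b = T.split_cases(ids, seed=9)
        assert a.assignment == b.assignment

    @pytest.mark.parametrize("seed", range(50))
    def test_no_leakage_every_case_in_exactly_one_partition(self, seed):
        ids = [f"c{i}" for i in range(41)]
        split = T.split_cases(ids, seed=seed)
        parts = [set(split.cases(p)) for p in ("train", "val", "test")]
        assert parts[0] | parts[1] | parts[2] == set(ids)
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_sizes_stay_within_one_case_of_rounded_targets(self):
        split = T.split_cases([f"c{i}" for i in range(262)], seed=3)
        sizes = [len(split.cases(p)) for p in ("train", "val", "test")]
        assert sum(sizes) == 262
        for size, ratio in zip(sizes, (0.65, 0.20, 0.15)):
            assert abs(size - round(262 * ratio)) <= 1

    def test_bad_ratios_and_tiny_cohorts_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            T.split_cases(list("abcdef"), (0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            T.split_cases(["a", "b"])


class TestJaccardLoss:
    def test_perfect_one_hot_prediction_is_zero(self):
        labels = np.zeros((8, 8), np.int64)
        labels[2:6, 2:6] = 1
        labels[0:2, 0:2] = 2
        probs = np.eye(3)[labels]
        assert T.jaccard_loss(probs, labels) < 1e-5

    def test_uniform_prediction_matches_direct_summation_oracle(self):
        labels = np.zeros((4, 4), np.int64)
        labels[:2] = 1
        labels[2:] = 2
        probs = np.full((4, 4, 3), 1 / 3)
        # oracle: per class, I = sum(p*t), U = sum(p + t - p*t)
        expected = 0.0
        for c in (1, 2):
            t = (labels == c).astype(float)
            inter = (1 / 3 * t).sum()
            union = (1 / 3 + t - 1 / 3 * t).sum()
            expected += 1 - (inter + 1e-6) / (union + 1e-6)
        expected /= 2
        assert T.jaccard_loss(probs, labels) == pytest.approx(expected, rel=1e-12)

    def test_swapped_classes_score_strictly_worse(self):
        labels = np.zeros((6, 6), np.int64)
        labels[:3] = 1
        labels[3:] = 2
        matched = np.eye(3)[labels]
        swapped = matched[..., [0, 2, 1]]
        assert T.jaccard_loss(swapped, labels) > T.jaccard_loss(matched, labels)

    def test_probabilities_outside_unit_interval_rejected(self):
        labels = np.zeros((2, 2), np.int64)
        with pytest.raises(ValueError):
            T.jaccard_loss(np.full((2, 2, 3), 1.5), labels)

    def test_one_hot_loss_equals_one_minus_hard_iou(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            truth = rng.integers(0, 3, (10, 10))
            pred = rng.integers(0, 3, (10, 10))
            probs = np.eye(3)[pred]
            ious = []
            for c in (1, 2):
                inter = np.sum((pred == c) & (truth == c))
                union = np.sum((pred == c) | (truth == c))
                ious.append(1.0 if union == 0 else inter / union)
            assert T.jaccard_loss(probs, truth) == pytest.approx(
                1 - np.mean(ious), abs=1e-4)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(1, 3, 6, 6))
        labels = rng.integers(0, 3, (1, 6, 6))
        loss, grad = T.jaccard_loss_and_grad(logits, labels)
        for _ in range(8):
            idx = (0, rng.integers(3), rng.integers(6), rng.integers(6))
            eps = 1e-5
            lp = T.jaccard_loss_and_grad(
                np.where(np.zeros_like(logits), 0, logits) + _delta(logits.shape, idx, eps),
                labels)[0]
            lm = T.jaccard_loss_and_grad(logits - _delta(logits.shape, idx, eps), labels)[0]
            assert grad[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6, rel=1e-3)


def _delta(shape, idx, eps):
    d = np.zeros(shape)
    d[idx] = eps
    return d


class TestSchedule:
    CFG = T.TrainConfig(epochs=150, curriculum_switch_epoch=70,
                        restart_periods=(70, 80))

    def test_cosine_endpoints_and_midpoint(self):
        assert T.cosine_lr(0, 70, 1e-3, 1e-6) == pytest.approx(1e-3)
        assert T.cosine_lr(70, 70, 1e-3, 1e-6) == pytest.approx(1e-6)
        assert T.cosine_lr(35, 70, 1e-3, 1e-6) == pytest.approx((1e-3 + 1e-6) / 2)

    def test_restart_boundary_resets_to_lr_max(self):
        assert T.lr_at(0, self.CFG) == pytest.approx(1e-3)
        assert T.lr_at(70, self.CFG) == pytest.approx(1e-3)
        assert T.lr_at(150, self.CFG) == pytest.approx(1e-6)
        assert T.lr_at(69.999, self.CFG) < 2e-6

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(epoch=st.floats(0, 150))
    def test_rate_always_bounded_by_the_configured_extremes(self, epoch):
        lr = T.lr_at(epoch, self.CFG)
        assert self.CFG.lr_min - 1e-12 <= lr <= self.CFG.lr_max + 1e-12

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            T.TrainConfig(epochs=150, restart_periods=(60, 80))
        with pytest.raises(ValueError, match="restart boundary"):
            T.TrainConfig(epochs=150, curriculum_switch_epoch=75,
                          restart_periods=(70, 80))
        with pytest.raises(ValueError):
            T.lr_at(151, self.CFG)


class TestCurriculum:
    def manifest(self):
        kinds = ["T1map", "T2map"] + ["T1weighted"] * 8 + ["T2weighted"] * 3
        return pd.DataFrame({"map_kind": kinds, "index": range(len(kinds))})

    def test_phase_one_keeps_all_thirteen_samples(self):
        assert len(T.curriculum_filter(self.manifest(), 0, 70)) == 13

    def test_phase_two_keeps_only_the_two_maps(self):
        out = T.curriculum_filter(self.manifest(), 70, 70)
        assert sorted(out["map_kind"]) == ["T1map", "T2map"]

    def test_empty_manifest_stays_empty(self):
        empty = pd.DataFrame({"map_kind": pd.Series([], dtype=str)})
        assert len(T.curriculum_filter(empty, 0, 70)) == 0

    def test_unknown_kind_rejected(self):
        bad = pd.DataFrame({"map_kind": ["T1map", "FLAIR"]})
        with pytest.raises(ValueError, match="FLAIR"):
            T.curriculum_filter(bad, 0, 70)


class TestAugment:
    CFG = T.TrainConfig(epochs=2, curriculum_switch_epoch=1, restart_periods=(1, 1),
                        input_size=(32, 32), crop_fraction=(1.0, 1.0),
                        contrast_jitter=(1.0, 1.0), intensity_jitter=(0.0, 0.0))

    def image_and_mask(self):
        rng = np.random.default_rng(0)
        img = rng.normal(1000, 100, (32, 32)).astype(np.float32)
        mask = np.zeros((32, 32), np.uint8)
        mask[8:24, 8:24] = 2
        mask[12:20, 12:20] = 1
        return img, mask

    def test_zero_jitter_full_crop_is_identity(self):
        img, mask = self.image_and_mask()
        out_img, out_mask = T.augment(img, mask, self.CFG, np.random.default_rng(1))
        np.testing.assert_allclose(out_img, img, rtol=1e-6)
        np.testing.assert_array_equal(out_mask, mask)

    def test_same_seed_reproduces_the_augmentation(self):
        img, mask = self.image_and_mask()
        cfg = T.TrainConfig(epochs=2, curriculum_switch_epoch=1, restart_periods=(1, 1),
                            input_size=(32, 32))
        a = T.augment(img, mask, cfg, np.random.default_rng(5))
        b = T.augment(img, mask, cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_photometric_jitter_leaves_the_mask_untouched(self):
        img, mask = self.image_and_mask()
        cfg = T.TrainConfig(epochs=2, curriculum_switch_epoch=1, restart_periods=(1, 1),
                            input_size=(32, 32), crop_fraction=(1.0, 1.0),
                            contrast_jitter=(0.5, 2.0), intensity_jitter=(-0.5, 0.5))
        _, out_mask = T.augment(img, mask, cfg, np.random.default_rng(2))
        np.testing.assert_array_equal(out_mask, mask)

    def test_mask_class_counts_scale_with_crop_area(self):
        img, mask = self.image_and_mask()
        cfg = T.TrainConfig(epochs=2, curriculum_switch_epoch=1, restart_periods=(1, 1),
                            input_size=(64, 64), crop_fraction=(1.0, 1.0),
                            contrast_jitter=(1.0, 1.0), intensity_jitter=(0.0, 0.0))
        _, out_mask = T.augment(img, mask, cfg, np.random.default_rng(3))
        # upsampling 2x quadruples the pixel count of each class
        for cls in (1, 2):
            assert int((out_mask == cls).sum()) == 4 * int((mask == cls).sum())

    def test_oversized_crop_rejected(self):
        img, mask = self.image_and_mask()
        cfg = T.TrainConfig(epochs=2, curriculum_switch_epoch=1, restart_periods=(1, 1),
                            input_size=(32, 32), crop_fraction=(1.2, 1.2))
        with pytest.raises(ValueError, match="crop"):
            T.augment(img, mask, cfg, np.random.default_rng(4))


@pytest.fixture(scope="module")
def tiny_setup():
    acq = phantom.AcquisitionSpec(image_shape=(32, 32))
    sampler = phantom.GeometrySamplerConfig(
        basal_epi_radius=(8.0, 10.0), wall_thickness=(2.5, 3.5),
        center_jitter_px=2.0, gap_probability=0.0)
    cases = phantom.generate_phantom_cohort(6, seed=77, acquisition=acq,
                                            sampler=sampler)
    samples = T.samples_from_cases(cases, include_weighted=False)
    split = T.split_cases([c.case_id for c in cases], (0.5, 0.25, 0.25), seed=0)
    cfg = T.TrainConfig(epochs=2, curriculum_switch_epoch=1, restart_periods=(1, 1),
                        batch_size=4, input_size=(32, 32), seed=0)
    model_cfg = ModelConfig(encoder_kind="small-resnet", input_size=(32, 32),
                            encoder_stage_widths=(4, 8, 16, 24))
    return samples, split, cfg, model_cfg


class TestTrainLoop:
    def test_two_runs_same_seed_are_identical(self, tiny_setup):
        samples, split, cfg, model_cfg = tiny_setup
        results = []
        for _ in range(2):
            model = build_model(model_cfg, seed=0)
            results.append(T.train(model, samples, split, cfg))
        assert results[0].history["val_dice"].tolist() == results[1].history["val_dice"].tolist()
        assert results[0].history["loss"].tolist() == results[1].history["loss"].tolist()

    def test_history_lr_follows_the_schedule(self, tiny_setup):
        samples, split, cfg, model_cfg = tiny_setup
        model = build_model(model_cfg, seed=1)
        result = T.train(model, samples, split, cfg)
        for _, row in result.history.iterrows():
            assert row["lr"] == pytest.approx(T.lr_at(row["epoch"], cfg))

    def test_empty_partition_rejected(self, tiny_setup):
        samples, split, cfg, model_cfg = tiny_setup
        bad_split = T.SplitAssignment(
            {cid: "train" for cid in split.assignment}, split.ratios, 0)
        with pytest.raises(T.TrainingError, match="empty"):
            T.train(build_model(model_cfg, seed=0), samples, bad_split, cfg)


def test_samples_from_cases_counts(cohort):
    with_weighted = T.samples_from_cases(cohort[:2], include_weighted=True)
    maps_only = T.samples_from_cases(cohort[:2], include_weighted=False)
    assert len(with_weighted) == 2 * 3 * 13  # 2 maps + 8 T1w + 3 T2w per slice
    assert len(maps_only) == 2 * 3 * 2
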