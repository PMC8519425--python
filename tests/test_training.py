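"""Training-loop tests: crop sampling, augmentation, schedules, checkpoints.

Actual optimization runs here are deliberately short (tens of iterations);
the convergence properties of the full tiny profile are exercised by the
acceptance suite.
"""

import numpy as np
import pytest
from scipy import stats

from virtustain.imaging_io import Channel
from virtustain.losses import LossConfig
from virtustain.training import (
    NucleiCenters,
    TrainConfig,
    TrainExample,
    extract_nuclei_centers,
    augment,
    load_checkpoint,
    sample_crop,
    save_checkpoint,
    train_channel,
    validation_loss,
)


class TestExtractNucleiCenters:
    def test_square_centroid(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[20:30, 40:50] = 1
        centers = extract_nuclei_centers(mask)
        assert len(centers.centers) == 1
        r, c = centers.centers[0]
        assert r in (24, 25) and c in (44, 45)

    def test_empty_mask(self):
        assert extract_nuclei_centers(np.zeros((16, 16), dtype=np.uint8)).centers == []

    def test_two_blobs_two_centers(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[5:10, 5:10] = 1
        mask[40:50, 40:50] = 1
        assert len(extract_nuclei_centers(mask).centers) == 2


def _example(h=128, w=128, seed=0):
    rng = np.random.default_rng(seed)
    return TrainExample(stack=rng.random((7, h, w)), target=rng.random((h, w)),
                        mask=(rng.random((h, w)) > 0.9).astype(np.uint8))


class TestSampleCrop:
    def _cfg(self, **kw):
        base = dict(channel=Channel.NUCLEI, crop=64, max_center_offset=24,
                    model=TrainConfig.tiny("nuclei").model, iterations=10)
        base.update(kw)
        return TrainConfig(**base)

    def test_center_crop_hits_nucleus_center(self):
        cfg = self._cfg(p_center_crop=1.0, max_center_offset=0)
        centers = NucleiCenters([(70, 70)])
        cropped = sample_crop(_example(), centers, cfg, np.random.default_rng(0))
        # window centred on (70, 70): top-left (38, 38)
        np.testing.assert_array_equal(cropped.target,
                                      _example().target[38:102, 38:102])

    def test_chosen_nucleus_always_inside_crop(self):
        # offset bound below half the crop size keeps the anchor nucleus inside
        cfg = self._cfg(p_center_crop=1.0)
        ex = _example()
        rng = np.random.default_rng(1)
        centers = NucleiCenters([(64, 64)])
        for _ in range(200):
            c = sample_crop(ex, centers, cfg, rng)
            assert c.target.shape == (64, 64)
        assert cfg.max_center_offset < cfg.crop // 2

    def test_identical_window_for_stack_target_mask(self):
        cfg = self._cfg(p_center_crop=0.5)
        ex = _example()
        marker = (100, 30)
        ex.target[marker] = 5.0  # sentinel (values unused by cropping)
        ex.stack[:, marker[0], marker[1]] = 5.0
        ex.mask[marker] = 1
        rng = np.random.default_rng(3)
        for _ in range(50):
            c = sample_crop(ex, NucleiCenters([marker]), cfg, rng)
            where_t = np.argwhere(c.target == 5.0)
            where_s = np.argwhere(c.stack[0] == 5.0)
            if len(where_t):
                assert len(where_s)
                np.testing.assert_array_equal(where_t[0], where_s[0])

    def test_uniform_crop_distribution(self):
        # p_center_crop = 0: window origins should be uniform over valid range
        cfg = self._cfg(p_center_crop=0.0)
        h = w = 128
        ex = TrainExample(stack=np.zeros((7, h, w)),
                          target=np.arange(h * w, dtype=float).reshape(h, w))
        rng = np.random.default_rng(4)
        n_draws, n_pos = 5000, h - cfg.crop + 1
        tops, lefts = [], []
        for _ in range(n_draws):
            v = int(sample_crop(ex, None, cfg, rng).target[0, 0])
            tops.append(v // w)
            lefts.append(v % w)
        for origins in (tops, lefts):
            counts = np.bincount(origins, minlength=n_pos)
            expected = n_draws / n_pos
            chi2 = ((counts - expected) ** 2 / expected).sum()
            assert chi2 < stats.chi2.ppf(0.999, df=n_pos - 1)

    def test_image_smaller_than_crop_rejected(self):
        cfg = self._cfg()
        with pytest.raises(ValueError):
            sample_crop(_example(32, 32), None, cfg, np.random.default_rng(0))


class TestAugment:
    def test_lipid_mode_preserves_pixel_content(self):
        # flips and 90-degree rotations permute pixels without interpolation
        ex = _example(64, 64)
        out = augment(ex, np.random.default_rng(0), mode="lipids")
        assert np.allclose(np.sort(out.target, axis=None),
                           np.sort(np.clip(ex.target, 0, 1), axis=None))

    def test_double_horizontal_flip_is_identity(self):
        ex = _example(64, 64)
        flipped = TrainExample(stack=ex.stack[:, :, ::-1].copy(),
                               target=ex.target[:, ::-1].copy(),
                               mask=ex.mask[:, ::-1].copy())
        back = TrainExample(stack=flipped.stack[:, :, ::-1], target=flipped.target[:, ::-1],
                            mask=flipped.mask[:, ::-1])
        np.testing.assert_array_equal(back.target, ex.target)

    def test_ninety_degree_rotation_keeps_registration(self):
        ex = _example(64, 64)
        ex.target[:] = 0.0
        ex.stack[:] = 0.0
        ex.target[10, 20] = 1.0
        ex.stack[:, 10, 20] = 1.0
        # find a seed whose draw applies a non-trivial rotation
        for seed in range(20):
            out = augment(ex, np.random.default_rng(seed), mode="lipids")
            pos_t = tuple(np.argwhere(out.target == 1.0)[0])
            pos_s = tuple(np.argwhere(out.stack[3] == 1.0)[0])
            assert pos_t == pos_s

    def test_continuous_rotation_keeps_registration(self):
        ex = _example(64, 64)
        ex.target[:] = 0.0
        ex.stack[:] = 0.0
        ex.mask[:] = 0
        ex.target[20:26, 30:36] = 1.0
        ex.stack[:, 20:26, 30:36] = 1.0
        ex.mask[20:26, 30:36] = 1
        out = augment(ex, np.random.default_rng(5), mode="nuclei")
        com_t = np.array(np.argwhere(out.target > 0.5).mean(axis=0))
        com_s = np.array(np.argwhere(out.stack[0] > 0.5).mean(axis=0))
        com_m = np.array(np.argwhere(out.mask > 0).mean(axis=0))
        np.testing.assert_allclose(com_t, com_s, atol=1.0)
        np.testing.assert_allclose(com_t, com_m, atol=1.5)

    def test_mask_stays_binary_under_rotation(self):
        ex = _example(64, 64)
        out = augment(ex, np.random.default_rng(2), mode="nuclei")
        assert set(np.unique(out.mask)) <= {0, 1}


@pytest.fixture(scope="module")
def tiny_run(splits):
    train_set, val_set, _ = splits
    cfg = TrainConfig.tiny("lipids", seed=0, iterations=120,
                           warmup_generator_iters=60, val_interval=30)
    return cfg, train_channel(cfg, train_set, val_set)


class TestTrainChannel:
    def test_warmup_has_no_discriminator_updates(self, tiny_run):
        cfg, result = tiny_run
        d_steps = result.history.query("component == 'd_loss'")["step"]
        assert d_steps.min() >= cfg.warmup_generator_iters
        assert len(d_steps) == cfg.iterations - cfg.warmup_generator_iters

    def test_history_contains_all_components(self, tiny_run):
        _, result = tiny_run
        comps = set(result.history["component"])
        assert {"l1", "grad", "total", "adv", "d_loss", "val_loss"} <= comps

    def test_checkpoint_reload_reproduces_validation_loss(self, tiny_run, splits, tmp_path):
        cfg, result = tiny_run
        _, val_set, _ = splits
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, result.model, cfg, result.best_step,
                        result.best_val_loss, state=result.best_state)
        model, meta = load_checkpoint(path)
        val_examples = [TrainExample.from_scene(ex, cfg.channel) for ex in val_set]
        reloaded = validation_loss(model, cfg, val_examples)
        assert reloaded == pytest.approx(result.best_val_loss, rel=1e-5)
        assert meta["step"] == result.best_step

    def test_empty_training_set_rejected(self, splits):
        _, val_set, _ = splits
        with pytest.raises(ValueError):
            train_channel(TrainConfig.tiny("cytoplasm", iterations=10), [], val_set)


class TestConfigValidation:
    def test_paper_defaults_per_channel(self):
        nuc = TrainConfig.for_channel("nuclei")
        lip = TrainConfig.for_channel("lipids")
        cyt = TrainConfig.for_channel("cytoplasm")
        assert (nuc.iterations, nuc.batch_size, nuc.lr) == (51_400, 12, 1e-3)
        assert (lip.iterations, lip.batch_size, lip.lr) == (30_000, 4, 1e-4)
        assert (cyt.iterations, cyt.batch_size, cyt.lr) == (75_000, 4, 1e-4)
        assert nuc.model.n_blocks_per_path == 5
        assert lip.model.n_blocks_per_path == 4
        assert lip.lr_discriminator == 1e-5
        assert lip.warmup_generator_iters == 1500

    def test_warmup_must_precede_end(self):
        with pytest.raises(ValueError):
            TrainConfig.tiny("lipids", iterations=50)  # warmup is 100

    def test_crop_divisibility_enforced(self):
        with pytest.raises(ValueError):
            TrainConfig.tiny("nuclei", crop=66)
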