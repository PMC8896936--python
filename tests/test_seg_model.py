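"""Segmenter architecture contracts, patch sampling and training behaviour."""

import numpy as np
import pytest
from scipy import stats

from ribseg.geometry import BinaryMask, ImageVolume, VolumeGeometry
from ribseg.losses import LossConfig
from ribseg.seg_model import (
    PRESETS,
    CascadeConfig,
    CascadeSegmenter,
    TrainConfig,
    UNetConfig,
    build_segmenter,
    load_segmenter,
    sample_patch,
    save_segmenter,
    train_cascade,
    train_segmenter,
)

TINY16 = UNetConfig(dims=3, patch_size=(16, 16, 16), pools_per_axis=(2, 2, 2),
                    base_channels=4)


class TestBuild:
    def test_output_shape_and_range_3d(self, rng):
        net = build_segmenter(TINY16, seed=0)
        p = net.predict(rng.normal(size=(16, 16, 16)).astype(np.float32))
        assert p.shape == (16, 16, 16)
        assert p.min() >= 0 and p.max() <= 1

    def test_2d_variant_accepts_slices(self, rng):
        cfg = UNetConfig(dims=2, patch_size=(64, 64), pools_per_axis=(3, 3),
                         base_channels=4)
        net = build_segmenter(cfg, seed=0)
        p = net.predict(rng.normal(size=(64, 64)).astype(np.float32))
        assert p.shape == (64, 64)

    def test_anisotropic_pooling(self, rng):
        cfg = UNetConfig(dims=3, patch_size=(8, 16, 16),
                         pools_per_axis=(1, 2, 2), base_channels=4)
        net = build_segmenter(cfg, seed=0)
        assert net.predict(rng.normal(size=(8, 16, 16))).shape == (8, 16, 16)

    def test_seeded_initialization_reproducible(self, rng):
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        a = build_segmenter(TINY16, seed=5).predict(x)
        b = build_segmenter(TINY16, seed=5).predict(x)
        np.testing.assert_array_equal(a, b)

    def test_indivisible_patch_rejected(self):
        with pytest.raises(ValueError):
            UNetConfig(dims=3, patch_size=(20, 20, 20), pools_per_axis=(3, 3, 3))

    def test_published_presets_exist(self):
        assert PRESETS["published_3d_fullres"].patch_size == (96, 160, 160)
        assert PRESETS["published_3d_fullres"].pools_per_axis == (4, 5, 5)
        assert PRESETS["published_2d"].dims == 2

    def test_checkpoint_round_trip(self, tmp_path, rng):
        net = build_segmenter(TINY16, seed=2)
        save_segmenter(net, tmp_path / "w.npz", tmp_path / "c.json")
        back = load_segmenter(tmp_path / "w.npz", tmp_path / "c.json")
        x = rng.normal(size=(16, 16, 16)).astype(np.float32)
        np.testing.assert_allclose(back.predict(x), net.predict(x), atol=1e-6)


def _volume_pair(rng, shape=(24, 24, 24), n_blobs=2, bright=3.0, noise=0.0):
    img = rng.normal(0, noise, size=shape).astype(np.float32) if noise else \
        np.zeros(shape, dtype=np.float32)
    mask = np.zeros(shape, dtype=np.uint8)
    for _ in range(n_blobs):
        c = rng.integers(4, np.asarray(shape) - 4)
        sl = tuple(slice(int(v) - 2, int(v) + 2) for v in c)
        img[sl] += bright
        mask[sl] = 1
    geometry = VolumeGeometry(shape, (1, 1, 1))
    return (ImageVolume(values=img, geometry=geometry),
            BinaryMask(values=mask, geometry=geometry))


class TestSamplePatch:
    def test_forced_foreground_centres_cover_foreground(self, rng):
        img, mask = _volume_pair(rng)
        for _ in range(20):
            _, tp = sample_patch(img, mask, (8, 8, 8), 1.0, rng)
            assert tp.sum() >= 1

    def test_uniform_origins_chi_square(self, rng):
        img, mask = _volume_pair(rng, shape=(12, 12, 12))
        # with fg_fraction 0 origins are uniform over 0..4 per axis
        counts = np.zeros(5)
        for _ in range(1000):
            xp, _ = sample_patch(img.values, mask.values, (8, 8, 8), 0.0, rng)
        # track origin via a coordinate-encoded volume
        coord = np.arange(12, dtype=np.float32)[:, None, None] * np.ones((12, 12))
        for _ in range(1000):
            patch, _ = sample_patch(coord, mask.values, (8, 8, 8), 0.0, rng)
            counts[int(patch[0, 0, 0])] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_small_volume_padded(self, rng):
        img, mask = _volume_pair(rng, shape=(24, 24, 24))
        xp, tp = sample_patch(img, mask, (32, 32, 32), 0.0, rng)
        assert xp.shape == (32, 32, 32)
        assert tp.shape == (32, 32, 32)
        assert not tp[24:].any()  # padded mask region is background

    def test_2d_patch_from_3d_volume(self, rng):
        img, mask = _volume_pair(rng)
        xp, tp = sample_patch(img, mask, (16, 16), 1.0, rng)
        assert xp.shape == (16, 16) and tp.shape == (16, 16)
        assert tp.any()


class TestTraining:
    def _dataset(self, rng, n=3):
        return [_volume_pair(rng, noise=0.0) for _ in range(n)]

    def test_zero_epochs_returns_initialized_operator(self, rng):
        net, history = train_segmenter(
            self._dataset(rng), TINY16, TrainConfig(epochs=0, seed=0))
        assert history == []
        assert net.predict(np.zeros((16, 16, 16), np.float32)).shape == (16, 16, 16)

    def test_history_length_equals_epochs(self, rng):
        _, history = train_segmenter(
            self._dataset(rng), TINY16,
            TrainConfig(epochs=3, steps_per_epoch=2, seed=0))
        assert len(history) == 3

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_segmenter([], TINY16, TrainConfig(epochs=1, seed=0))

    def test_training_is_seed_reproducible(self, rng):
        data = self._dataset(rng)
        tc = TrainConfig(epochs=2, steps_per_epoch=2, seed=9)
        _, h1 = train_segmenter(data, TINY16, tc)
        _, h2 = train_segmenter(data, TINY16, tc)
        assert [v.total for v in h1] == [v.total for v in h2]

    def test_learns_separable_blob_task(self, rng):
        """Bright blobs vs clean background: patch Dice >= 0.6 within 30
        epochs for a tiny 3-D model."""
        data = [_volume_pair(rng, noise=0.1) for _ in range(4)]
        tc = TrainConfig(epochs=30, steps_per_epoch=6, batch_size=2,
                         learning_rate=2e-2, fg_patch_fraction=0.8, seed=1)
        net, history = train_segmenter(data, TINY16, tc)
        assert history[-1].total < history[0].total
        dices = []
        srng = np.random.default_rng(0)
        for img, mask in data:
            xp, tp = sample_patch(img, mask, (16, 16, 16), 1.0, srng)
            pred = (net.predict(xp) >= 0.5)
            inter = (pred & (tp > 0)).sum()
            dices.append(2 * inter / max(pred.sum() + (tp > 0).sum(), 1))
        assert np.mean(dices) >= 0.6


class TestCascade:
    def test_cascade_smoke_and_contracts(self, rng):
        shape = (16, 16, 16)
        data = [_volume_pair(rng, shape=shape) for _ in range(2)]
        cc = CascadeConfig(
            coarse_spacing_mm=(2.0, 2.0, 2.0),
            coarse=UNetConfig(patch_size=(8, 8, 8), pools_per_axis=(1, 1, 1),
                              base_channels=2),
            fine=UNetConfig(patch_size=(16, 16, 16), pools_per_axis=(1, 1, 1),
                            base_channels=2),
        )
        tc = TrainConfig(epochs=1, steps_per_epoch=2, seed=0)
        coarse, fine, history = train_cascade(data, cc, tc, LossConfig(),
                                              return_history=True)
        assert fine.in_channels == 2
        assert coarse.in_channels == 1
        assert len(history) == 1 and np.isfinite(history[0].total)
        cascade = CascadeSegmenter(coarse, fine, cc.coarse_spacing_mm)
        prob = cascade.predict_full(data[0][0])
        assert prob.values.shape == shape
        assert np.isfinite(prob.values).all()
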