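"""Geometry and intensity behaviour of the preprocessing pipeline."""

import numpy as np
import pytest

from retseg.preprocess import (
    PreprocessConfig,
    crop_blank_borders,
    equalize_histogram,
    preprocess,
    resize_to_target,
)
from retseg.synthetic import SyntheticConfig, generate_sample


def disc_image(h=40, w=60, r=10, cy=20, cx=30, value=0.8):
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((3, h, w))
    img[:, (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = value
    return img


class TestCrop:
    def test_crop_box_is_tight_disc_bounding_box(self):
        img = disc_image()
        cropped, box = crop_blank_borders(img, threshold=0.02)
        assert box == (10, 31, 20, 41)
        assert cropped.shape == (3, 21, 21)
        # first/last rows and columns must contain an above-threshold pixel
        assert cropped.max(axis=0)[0].max() > 0.02
        assert cropped.max(axis=0)[-1].max() > 0.02

    def test_no_blank_border_is_identity(self, rng):
        img = rng.random((3, 12, 15)) * 0.8 + 0.2
        cropped, box = crop_blank_borders(img, threshold=0.02)
        assert box == (0, 12, 0, 15)
        np.testing.assert_array_equal(cropped, img)

    def test_fully_blank_image_is_error(self):
        with pytest.raises(ValueError, match="blank"):
            crop_blank_borders(np.zeros((3, 10, 10)), threshold=0.02)


class TestEqualize:
    def test_constant_channel_stays_constant(self):
        img = np.full((3, 8, 8), 0.4)
        out = equalize_histogram(img)
        for c in range(3):
            assert np.allclose(out[c], out[c].flat[0])

    def test_two_level_image_maps_to_cdf_values(self):
        # equal proportions of 0.2 and 0.8: CDF = 0.5 at the low level, 1.0
        # at the high level, so equalisation spreads them to 0.5 and 1.0
        img = np.zeros((1, 4, 4))
        img[0, :2] = 0.2
        img[0, 2:] = 0.8
        out = equalize_histogram(img)
        lows = out[0][:2]
        highs = out[0][2:]
        assert np.allclose(lows, 0.5, atol=0.01)
        assert np.allclose(highs, 1.0, atol=0.01)

    def test_flattens_histogram_of_natural_image(self):
        img, _ = generate_sample(
            SyntheticConfig(image_size=64), np.random.default_rng(0)
        )
        fov = img.max(axis=0) > 0.02
        out = equalize_histogram(img, fov)

        def bin_count_variance(channel):
            counts, _ = np.histogram(channel[fov], bins=16, range=(0, 1))
            return counts.var()

        assert bin_count_variance(out[1]) < bin_count_variance(img[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            equalize_histogram(np.full((3, 4, 4), 1.5))


class TestResize:
    def test_integer_downscale_no_padding(self, rng):
        img = rng.random((3, 64, 64))
        cfg = PreprocessConfig(target_size=32)
        out, _ = resize_to_target(img, None, cfg)
        assert out.shape == (3, 32, 32)
        # no pad rows: corners come from the image, not the pad value
        assert out[:, 0, :].mean() > 0.2

    def test_aspect_preserving_pad_split(self, rng):
        img = rng.random((3, 50, 100)) * 0.5 + 0.5
        cfg = PreprocessConfig(target_size=64, pad_value=0.0)
        out, _ = resize_to_target(img, None, cfg)
        assert out.shape == (3, 64, 64)
        # 50x100 -> 32x64, pad 32 rows split 16 top / 16 bottom
        assert np.all(out[:, :16, :] == 0.0)
        assert np.all(out[:, 48:, :] == 0.0)
        assert out[:, 16:48, :].min() > 0.0

    def test_masks_stay_strictly_binary(self, rng):
        img = rng.random((3, 40, 80))
        mask = (rng.random((40, 80)) > 0.5).astype(np.uint8)
        cfg = PreprocessConfig(target_size=64)
        _, masks = resize_to_target(img, {"EX": mask}, cfg)
        assert set(np.unique(masks["EX"])) <= {0, 1}
        assert masks["EX"].shape == (64, 64)


class TestPreprocessPipeline:
    def _sample(self, size=64):
        cfg = SyntheticConfig(image_size=size)
        return generate_sample(cfg, np.random.default_rng(3))

    def test_output_contract(self):
        img, masks = self._sample()
        cfg = PreprocessConfig(target_size=64)
        out, out_masks = preprocess(img, masks, cfg)
        assert out.shape == (3, 64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0
        for m in out_masks.values():
            assert m.shape == (64, 64)
            assert set(np.unique(m)) <= {0, 1}

    def test_near_idempotence(self):
        img, _ = self._sample()
        cfg = PreprocessConfig(target_size=64)
        once, _ = preprocess(img, None, cfg)
        twice, _ = preprocess(once, None, cfg)
        assert np.abs(once - twice).mean() < 0.05

    def test_mask_image_alignment_preserved(self):
        img, masks = self._sample(size=96)
        cfg = PreprocessConfig(target_size=64, equalize=False)
        out, out_masks = preprocess(img, masks, cfg)
        # the bright exudate lesions must still coincide with their mask:
        # mean green intensity inside the EX mask stays well above the
        # image mean if geometry was applied consistently
        m = out_masks["EX"].astype(bool)
        assert m.sum() > 0
        assert out[1][m].mean() > out[1].mean() + 0.15

    def test_lesion_centroid_tracks_geometry(self):
        # a single bright square at a known position must land where the
        # crop/scale arithmetic says it should
        img = np.zeros((3, 40, 80))
        img[:, 10:30, 20:60] = 0.5  # content region -> crop box
        img[:, 18:22, 38:42] = 1.0
        mask = np.zeros((40, 80), dtype=np.uint8)
        mask[18:22, 38:42] = 1
        cfg = PreprocessConfig(target_size=64, equalize=False)
        out, out_masks = preprocess(img, {"EX": mask}, cfg)
        ys, xs = np.nonzero(out_masks["EX"])
        # crop -> 20x40 starting at (10,20); scale 64/40=1.6 -> 32x64;
        # pad 16 rows. centroid (9.5, 19.5) -> (15.2, 31.2) + (16, 0)
        assert abs(ys.mean() - (9.5 * 1.6 + 16)) < 2.5
        assert abs(xs.mean() - 19.5 * 1.6) < 2.5

    def test_unlabeled_sample_passes_through(self):
        img, _ = self._sample()
        out, out_masks = preprocess(img, None, PreprocessConfig(target_size=64))
        assert out_masks is None
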