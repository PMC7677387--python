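"""Cropping, normalization, reflection and subject preparation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psoasvol.core import DixonVolume, LandmarkSet, MuscleMask
from psoasvol.preprocess import (
    DegenerateInputError,
    crop_to_roi,
    embed_crop,
    normalize_crop,
    normalize_intensity,
    prepare_subject,
    reflect_crop,
)
from psoasvol.synthetic import PhantomSpec, generate_phantom


def _volume(shape=(64, 50, 70), seed=0):
    rng = np.random.default_rng(seed)
    return DixonVolume(rng.random(shape).astype(np.float32))


class TestCropToRoi:
    def test_centre_landmark_matches_direct_extraction(self):
        vol = _volume()
        lm = (32, 25, 35)
        crop = crop_to_roi(vol, lm, crop_shape=(16, 16, 32))
        # oracle: direct subvolume per the placement rule (in-plane
        # centred, landmark at 25% of the out-of-plane extent)
        i0, j0, k0 = 32 - 8, 25 - 8, 35 - 8
        expected = vol.data[i0:i0 + 16, j0:j0 + 16, k0:k0 + 32]
        assert np.array_equal(crop.intensities, expected)
        assert crop.source_offset == (i0, j0, k0)

    def test_corner_landmark_pads_with_zeros(self):
        vol = _volume()
        crop = crop_to_roi(vol, (0, 0, 0), crop_shape=(16, 16, 32))
        assert crop.shape == (16, 16, 32)
        assert (crop.intensities == 0).mean() > 0.5

    def test_outside_landmark_raises(self):
        vol = _volume()
        with pytest.raises(ValueError, match="outside"):
            crop_to_roi(vol, (64, 0, 0))

    def test_reembed_recrop_roundtrip(self):
        vol = _volume()
        crop = crop_to_roi(vol, (10, 40, 60), crop_shape=(16, 16, 32))
        parent = embed_crop(crop.intensities, crop.source_offset, vol.shape)
        recrop = crop_to_roi(DixonVolume(parent, vol.voxel_mm), (10, 40, 60),
                             crop_shape=(16, 16, 32))
        assert np.array_equal(recrop.intensities, crop.intensities)

    def test_mask_receives_same_transform(self):
        vol = _volume()
        # a coordinate grid encoded in a mask: transform both, compare
        mask = MuscleMask((np.indices(vol.shape).sum(0) % 2).astype(np.uint8))
        crop = crop_to_roi(vol, (20, 20, 20), crop_shape=(16, 16, 32),
                           mask=mask)
        direct = crop_to_roi(DixonVolume(mask.data.astype(float)),
                             (20, 20, 20), crop_shape=(16, 16, 32))
        assert np.array_equal(crop.mask, direct.intensities.astype(np.uint8))


class TestNormalizeIntensity:
    def test_constant_volume_maps_to_one(self):
        out = normalize_intensity(np.full((10, 10, 10), 7.0))
        assert np.allclose(out, 1.0)

    def test_brute_force_percentile_oracle(self):
        x = np.arange(1.0, 10001.0).reshape(10, 10, 100)
        # oracle: sorted linear-interpolation percentile
        flat = np.sort(x.ravel())
        pos = 0.99 * (flat.size - 1)
        lo, frac = int(pos), pos - int(pos)
        p99 = flat[lo] * (1 - frac) + flat[lo + 1] * frac
        out = normalize_intensity(x)
        assert out.ravel()[9899] == pytest.approx(min(9900.0 / p99, 1.0))
        assert out.ravel()[4949] == pytest.approx(4950.0 / p99)
        assert out.max() == 1.0

    def test_spike_is_clipped_without_rescaling_the_rest(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 2, size=4000)
        spike = x.copy()
        spike[0] = 200.0  # single extreme value, 100x the rest
        p99_no_spike = np.percentile(x[1:], 99)
        p99_with_spike = np.percentile(spike, 99)
        # the 99th percentile barely moves, so sub-percentile values keep
        # their relative scale and the spike itself is clipped to 1
        assert p99_with_spike == pytest.approx(p99_no_spike, rel=0.01)
        out = normalize_intensity(spike)
        assert out[0] == 1.0
        assert np.allclose(out[1:], np.minimum(spike[1:] / p99_with_spike, 1))

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateInputError):
            normalize_intensity(np.zeros((5, 5, 5)))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_idempotent_up_to_clipping(self, seed):
        x = np.random.default_rng(seed).gamma(2.0, 1.0, size=(8, 8, 8))
        once = normalize_intensity(x)
        twice = normalize_intensity(once)
        assert twice.min() >= 0 and twice.max() <= 1
        # ordering below the percentile is preserved
        sub = once < 1.0
        a, b = once[sub], twice[sub]
        assert np.array_equal(np.argsort(a, kind="stable"),
                              np.argsort(b, kind="stable"))


class TestReflectCrop:
    def test_involution(self):
        vol = _volume()
        crop = crop_to_roi(vol, (20, 25, 35), crop_shape=(16, 16, 32),
                           side="left")
        back = reflect_crop(reflect_crop(crop))
        assert np.array_equal(back.intensities, crop.intensities)
        assert back.side == crop.side
        assert back.reflected == crop.reflected

    def test_side_label_swaps(self):
        vol = _volume()
        crop = crop_to_roi(vol, (20, 25, 35), side="left")
        assert reflect_crop(crop).side == "right"

    def test_symmetric_phantom_reflected_left_equals_right(self):
        # noiseless mirror-symmetric phantom; odd in-plane crop size so
        # the centred box mirrors onto itself exactly
        subj = generate_phantom(PhantomSpec.desk(noise_sd=0.0), 52.0, 52.0)
        crops = prepare_subject(subj.volume, subj.landmarks,
                                subj.left_mask, subj.right_mask,
                                crop_shape=(17, 17, 32), normalize=False)
        assert np.array_equal(crops.left.intensities, crops.right.intensities)
        assert np.array_equal(crops.left.mask, crops.right.mask)


class TestPrepareSubject:
    def test_crops_contain_95pct_of_mask(self):
        subj = generate_phantom(PhantomSpec.desk(), 55.0, 48.0)
        crops = prepare_subject(subj.volume, subj.landmarks,
                                subj.left_mask, subj.right_mask,
                                crop_shape=(32, 32, 48))
        for crop, full in ((crops.left, subj.left_mask),
                           (crops.right, subj.right_mask)):
            assert crop.mask.sum() >= 0.95 * full.data.sum()

    def test_default_scale_crop_containment(self):
        subj = generate_phantom(PhantomSpec(), 271.0, 278.0)
        crops = prepare_subject(subj.volume, subj.landmarks,
                                subj.left_mask, subj.right_mask)
        assert crops.left.shape == (96, 96, 192)
        for crop, full in ((crops.left, subj.left_mask),
                           (crops.right, subj.right_mask)):
            assert crop.mask.sum() >= 0.95 * full.data.sum()

    def test_left_is_reflected_right_is_not(self):
        subj = generate_phantom(PhantomSpec.desk(), 50.0, 50.0)
        crops = prepare_subject(subj.volume, subj.landmarks,
                                subj.left_mask, subj.right_mask,
                                crop_shape=(32, 32, 48))
        assert crops.left.reflected
        assert not crops.right.reflected
        assert crops.left.side == "left"
        assert crops.right.side == "right"

    def test_optional_masks(self):
        subj = generate_phantom(PhantomSpec.desk(), 50.0, 50.0)
        crops = prepare_subject(subj.volume, subj.landmarks,
                                crop_shape=(32, 32, 48))
        assert crops.left.mask is None and crops.right.mask is None

    def test_normalized_range_and_determinism(self):
        subj = generate_phantom(PhantomSpec.desk(), 50.0, 50.0)
        a = prepare_subject(subj.volume, subj.landmarks, crop_shape=(32, 32, 48))
        b = prepare_subject(subj.volume, subj.landmarks, crop_shape=(32, 32, 48))
        assert a.right.intensities.min() >= 0
        assert a.right.intensities.max() <= 1
        assert np.array_equal(a.left.intensities, b.left.intensities)
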