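"""Volume I/O, standardisation and paired augmentation."""

import numpy as np
import pytest

from ranet.imaging_io import (AugmentationPlan, DimensionalityError,
                              FormatError, ImageSlice, MaskImage,
                              augment_pair, read_volume,
                              resample_to_spacing, resize_and_standardize,
                              write_mhd, write_nifti)
from ranet.metrics import dsc
from ranet.phantom import PhantomParams, generate_phantom


class TestContainers:
    def test_image_slice_validates(self):
        with pytest.raises(ValueError):
            ImageSlice(np.array([1.0, 2.0]))  # 1-D
        with pytest.raises(ValueError):
            ImageSlice(np.array([[np.inf, 0.0]]))

    def test_mask_image_validates_binary(self):
        with pytest.raises(ValueError):
            MaskImage(np.array([[0, 2]]))
        m = MaskImage(np.array([[0, 1], [1, 0]]))
        assert m.labels.dtype == np.uint8


class TestReadVolume:
    def test_nifti_round_trip_four_slices(self, tmp_path):
        vol = np.random.default_rng(0).random((20, 24, 4)).astype(np.float32)
        path = write_nifti(vol, tmp_path / "v.nii.gz", spacing=(0.7, 0.8, 3.0))
        slices = read_volume(path)
        assert len(slices) == 4
        stacked = np.stack([s.pixels for s in slices], axis=-1)
        assert np.array_equal(stacked.astype(np.float32), vol)
        assert slices[0].spacing == pytest.approx((0.7, 0.8))

    def test_hand_written_mhd_header_spacing(self, tmp_path):
        raw = np.arange(2 * 3 * 4, dtype=np.float32)
        (tmp_path / "h.raw").write_bytes(raw.tobytes())
        (tmp_path / "h.mhd").write_text(
            "ObjectType = Image\nNDims = 3\nDimSize = 4 3 2\n"
            "ElementType = MET_FLOAT\nElementSpacing = 0.5 0.5 3.0\n"
            "ElementDataFile = h.raw\n")
        slices = read_volume(tmp_path / "h.mhd")
        assert len(slices) == 2
        assert slices[0].spacing == (0.5, 0.5)
        assert np.array_equal(slices[0].pixels,
                              raw[:12].reshape(3, 4))

    def test_truncated_raw_payload_raises_format_error(self, tmp_path):
        raw = np.arange(24, dtype=np.float32).tobytes()
        (tmp_path / "t.raw").write_bytes(raw[:10])
        (tmp_path / "t.mhd").write_text(
            "ObjectType = Image\nNDims = 3\nDimSize = 4 3 2\n"
            "ElementType = MET_FLOAT\nElementSpacing = 1 1 1\n"
            "ElementDataFile = t.raw\n")
        with pytest.raises(FormatError):
            read_volume(tmp_path / "t.mhd")

    def test_wrong_dimensionality_rejected(self, tmp_path):
        path = tmp_path / "v4.nii.gz"
        import nibabel as nib
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 2, 3), dtype=np.float32),
                                 np.eye(4)), str(path))
        with pytest.raises(DimensionalityError):
            read_volume(path)

    def test_unknown_suffix_rejected(self, tmp_path):
        p = tmp_path / "x.dat"
        p.write_text("")
        with pytest.raises(FormatError):
            read_volume(p)

    def test_mhd_write_read_round_trip(self, tmp_path):
        vol = np.random.default_rng(1).random((3, 8, 8)).astype(np.float32)
        path = write_mhd(vol, tmp_path / "w.mhd", spacing=(0.5, 0.5, 3.0))
        slices = read_volume(path)
        assert np.array_equal(np.stack([s.pixels for s in slices]), vol)


class TestResizeStandardize:
    def test_resize_to_256_and_zscore(self):
        pair = generate_phantom(PhantomParams(image_side=320,
                                              gland_axes_range=(50, 100)),
                                seed=3)
        out = resize_and_standardize(pair.image, 256)
        assert out.pixels.shape == (256, 256)
        assert abs(out.pixels.mean()) < 1e-6
        assert abs(out.pixels.std() - 1) < 1e-3

    def test_constant_input_maps_to_zeros(self):
        out = resize_and_standardize(ImageSlice(np.full((64, 64), 5.0)), 32)
        assert np.array_equal(out.pixels, np.zeros((32, 32)))

    def test_identity_resize_is_pure_zscore(self):
        rng = np.random.default_rng(4)
        px = rng.random((64, 64))
        out = resize_and_standardize(ImageSlice(px), 64)
        expected = (px - px.mean()) / px.std()
        assert np.allclose(out.pixels, expected)

    def test_spacing_rescaled(self):
        slc = ImageSlice(np.zeros((64, 64)) + np.eye(64), spacing=(0.5, 0.5))
        out = resize_and_standardize(slc, 32)
        assert out.spacing == pytest.approx((1.0, 1.0))

    def test_resample_to_spacing(self):
        slc = ImageSlice(np.random.default_rng(0).random((32, 32)),
                         spacing=(1.0, 1.0))
        out = resample_to_spacing(slc, (0.5, 0.5))
        assert out.pixels.shape == (64, 64)


@pytest.fixture()
def clean_pair():
    # blur-free so the gland support equals the mask exactly: geometric
    # consistency then isolates the augmentation itself
    params = PhantomParams.small(64, noise_sigma=0.0,
                                 bias_field_amplitude=0.0,
                                 blur_kernel_sigma=0.0)
    pair = generate_phantom(params, seed=11)
    return pair.image, pair.mask, params


class TestAugmentPair:
    def test_identity_plan_returns_inputs_unchanged(self, clean_pair):
        image, mask, _ = clean_pair
        img2, msk2 = augment_pair(image, mask, AugmentationPlan(seed=0))
        assert np.array_equal(img2.pixels, image.pixels)
        assert np.array_equal(msk2.labels, mask.labels)

    def test_horizontal_shift_moves_centroid(self, clean_pair):
        image, mask, _ = clean_pair
        plan = AugmentationPlan(horizontal_shift=True,
                                shift_range=(5.0, 5.0), seed=1)
        _, msk2 = augment_pair(image, mask, plan)
        c0 = np.argwhere(mask.labels).mean(axis=0)
        c1 = np.argwhere(msk2.labels).mean(axis=0)
        assert abs((c1 - c0)[1] - 5.0) < 0.5  # x moves
        assert abs((c1 - c0)[0]) < 0.5  # y does not

    def test_seeded_determinism(self, clean_pair):
        image, mask, _ = clean_pair
        plan = AugmentationPlan(horizontal_shift=True, vertical_shift=True,
                                zoom=True, random_brightness=True, seed=3)
        a = augment_pair(image, mask, plan)
        b = augment_pair(image, mask, plan)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].labels, b[1].labels)

    def test_geometric_consistency_of_image_and_mask(self, clean_pair):
        """The gland recovered from the transformed noise-free image must
        coincide with the transformed mask (DSC > 0.98)."""
        image, mask, params = clean_pair
        mid = (params.gland_intensity + params.background_intensity) / 2
        for seed in range(5):
            plan = AugmentationPlan(horizontal_shift=True, vertical_shift=True,
                                    zoom=True, shift_range=(-8, 8), seed=seed)
            img2, msk2 = augment_pair(image, mask, plan)
            recovered = (img2.pixels > mid).astype(np.uint8)
            assert dsc(recovered, msk2.labels) > 0.98

    def test_mask_stays_binary_under_all_switches(self, clean_pair):
        image, mask, _ = clean_pair
        plan = AugmentationPlan(horizontal_shift=True, vertical_shift=True,
                                diagonal_shift=True, zoom=True,
                                hue_saturation=True, random_brightness=True,
                                random_contrast=True, seed=9)
        _, msk2 = augment_pair(image, mask, plan)
        assert set(np.unique(msk2.labels)) <= {0, 1}

    def test_photometric_ops_leave_mask_alone(self, clean_pair):
        image, mask, _ = clean_pair
        plan = AugmentationPlan(random_brightness=True, random_contrast=True,
                                hue_saturation=True, seed=2)
        img2, msk2 = augment_pair(image, mask, plan)
        assert np.array_equal(msk2.labels, mask.labels)
        assert not np.array_equal(img2.pixels, image.pixels)

    def test_hue_noop_mode(self, clean_pair):
        image, mask, _ = clean_pair
        plan = AugmentationPlan(hue_saturation=True, hue_mode="noop", seed=2)
        img2, _ = augment_pair(image, mask, plan)
        assert np.array_equal(img2.pixels, image.pixels)

    def test_oversized_shift_rejected(self, clean_pair):
        image, mask, _ = clean_pair
        plan = AugmentationPlan(horizontal_shift=True,
                                shift_range=(80.0, 80.0), seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            augment_pair(image, mask, plan)

    def test_dimension_mismatch_rejected(self, clean_pair):
        image, _, _ = clean_pair
        small = MaskImage(np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ValueError, match="differ"):
            augment_pair(image, small, AugmentationPlan(seed=0))
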