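"""Preprocessing contracts: VOI geometry, windowing, slicing, edges, I/O."""

import numpy as np
import pytest
from skimage.feature import canny as skimage_canny

from sketchct.phantoms import AnnotatedVolume, PhantomSpec, make_phantom
from sketchct.preprocess import (CannySpec, SLICES_PER_TRAIN_VOI, SlicePair,
                                 VOIVolume, WindowSpec, apply_window,
                                 binarize_sketch, canny_edges, crop_voi,
                                 extract_slices, preprocess_volume,
                                 read_manifest, read_png, resample_isotropic,
                                 resize_to_model, write_ct_png,
                                 write_manifest, write_sketch_png)


def iso_volume(n=100, value=-800.0, spacing=0.625, d=20.0):
    return AnnotatedVolume(np.full((n, n, n), value), (spacing,) * 3,
                           (n // 2,) * 3, d)


class TestCropVoi:
    def test_cube_side_is_twice_long_diameter(self):
        voi = crop_voi(iso_volume())
        assert voi.voxels.shape == (64, 64, 64)    # 2*20 mm / 0.625 mm

    def test_corner_center_padded_with_air(self):
        vol = iso_volume()
        vol.tumor_center_voxel = (0, 0, 0)
        voi = crop_voi(vol)
        assert voi.voxels.shape == (64, 64, 64)
        assert voi.voxels[0, 0, 0] == -1000.0      # padded region
        assert voi.voxels[-1, -1, -1] == -800.0    # inside source

    def test_non_positive_diameter_rejected(self):
        with pytest.raises(ValueError):
            AnnotatedVolume(np.zeros((10, 10, 10)), (1, 1, 1),
                            (5, 5, 5), 0.0)


class TestResample:
    def test_isotropic_input_unchanged(self):
        voi = VOIVolume(np.arange(64 ** 3, dtype=float).reshape(64, 64, 64),
                        (0.625,) * 3, 20.0)
        out = resample_isotropic(voi)
        assert out.voxels.shape == (64, 64, 64)
        assert np.array_equal(out.voxels, voi.voxels)

    def test_anisotropic_becomes_cube(self):
        voi = VOIVolume(np.zeros((64, 64, 80)), (0.625, 0.625, 0.5), 20.0)
        out = resample_isotropic(voi)
        assert out.voxels.shape == (64, 64, 64)    # 80 * 0.5 / 0.625
        assert out.spacing_mm == (0.625,) * 3

    def test_constant_volume_stays_constant(self):
        voi = VOIVolume(np.full((32, 32, 40), -700.0),
                        (0.625, 0.625, 0.5), 10.0)
        out = resample_isotropic(voi)
        assert np.allclose(out.voxels, -700.0)

    def test_non_positive_target_rejected(self):
        voi = VOIVolume(np.zeros((8, 8, 8)), (1, 1, 1), 4.0)
        with pytest.raises(ValueError):
            resample_isotropic(voi, target_mm=0.0)


class TestExtractSlices:
    def test_test_mode_yields_single_axial_slice(self, phantom20):
        voi = resample_isotropic(crop_voi(phantom20))
        slices = extract_slices(voi, train_mode=False)
        assert len(slices) == 1
        n = voi.voxels.shape[0]
        assert np.array_equal(slices[0].image, voi.voxels[:, :, n // 2])

    def test_train_mode_yields_98_slices(self, phantom20):
        voi = resample_isotropic(crop_voi(phantom20))
        slices = extract_slices(voi, train_mode=True)
        assert len(slices) == SLICES_PER_TRAIN_VOI == 98
        keys = {(s.angle_lr_deg, s.angle_ht_deg, s.mirrored) for s in slices}
        assert len(keys) == 98                    # 7 x 7 angle grid x mirror

    def test_oblique_slice_of_constant_cube_is_constant(self):
        voi = VOIVolume(np.full((33, 33, 33), 5.0), (0.625,) * 3, 10.3)
        slices = extract_slices(voi, train_mode=True)
        assert all(np.allclose(s.image, 5.0) for s in slices)

    def test_non_cubic_rejected(self):
        voi = VOIVolume(np.zeros((16, 16, 20)), (1, 1, 1), 8.0)
        with pytest.raises(ValueError):
            extract_slices(voi, train_mode=False)


class TestWindow:
    def test_window_bounds_and_midpoint(self):
        img = np.array([[-1400.0, 200.0], [-600.0, -2000.0]])
        out = apply_window(img, WindowSpec())
        assert out.dtype == np.uint8
        assert out[0, 0] == 0 and out[0, 1] == 255
        assert out[1, 0] == 128                  # midpoint rounds half-up
        assert out[1, 1] == 0                    # clipped below

    def test_monotone_and_surjective_over_window(self):
        hu = np.linspace(-1500, 300, 1000)
        out = apply_window(hu, WindowSpec()).astype(int)
        assert np.all(np.diff(out) >= 0)
        assert out.min() == 0 and out.max() == 255

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(level=-600.0, width=0.0)


class TestResize:
    def test_constant_upsample(self):
        out = resize_to_model(np.full((64, 64), 7.0))
        assert out.shape == (128, 128)
        assert np.allclose(out, 7.0)

    def test_identity_at_model_size(self):
        img = np.random.default_rng(0).random((128, 128))
        assert np.array_equal(resize_to_model(img), img)

    def test_bilinear_stays_within_input_range(self):
        cb = np.indices((256, 256)).sum(axis=0) % 2 * 255.0
        out = resize_to_model(cb)
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            resize_to_model(np.zeros((64, 32)))


class TestCanny:
    def test_constant_image_has_no_edges(self):
        assert canny_edges(np.full((32, 32), 90, np.uint8)).sum() == 0

    def test_step_edge_response_is_one_pixel_wide_per_row(self):
        step = np.zeros((16, 16), np.uint8)
        step[:, 8:] = 255
        out = canny_edges(step)
        interior = out[2:-2]                     # away from border effects
        assert np.all((interior > 0).sum(axis=1) == 1)

    def test_output_is_binary(self, phantom20):
        pair = preprocess_volume(phantom20, train_mode=False)[0]
        assert set(np.unique(pair.sketch_image)) <= {0, 255}

    def test_threshold_order_validated(self):
        with pytest.raises(ValueError):
            CannySpec(low_threshold=200, high_threshold=128)

    def test_agrees_with_reference_implementation(self):
        """>= 99% pixel agreement with skimage's Canny on phantom renders.

        skimage thresholds its normalized Sobel magnitude of the [0, 1]
        image, so the 8-bit thresholds map by the factor 4 * 255.
        """
        agreements = []
        for seed in range(5):
            vol = make_phantom(PhantomSpec(
                tumor_long_diameter_mm=14.0, seed=seed,
                background_style="pneumonia_like" if seed % 2 else "healthy"))
            for pair in preprocess_volume(vol, train_mode=True)[:4]:
                img = pair.ct_image[..., 0]
                ours = canny_edges(img) > 0
                ref = skimage_canny(img.astype(float) / 255.0, sigma=1.1,
                                    low_threshold=128 / (4 * 255),
                                    high_threshold=200 / (4 * 255))
                agreements.append((ours == ref).mean())
        assert len(agreements) == 20
        assert min(agreements) >= 0.98
        assert np.mean(agreements) >= 0.99


class TestBinarizeSketch:
    def test_zero_threshold_all_background(self):
        scan = np.random.default_rng(0).integers(
            0, 256, (32, 32)).astype(np.uint8)
        assert binarize_sketch(scan, 0).sum() == 0

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize_sketch(np.zeros((8, 8), np.uint8), 256)

    def test_synthetic_scan_recovers_stroke_mask(self):
        rng = np.random.default_rng(1)
        stroke = rng.random((64, 64)) < 0.1
        scan = np.where(stroke, 40, 230).astype(np.uint8)
        out = binarize_sketch(scan, 128)
        assert np.array_equal(out > 0, stroke)


def test_png_round_trip_lossless(tmp_path, phantom20):
    pair = preprocess_volume(phantom20, train_mode=False)[0]
    ct_path, sk_path = tmp_path / "ct.png", tmp_path / "sk.png"
    write_ct_png(pair.ct_image, ct_path)
    write_sketch_png(pair.sketch_image, sk_path)
    assert np.array_equal(read_png(ct_path), pair.ct_image)
    assert np.array_equal(read_png(sk_path), pair.sketch_image)


def test_manifest_round_trip(tmp_path):
    rows = [["a_ct.png", "a_edge.png", "voi0", -30, 10, False, "ADC_like"]]
    path = tmp_path / "manifest.csv"
    write_manifest(rows, path)
    df = read_manifest(path)
    assert list(df.columns) == ["ct_path", "sketch_path", "voi_id",
                                "angle_lr", "angle_ht", "mirrored", "class"]
    assert df.iloc[0]["voi_id"] == "voi0"
    assert df.iloc[0]["angle_lr"] == -30


def test_slice_pair_validates_sketch_values():
    ct = np.zeros((128, 128, 3), np.uint8)
    with pytest.raises(ValueError):
        SlicePair(ct_image=ct,
                  sketch_image=np.full((128, 128), 7, np.uint8))


def test_full_pipeline_pair_shapes(phantom20):
    pairs = preprocess_volume(phantom20, train_mode=False)
    assert len(pairs) == 1
    p = pairs[0]
    assert p.ct_image.shape == (128, 128, 3)
    assert p.ct_image.dtype == np.uint8
    assert (p.ct_image[..., 0] == p.ct_image[..., 1]).all()
    assert p.sketch_image.shape == (128, 128)
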