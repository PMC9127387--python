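"""Rotation, contrast stretching, bilateral filtering, watershed levels."""

import numpy as np
import pytest

from fluorotrack.core import BBox
from fluorotrack.preprocess import (RotationSpec, StretchSpec,
                                    bilateral_denoise, contrast_stretch,
                                    rotate_about, rotation_matrix,
                                    watershed_segment)


class TestRotation:
    def test_zero_angle_is_identity(self, rng):
        f = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        np.testing.assert_array_equal(rotate_about(f, RotationSpec((8, 8), 0.0)), f)

    def test_hand_computed_90_degree_mapping(self):
        # bright pixel at (x=6, y=2); clockwise 90 deg about (4, 4):
        # translate -O -> (2, -2); rotate [[c, s], [-s, c]] -> (-2, -2);
        # translate +O -> (2, 2)
        f = np.zeros((9, 9), np.uint8)
        f[2, 6] = 255
        out = rotate_about(f, RotationSpec((4, 4), 90.0))
        iy, ix = np.unravel_index(np.argmax(out), out.shape)
        assert (ix, iy) == (2, 2)
        assert out[2, 2] == 255

    def test_matrix_composition_equals_closed_form(self, rng):
        # C @ B @ A must equal the direct rotation about O for any angle
        for _ in range(100):
            a, b = rng.uniform(0, 30, 2)
            th = rng.uniform(-179.0, 180.0)
            M = rotation_matrix(RotationSpec((a, b), th))
            c, s = np.cos(np.deg2rad(th)), np.sin(np.deg2rad(th))
            direct = np.array([
                [c, s, a - c * a - s * b],
                [-s, c, b + s * a - c * b],
                [0, 0, 1.0]])
            np.testing.assert_allclose(M, direct, atol=1e-12)

    def test_forward_backward_roundtrip_tolerance(self, rng):
        # smooth anatomy-like content: bilinear interpolation error stays
        # below 2 intensity levels away from the zero-filled borders
        from scipy.ndimage import gaussian_filter
        f = gaussian_filter(rng.uniform(60, 200, (40, 40)), 2.5)
        f = f.astype(np.uint8)
        spec = RotationSpec((20, 20), 17.0)
        back = rotate_about(rotate_about(f, spec),
                            RotationSpec((20, 20), -17.0))
        core = (slice(10, 30), slice(10, 30))  # away from zero-filled borders
        err = np.abs(back[core].astype(float) - f[core].astype(float))
        assert err.mean() < 2.0

    def test_center_outside_frame_rejected(self):
        f = np.zeros((10, 10), np.uint8)
        with pytest.raises(ValueError):
            rotate_about(f, RotationSpec((20, 5), 10.0))

    def test_angle_range_validated(self):
        with pytest.raises(ValueError):
            RotationSpec((5, 5), 181.0)


class TestContrastStretch:
    def test_endpoint_mapping(self):
        f = np.array([[50, 150]], dtype=np.uint8)
        out = contrast_stretch(f, StretchSpec(o_min=10, o_max=200))
        assert out[0, 0] == 10 and out[0, 1] == 200

    def test_midpoint_integer_truncation(self):
        # N_min=50, N_max=150, O=[0,255]: P=100 -> 127.5 -> 127
        f = np.array([[50, 100, 150]], dtype=np.uint8)
        out = contrast_stretch(f, StretchSpec(0, 255))
        assert out[0, 1] == 127

    def test_monotone_in_input(self, rng):
        f = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        out = contrast_stretch(f, StretchSpec(0, 255))
        a = f.ravel().argsort(kind="stable")
        assert np.all(np.diff(out.ravel()[a].astype(int)) >= 0)

    def test_output_limit_validation(self):
        with pytest.raises(ValueError):
            StretchSpec(0, 300)
        with pytest.raises(ValueError):
            StretchSpec(100, 50)

    def test_constant_frame_warns_and_passes_through(self):
        f = np.full((5, 5), 77, np.uint8)
        with pytest.warns(UserWarning):
            out = contrast_stretch(f, StretchSpec())
        np.testing.assert_array_equal(out, f)

    def test_local_scope_stretches_flat_gradient(self):
        f = np.tile(np.arange(100, 120, dtype=np.uint8), (21, 1))
        out = contrast_stretch(f, StretchSpec(0, 255, scope="local", window=5))
        assert out.astype(int).max() - out.astype(int).min() \
            > f.astype(int).max() - f.astype(int).min()


def _bilateral_oracle(sub, sigma_s, sigma_r):
    r = int(np.ceil(2.5 * sigma_s))
    pad = np.pad(sub.astype(float), r, mode="edge")
    out = np.zeros_like(sub, dtype=float)
    for y in range(sub.shape[0]):
        for x in range(sub.shape[1]):
            acc = wsum = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    v = pad[y + r + dy, x + r + dx]
                    w = np.exp(-(dx * dx + dy * dy) / (2 * sigma_s ** 2)) \
                        * np.exp(-((v - sub[y, x]) ** 2) / (2 * sigma_r ** 2))
                    acc += w * v
                    wsum += w
            out[y, x] = acc / wsum
    return out


class TestBilateral:
    def test_constant_roi_is_fixed_point(self):
        f = np.full((12, 12), 90, np.uint8)
        out = bilateral_denoise(f, BBox(2, 2, 8, 8), 1.5, 20.0)
        np.testing.assert_array_equal(out, f)

    def test_pixels_outside_roi_untouched(self, rng):
        f = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        roi = BBox(4, 4, 6, 6)
        out = bilateral_denoise(f, roi, 1.5, 20.0)
        mask = np.ones_like(f, bool)
        mask[roi.slices()] = False
        np.testing.assert_array_equal(out[mask], f[mask])

    def test_matches_double_loop_oracle(self, rng):
        f = np.full((14, 14), 100, np.uint8)
        f[7, 7] = 160  # salt pixel within range-kernel reach
        f[2:12, 2:12] += rng.integers(0, 5, (10, 10)).astype(np.uint8)
        roi = BBox(3, 3, 9, 9)
        out = bilateral_denoise(f, roi, 1.5, 30.0)
        oracle = _bilateral_oracle(f[roi.slices()], 1.5, 30.0)
        np.testing.assert_array_equal(
            out[roi.slices()], np.clip(np.round(oracle), 0, 255).astype(np.uint8))
        assert 100 < out[7, 7] < 160  # salt attenuated toward neighborhood

    def test_empty_roi_rejected(self):
        f = np.zeros((8, 8), np.uint8)
        with pytest.raises(ValueError):
            bilateral_denoise(f, BBox(20, 20, 4, 4), 1.5, 20.0)


def _two_disc_frame():
    f = np.full((48, 48), 210, np.uint8)
    Y, X = np.mgrid[0:48, 0:48]
    f[(X - 14) ** 2 + (Y - 14) ** 2 <= 36] = 40
    f[(X - 34) ** 2 + (Y - 34) ** 2 <= 36] = 40
    return f


class TestWatershed:
    @pytest.mark.parametrize("c", [1, 2, 3, 4])
    def test_two_discs_give_two_dark_regions(self, c):
        f = _two_disc_frame()
        seg = watershed_segment(f, BBox(0, 0, 48, 48), c)
        dark = [lab for lab, st in seg.regions.items() if st.mean_gray < 128]
        assert len(dark) == 2
        # dark regions together cover both disc interiors
        cover = np.zeros(f.shape, bool)
        for lab in dark:
            cover |= seg.region_mask(lab, f.shape)
        # watershed lines exclude a 1-px rim, so interior coverage ~0.84
        truth = f == 40
        assert (cover & truth).sum() / truth.sum() > 0.8
        assert not (cover & ~truth).any()  # and nothing outside the discs

    def test_uniform_image_single_region(self):
        f = np.full((20, 20), 120, np.uint8)
        seg = watershed_segment(f, BBox(0, 0, 20, 20), 2)
        assert seg.n_regions == 1

    def test_region_count_monotone_in_level(self, rng):
        f = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        n2 = watershed_segment(f, BBox(0, 0, 40, 40), 2).n_regions
        n4 = watershed_segment(f, BBox(0, 0, 40, 40), 4).n_regions
        assert n2 >= n4

    def test_region_areas_sum_to_labeled_pixels(self):
        f = _two_disc_frame()
        seg = watershed_segment(f, BBox(4, 4, 40, 40), 2)
        assert sum(st.area for st in seg.regions.values()) \
            == int((seg.labels > 0).sum())

    def test_parameter_validation(self):
        f = np.zeros((10, 10), np.uint8)
        with pytest.raises(ValueError):
            watershed_segment(f, BBox(0, 0, 2, 2), 2)
        with pytest.raises(ValueError):
            watershed_segment(f, BBox(0, 0, 10, 10), 0)
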