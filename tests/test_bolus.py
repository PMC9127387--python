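"""Discrete-point bolus tracking: sampling, scoring, stepping."""

import numpy as np
import pytest

from fluorotrack.bolus import (BolusState, DiscretePointSet, EvaParams,
                               evaluate_region, expand_box, init_bolus,
                               sample_points, step_bolus, threshold_segment,
                               track_bolus)
from fluorotrack.config import RunConfig
from fluorotrack.core import BBox
from fluorotrack.synthetic import (BlobSpec, SceneSpec, render)


def _flat_frame(value=80, shape=(32, 32)):
    return np.full(shape, value, np.uint8)


class TestSamplePoints:
    def test_count_and_membership(self, rng):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True  # 100 px
        pts = sample_points(mask, _flat_frame(), 0.1, rng)
        assert len(pts.points) == 10
        assert all(mask[y, x] for x, y in pts.points)

    def test_mean_gray_constant_region(self, rng):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        pts = sample_points(mask, _flat_frame(80, (10, 10)), 0.5, rng)
        assert pts.g_avg == 80.0

    def test_mean_gray_arithmetic(self, rng):
        frame = np.zeros((3, 3), np.uint8)
        frame[0, :] = [10, 20, 30]
        mask = np.zeros((3, 3), bool)
        mask[0, :] = True
        pts = sample_points(mask, frame, 1.0, rng)
        assert pts.g_avg == pytest.approx(20.0)

    def test_tiny_region_falls_back_to_centroid(self, rng):
        mask = np.zeros((10, 10), bool)
        mask[4, 4] = True
        pts = sample_points(mask, _flat_frame(80, (10, 10)), 0.1, rng)
        assert len(pts.points) == 1
        assert tuple(pts.points[0]) == (4, 4)

    def test_point_count_tracks_region_area(self, rng):
        # |P_r| = round(gamma_p * |S_p|) for the stated default ratio
        mask = np.zeros((30, 30), bool)
        mask[0:10, 0:20] = True  # 200 px
        pts = sample_points(mask, _flat_frame(80, (30, 30)), 0.1, rng)
        assert len(pts.points) == 20


class TestExpandBox:
    def test_paper_factor_arithmetic(self):
        assert expand_box(BBox(40, 40, 100, 50), 1.2, (500, 500)) \
            == BBox(30, 35, 120, 60)

    def test_identity_factor(self):
        assert expand_box(BBox(3, 4, 10, 10), 1.0, (50, 50)) == BBox(3, 4, 10, 10)

    def test_clipped_at_corner(self):
        out = expand_box(BBox(0, 0, 10, 10), 2.0, (14, 14))
        assert out.x == 0 and out.y == 0 and out.x2 <= 14 and out.y2 <= 14


class TestEvaluateRegion:
    def _points(self, coords, g_avg=50.0):
        return DiscretePointSet(np.asarray(coords), 0.1, g_avg)

    def test_all_points_in_region_share_term(self):
        region = np.zeros((10, 10), bool)
        region[0:5, 0:5] = True
        pts = self._points([(1, 1), (2, 2), (3, 3)])
        p = EvaParams(theta0=0, theta1=1, theta2=0, theta3=0)
        frame = _flat_frame(50, (10, 10))
        assert evaluate_region(region, pts, frame, p) == pytest.approx(1.0)

    def test_gray_distance_zero_at_target_gray(self):
        region = np.zeros((10, 10), bool)
        region[0:5, 0:5] = True
        pts = self._points([(1, 1)], g_avg=80.0)
        p = EvaParams(theta0=0, theta1=0, theta2=0, theta3=1)
        assert evaluate_region(region, pts, _flat_frame(80, (10, 10)), p) \
            == pytest.approx(0.0)

    def test_mixed_terms_arithmetic(self):
        # 5 of 10 points inside a 50-px region: 1*(5/10) + 1*(5/50) = 0.6
        region = np.zeros((10, 10), bool)
        region[0:5, 0:10] = True
        inside = [(x, 0) for x in range(5)]
        outside = [(x, 9) for x in range(5)]
        pts = self._points(inside + outside)
        p = EvaParams(theta0=0, theta1=1, theta2=1, theta3=0)
        assert evaluate_region(region, pts, _flat_frame(50, (10, 10)), p) \
            == pytest.approx(0.6)

    def test_empty_region_rejected(self):
        p = EvaParams()
        out = evaluate_region(np.zeros((5, 5), bool), self._points([(1, 1)]),
                              _flat_frame(50, (5, 5)), p)
        assert np.isnan(out)


class TestThresholdSegment:
    def test_gray_band_keeps_two_of_three(self):
        frame = np.zeros((1, 3), np.uint8)
        frame[0, :] = [40, 90, 200]
        region = np.ones((1, 3), bool)
        p = EvaParams(g0=30, g1=100)
        kept = threshold_segment(frame, region, p)
        assert kept.sum() == 2 and not kept[0, 2]

    def test_all_outside_band_empty(self):
        frame = np.full((4, 4), 200, np.uint8)
        p = EvaParams(g0=30, g1=100)
        assert threshold_segment(frame, np.ones((4, 4), bool), p).sum() == 0


class TestInitAndStep:
    def test_init_recovers_blob_mask(self, clean_scene, rng):
        seq, truth = clean_scene
        tt = truth["bolus"]
        st = init_bolus(seq[0], tt.boxes[0].expand(1.6, seq.shape),
                        RunConfig(), rng)
        inter = np.logical_and(st.mask, tt.masks[0]).sum()
        dice = 2 * inter / (st.mask.sum() + tt.masks[0].sum())
        assert dice >= 0.8
        assert st.velocity == (0.0, 0.0)

    def test_uniform_bright_box_raises(self, rng):
        frame = np.full((40, 40), 220, np.uint8)
        with pytest.raises(ValueError, match="no bolus"):
            init_bolus(frame, BBox(5, 5, 20, 20), RunConfig(), rng)

    def test_point_count_conserved_after_steps(self, clean_scene, rng):
        seq, truth = clean_scene
        cfg = RunConfig()
        st = init_bolus(seq[0], truth["bolus"].boxes[0].expand(1.6, seq.shape),
                        cfg, rng)
        for i in range(1, 6):
            st = step_bolus(st, seq[i], cfg, rng)
            assert len(st.points.points) \
                == max(1, round(cfg.gamma_p * st.mask.sum()))

    def test_static_blob_velocity_and_drift(self, rng):
        nf = 12
        spec = SceneSpec("static", (64, 64), nf, blobs=[BlobSpec(
            "bolus", np.tile([32.0, 32.0], (nf, 1)),
            radius=np.full(nf, 8.0), intensity=np.full(nf, 70.0),
            deform=0.05)], noise_sigma=1.5, noise_poisson=0.01, seed=5)
        seq, truth = render(spec)
        cfg = RunConfig()
        st = init_bolus(seq[0], BBox(18, 18, 28, 28), cfg, rng)
        centroids = []
        for i in range(1, nf):
            st = step_bolus(st, seq[i], cfg, rng)
            ys, xs = np.nonzero(st.mask)
            centroids.append((xs.mean(), ys.mean()))
        assert abs(st.velocity[0]) <= 1 and abs(st.velocity[1]) <= 1
        drift = np.hypot(centroids[-1][0] - 32, centroids[-1][1] - 32)
        assert drift <= 2.0

    def test_constant_motion_velocity_recovered(self, rng):
        nf = 10
        path = np.array([[12.0 + 3.0 * i, 30.0] for i in range(nf)])
        spec = SceneSpec("drift", (64, 64), nf, blobs=[BlobSpec(
            "bolus", path, radius=np.full(nf, 7.0),
            intensity=np.full(nf, 70.0), deform=0.05)],
            noise_sigma=1.5, noise_poisson=0.01, seed=6)
        seq, _ = render(spec)
        cfg = RunConfig()
        st = init_bolus(seq[0], BBox(3, 21, 20, 20), cfg, rng)
        for i in range(1, 4):
            st = step_bolus(st, seq[i], cfg, rng)
        assert st.velocity[0] == pytest.approx(3.0, abs=1.0)
        assert st.velocity[1] == pytest.approx(0.0, abs=1.0)

    def test_vanishing_blob_flags_lost(self, rng):
        nf = 8
        spec = SceneSpec("vanish", (64, 64), nf, blobs=[BlobSpec(
            "bolus", np.tile([32.0, 32.0], (nf, 1)),
            radius=np.full(nf, 8.0), intensity=np.full(nf, 70.0),
            deform=0.05, end=4)], noise_sigma=1.0, noise_poisson=0.01, seed=7)
        seq, _ = render(spec)
        cfg = RunConfig()
        st = init_bolus(seq[0], BBox(18, 18, 28, 28), cfg, rng)
        flags = []
        for i in range(1, nf):
            st = step_bolus(st, seq[i], cfg, rng)
            flags.append(st.lost)
        assert any(flags[3:])  # lost after the blob is swallowed

    def test_track_deterministic_under_seed(self, clean_scene):
        seq, truth = clean_scene
        box = truth["bolus"].boxes[0].expand(1.6, seq.shape)
        t1, m1 = track_bolus(seq, box, seed=9)
        t2, m2 = track_bolus(seq, box, seed=9)
        assert t1.records == t2.records
        for a, b in zip(m1, m2):
            np.testing.assert_array_equal(a, b)
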