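"""Correlation primitives, position/scale filters, MOSSE, occlusion guard."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from fluorotrack.config import RunConfig
from fluorotrack.core import BBox, VideoSequence
from fluorotrack.correlation import (combined_init, combined_step, correlate,
                                     gaussian_kernel_correlation, mosse_init,
                                     mosse_track, pf_detect, pf_init,
                                     pf_update, sf_estimate, sf_init,
                                     track_combined, _gaussian_peak_at_zero,
                                     _mosse_prep, _hann2d, get_subwindow)


def _spatial_correlation_oracle(x, m):
    """Double-loop circular cross-correlation summed over channels."""
    x = np.atleast_3d(x)
    m = np.atleast_3d(m)
    h, w, c = x.shape
    out = np.zeros((h, w))
    for ty in range(h):
        for tx in range(w):
            acc = 0.0
            for y in range(h):
                for xx in range(w):
                    for ch in range(c):
                        acc += x[(y + ty) % h, (xx + tx) % w, ch] * m[y, xx, ch]
            out[ty, tx] = acc
    return out


class TestCorrelate:
    def test_unit_impulse_is_identity(self, rng):
        x = rng.random((8, 8))
        m = np.zeros((8, 8))
        m[0, 0] = 1.0  # zero-shift impulse
        np.testing.assert_allclose(correlate(x, m), x, atol=1e-10)

    def test_autocorrelation_peaks_at_zero_shift(self, rng):
        x = rng.random((8, 8))
        r = correlate(x, x)
        assert np.unravel_index(np.argmax(r), r.shape) == (0, 0)

    @pytest.mark.parametrize("channels", [1, 3])
    def test_matches_double_loop_oracle(self, rng, channels):
        for _ in range(3):
            x = rng.random((8, 8, channels))
            m = rng.random((8, 8, channels))
            np.testing.assert_allclose(correlate(x, m),
                                       _spatial_correlation_oracle(x, m),
                                       atol=1e-8)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate(rng.random((8, 8)), rng.random((6, 6)))


class TestGaussianKernel:
    def test_self_correlation_peaks_at_one(self, rng):
        x = rng.random((8, 8))
        k = gaussian_kernel_correlation(x, x, 0.5)
        assert k[0, 0] == pytest.approx(1.0)
        assert np.unravel_index(np.argmax(k), k.shape) == (0, 0)

    def test_infinite_bandwidth_limit_all_ones(self, rng):
        x = rng.random((6, 6))
        z = rng.random((6, 6))
        k = gaussian_kernel_correlation(x, z, 1e9)
        np.testing.assert_allclose(k, 1.0, atol=1e-9)

    def test_matches_brute_force_shift_oracle(self, rng):
        x = rng.random((4, 4))
        z = rng.random((4, 4))
        sigma = 0.7
        k = gaussian_kernel_correlation(x, z, sigma)
        want = np.zeros((4, 4))
        for ty in range(4):
            for tx in range(4):
                zs = np.roll(np.roll(z, ty, axis=0), tx, axis=1)
                d2 = ((x - zs) ** 2).sum()
                want[ty, tx] = np.exp(-d2 / (sigma ** 2 * x.size))
        np.testing.assert_allclose(k, want, atol=1e-8)

    def test_nonpositive_sigma_rejected(self, rng):
        x = rng.random((4, 4))
        with pytest.raises(ValueError):
            gaussian_kernel_correlation(x, x, 0.0)


def _textured_frame(rng, shape=(96, 96)):
    f = gaussian_filter(rng.uniform(0, 255, shape), 1.5)
    return np.clip(f, 0, 255).astype(np.uint8)


class TestPositionFilter:
    def test_self_detection_zero_displacement(self, rng):
        f = _textured_frame(rng)
        box = BBox(30, 30, 24, 24)
        pf = pf_init(f, box, RunConfig())
        center, peak = pf_detect(pf, f, box.center)
        assert center[0] == pytest.approx(box.center[0], abs=0.51)
        assert center[1] == pytest.approx(box.center[1], abs=0.51)
        assert peak > 0.5

    def test_pure_translation_recovered(self, rng):
        f = _textured_frame(rng)
        g = np.roll(np.roll(f, 3, axis=0), 5, axis=1)  # shift (+5, +3)
        box = BBox(30, 30, 24, 24)
        # raw gray resolves to sub-pixel; HOG quantizes to half a cell
        for feats, tol in (("gray", 0.6), ("gray+hog", 2.0)):
            pf = pf_init(f, box, RunConfig(features=feats))
            center, _ = pf_detect(pf, g, box.center)
            assert center[0] - box.center[0] == pytest.approx(5.0, abs=tol)
            assert center[1] - box.center[1] == pytest.approx(3.0, abs=tol)

    def test_update_endpoints(self, rng):
        f = _textured_frame(rng)
        g = _textured_frame(rng)
        box = BBox(30, 30, 24, 24)
        pf = pf_init(f, box, RunConfig())
        a0 = pf.alpha_f.copy()
        t0 = pf.template.copy()
        pf_update(pf, g, box.center, theta=0.0)
        np.testing.assert_array_equal(pf.alpha_f, a0)
        np.testing.assert_array_equal(pf.template, t0)
        pf_update(pf, g, box.center, theta=1.0)
        fresh = pf_init(g, box, RunConfig())
        np.testing.assert_allclose(pf.alpha_f, fresh.alpha_f, atol=1e-10)

    def test_update_is_convex_combination(self, rng):
        f = _textured_frame(rng)
        g = _textured_frame(rng)
        box = BBox(30, 30, 24, 24)
        pf = pf_init(f, box, RunConfig())
        old = pf.alpha_f.copy()
        pf_update(pf, g, box.center, theta=1.0)
        new = pf.alpha_f.copy()
        pf2 = pf_init(f, box, RunConfig())
        theta = 0.3
        pf_update(pf2, g, box.center, theta=theta)
        for part in (np.real, np.imag):
            lo = np.minimum(part(old), part(new))
            hi = np.maximum(part(old), part(new))
            got = part(pf2.alpha_f)
            assert np.all(got >= lo - 1e-9) and np.all(got <= hi + 1e-9)

    def test_degenerate_box_rejected(self, rng):
        f = _textured_frame(rng)
        with pytest.raises(ValueError):
            pf_init(f, BBox(10, 10, 4, 4), RunConfig())

    def test_response_shift_equivariance(self, rng):
        # shifting the search patch cyclically shifts the response argmax
        x = rng.random((16, 16))
        pf_cfg = RunConfig(features="gray")
        sigma, lam = pf_cfg.sigma_k, pf_cfg.lam
        y = _gaussian_peak_at_zero((16, 16), 2.0)
        k = gaussian_kernel_correlation(x, x, sigma)
        alpha = np.fft.fft2(y) / (np.fft.fft2(k) + lam)
        for dy, dx in [(2, 5), (7, 1)]:
            xs = np.roll(np.roll(x, dy, axis=0), dx, axis=1)
            ks = gaussian_kernel_correlation(xs, x, sigma)
            res = np.real(np.fft.ifft2(alpha * np.fft.fft2(ks)))
            assert np.unravel_index(np.argmax(res), res.shape) == (dy, dx)


class TestScaleFilter:
    def test_factor_ladder_symmetric_single_unit(self):
        f = _textured_frame(np.random.default_rng(0))
        sf = sf_init(f, BBox(30, 30, 24, 24), RunConfig())
        facs = sf.factors
        assert np.sum(np.isclose(facs, 1.0)) == 1
        np.testing.assert_allclose(facs, 1.0 / facs[::-1], rtol=1e-12)

    def test_static_target_unit_factor(self, rng):
        f = _textured_frame(rng)
        box = BBox(30, 30, 24, 24)
        sf = sf_init(f, box, RunConfig())
        assert sf_estimate(sf, f, box.center) == pytest.approx(1.0)

    def test_zoom_by_one_step_detected(self, rng):
        from skimage.transform import rescale
        cfg = RunConfig()
        f = _textured_frame(rng, (120, 120))
        box = BBox(40, 40, 32, 32)
        sf = sf_init(f, box, cfg)
        a = cfg.scale_step
        zoomed = rescale(f.astype(float), a, order=1, preserve_range=True)
        cx, cy = box.center
        zc = (cx * a, cy * a)
        got = sf_estimate(sf, zoomed.astype(np.uint8), zc)
        assert abs(np.log(got) / np.log(a) - 1.0) <= 1.0  # within one step

    def test_single_scale_never_resizes(self, rng, scale_scene):
        seq, truth = scale_scene
        box = truth["organ"].boxes[0]
        traj = track_combined(seq, box,
                              RunConfig(n_scales=1, correction=False),
                              use_scale=True)
        sizes = {(r.box.w, r.box.h) for r in traj}
        assert len(sizes) == 1


class TestCombinedTracker:
    def test_tracks_translating_patch(self, lean_scene):
        seq, truth = lean_scene
        tt = truth["chin"]
        traj = track_combined(seq, tt.boxes[0], RunConfig())
        errs = [np.hypot(r.box.center[0] - tt.centroids[r.frame_index][0],
                         r.box.center[1] - tt.centroids[r.frame_index][1])
                for r in traj]
        assert np.mean(errs) <= 3.0

    def test_occlusion_freezes_template_and_reacquires(self, occlusion_scene):
        seq, truth = occlusion_scene
        tt = truth["organ"]
        cfg = RunConfig()
        tr = combined_init(seq[0], tt.boxes[0], cfg)
        frozen_alpha = None
        occluded_frames = []
        errs = []
        for i in range(1, len(seq)):
            before = tr.position.alpha_f.copy()
            box, flags = combined_step(tr, seq[i])
            if flags["occluded"]:
                occluded_frames.append(i)
                np.testing.assert_array_equal(tr.position.alpha_f, before)
            errs.append(np.hypot(box.center[0] - tt.centroids[i][0],
                                 box.center[1] - tt.centroids[i][1]))
        assert occluded_frames, "occluder never triggered the guard"
        assert np.mean(errs[-10:]) <= 10.0  # reacquired after the pass
        assert tr.lost_count == 0


class TestMosse:
    def test_training_frame_response_matches_gaussian_target(self, rng):
        f = _textured_frame(rng)
        box = BBox(30, 30, 24, 24)
        filt = mosse_init(f, box, RunConfig())
        ww, wh = filt.window_size
        patch = _mosse_prep(get_subwindow(f, box.center, (ww, wh)),
                            filt.cos_window)
        resp = np.real(np.fft.ifft2(filt.num / (filt.den + filt.lam)
                                    * np.fft.fft2(patch)))
        target = np.real(np.fft.ifft2(filt.y_f))
        assert np.corrcoef(resp.ravel(), target.ravel())[0, 1] > 0.95

    def test_tracks_noise_free_translation(self, rng):
        f = _textured_frame(rng, (80, 80))
        frames = [np.roll(np.roll(f, i, axis=0), 2 * i, axis=1)
                  for i in range(8)]
        seq = VideoSequence(frames)
        box = BBox(28, 28, 20, 20)
        traj = mosse_track(seq, box, RunConfig())
        for i, r in enumerate(traj):
            assert r.box.center[0] == pytest.approx(box.center[0] + 2 * i, abs=2.0)
            assert r.box.center[1] == pytest.approx(box.center[1] + i, abs=2.0)
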