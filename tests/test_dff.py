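"""dF/F0 pipeline: baseline, bleach correction, averaging, filtering, rendering."""

import numpy as np
import pytest
from matplotlib import colormaps

from photonbin import (
    DffStack,
    FrameStack,
    SceneSpec,
    acquire,
    adaptive_wiener,
    bleach_correct,
    compute_f0,
    dark_pixel_mask,
    dff,
    make_blank_trial,
    median_mask_render,
    roi_trace,
    trial_average,
)
from photonbin.binning import sliding_window_sum

from test_scenes import small_dendrite


def as_stack(arr, frame_interval=1e-3, bit_depth=32):
    return FrameStack(np.asarray(arr, dtype=np.float64), frame_interval, bit_depth)


class TestComputeF0:
    def test_constant_stack(self):
        stack = FrameStack(np.full((10, 4, 4), 100, dtype=np.uint8), 1e-3, 8)
        assert np.allclose(compute_f0(stack, (0, 10)), 100.0)

    def test_single_frame_window(self):
        rng = np.random.default_rng(0)
        stack = FrameStack(rng.integers(0, 200, (5, 4, 4)).astype(np.uint8), 1e-3, 8)
        assert np.array_equal(compute_f0(stack, (2, 3)), stack.data[2].astype(float))

    def test_poisson_f0_within_confidence_band(self, photon_cam, uniform_scene):
        # SE of a 200-frame mean of Poisson(100) is sqrt(100/200) ~ 0.71; 4 sigma ~ 3
        stack = acquire(uniform_scene(100.0, n_frames=200, side=8), photon_cam, seed=21)
        f0 = compute_f0(stack, (0, 200))
        assert np.abs(f0 - 100.0).max() < 3.0

    def test_empty_window_rejected_and_stim_overlap_warns(self):
        stack = FrameStack(np.ones((10, 2, 2), dtype=np.uint8), 1e-3, 8)
        with pytest.raises(ValueError):
            compute_f0(stack, (5, 5))
        with pytest.warns(UserWarning):
            compute_f0(stack, (0, 10), stim_onset=5e-3)


class TestBleachCorrect:
    def test_self_correction_yields_constant(self):
        sc = small_dendrite()
        blank = make_blank_trial(sc, bleach_tau=0.08)
        stack = as_stack(blank.rate_movie, blank.frame_interval)
        corrected = bleach_correct(stack, stack, baseline_window=(0, 40))
        trace = corrected.data[:, 8, 8]
        assert np.abs(trace - trace[0]).max() < 1e-6 * trace[0]

    def test_flat_blank_passthrough(self):
        sc = small_dendrite()
        blank = make_blank_trial(sc)  # no bleach
        stack = as_stack(sc.rate_movie, sc.frame_interval)
        corrected = bleach_correct(stack, as_stack(blank.rate_movie), baseline_window=(0, 40))
        assert np.allclose(corrected.data, stack.data, atol=1e-9)

    def test_step_recovery_under_efolding_bleach(self, photon_cam):
        """A 1% dF/F0 step on a bleaching baseline is recovered within 10% after
        correction, while the uncorrected estimate is biased far beyond that."""
        t, side, gamma, step = 400, 30, 150.0, 0.01
        times = np.arange(t) * 1e-3
        bleach = np.exp(-times / (t * 1e-3))  # e-folding over the trace
        dff_true = np.where(times >= 0.2, step, 0.0)
        rate = gamma * (1.0 + dff_true)[:, None, None] * bleach[:, None, None] * np.ones((t, side, side))
        scene = SceneSpec(rate, 1e-3, np.full((side, side), gamma), bleach_tau=t * 1e-3)
        stack = acquire(scene, photon_cam, seed=31)
        blank_rate = gamma * bleach[:, None, None] * np.ones((t, side, side))
        blank = acquire(SceneSpec(blank_rate, 1e-3, scene.baseline_map), photon_cam, seed=32)

        corrected = bleach_correct(stack, blank, baseline_window=(0, 150))
        f0 = compute_f0(corrected, (0, 150))
        ds = dff(corrected, f0)
        roi_mean = np.nanmean(ds.data, axis=(1, 2))
        recovered = roi_mean[210:].mean()
        assert recovered == pytest.approx(step, rel=0.10)

        f0_raw = compute_f0(stack, (0, 150))
        uncorrected = np.nanmean(dff(as_stack(stack.data.astype(float)), f0_raw).data, axis=(1, 2))
        assert abs(uncorrected[210:].mean() - step) > 0.1 * step

    def test_shape_and_window_validation(self):
        a = as_stack(np.ones((50, 4, 4)))
        b = as_stack(np.ones((40, 4, 4)))
        with pytest.raises(ValueError):
            bleach_correct(a, b)
        with pytest.raises(ValueError):
            bleach_correct(a, a, sg_window=51)
        with pytest.raises(ValueError):
            bleach_correct(a, a, sg_window=20)


class TestDff:
    def test_fractional_change_examples(self):
        corrected = as_stack(np.array([[[108.0]], [[100.0]], [[0.0]]]))
        ds = dff(corrected, np.array([[100.0]]))
        assert ds.data[0, 0, 0] == pytest.approx(0.08)
        assert ds.data[1, 0, 0] == 0.0
        assert ds.data[2, 0, 0] == -1.0

    def test_nonpositive_f0_rejected_unless_masked(self):
        corrected = as_stack(np.ones((3, 2, 2)))
        f0 = np.array([[1.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            dff(corrected, f0)
        mask = np.array([[True, False], [True, True]])
        ds = dff(corrected, f0, mask)
        assert np.isnan(ds.data[0, 0, 1])


class TestTrialAverage:
    def test_identity_cases(self):
        rng = np.random.default_rng(5)
        stack = FrameStack(rng.integers(0, 200, (6, 5, 5)).astype(np.uint8), 1e-3, 8)
        assert np.allclose(trial_average([stack]).data, stack.data)
        assert np.allclose(trial_average([stack, stack, stack]).data, stack.data)

    def test_nine_trial_noise_reduction(self, photon_cam, uniform_scene):
        # ROI collecting 1.2e5 photoelectrons/frame, 9 trials -> noise <= 0.4%
        scene = uniform_scene(120.0, n_frames=500, side=40)
        trials = [acquire(scene, photon_cam, seed=40 + k) for k in range(9)]
        trace = roi_trace(trial_average(trials), (0, 40, 0, 25), "sum")
        rel_sd = trace.std(ddof=1) / trace.mean()
        assert rel_sd <= 0.004

    def test_commutes_with_roi_trace(self, photon_cam, uniform_scene):
        scene = uniform_scene(50.0, n_frames=30, side=10)
        trials = [acquire(scene, photon_cam, seed=60 + k) for k in range(3)]
        roi = (2, 8, 1, 9)
        via_avg = roi_trace(trial_average(trials), roi, "sum")
        via_traces = np.mean([roi_trace(s, roi, "sum") for s in trials], axis=0)
        assert np.allclose(via_avg, via_traces, rtol=0, atol=1e-9)

    def test_mismatch_rejected(self):
        a = as_stack(np.ones((5, 4, 4)))
        b = as_stack(np.ones((5, 4, 5)))
        with pytest.raises(ValueError):
            trial_average([a, b])
        with pytest.raises(ValueError):
            trial_average([])


class TestAdaptiveWiener:
    def test_constant_frame_unchanged(self):
        frame = np.full((12, 12), 3.7)
        assert np.allclose(adaptive_wiener(frame, 5), frame)

    def test_smooths_white_noise(self):
        rng = np.random.default_rng(8)
        frame = rng.normal(0, 1, (32, 32))
        out = adaptive_wiener(frame, 5, passes=3)
        assert out.var() < 0.5 * frame.var()

    def test_matches_direct_formula(self):
        """Cross-check against an independent per-pixel evaluation of the
        local-mean/local-variance gain formula."""
        rng = np.random.default_rng(9)
        frame = rng.normal(5, 2, (16, 16))
        window = 5
        out = adaptive_wiener(frame, window)

        h, w = frame.shape
        lo, hi = window // 2, window // 2
        mu = np.empty_like(frame)
        var = np.empty_like(frame)
        for i in range(h):
            for j in range(w):
                patch = frame[max(0, i - lo) : min(h, i + hi + 1), max(0, j - lo) : min(w, j + hi + 1)]
                mu[i, j] = patch.mean()
                var[i, j] = patch.var()
        nu = var.mean()
        gain = np.where(var > 0, np.maximum(var - nu, 0.0) / np.maximum(var, nu), 0.0)
        expected = mu + gain * (frame - mu)
        assert np.abs(out - expected).max() < 1e-12

    def test_parameter_validation(self):
        frame = np.ones((8, 8))
        for bad in (2, 1, 9):
            with pytest.raises(ValueError):
                adaptive_wiener(frame, bad)


class TestRendering:
    def make_dffstack(self, values):
        data = np.asarray(values, dtype=float)[:, None, None] * np.ones((len(values), 10, 10))
        return DffStack(data, np.ones((10, 10)), np.ones((10, 10), bool), 1e-3)

    def test_all_zero_shows_background(self):
        bg = np.linspace(0, 1, 100).reshape(10, 10)
        rgb = median_mask_render(self.make_dffstack([0.0]), 3, 0.01, 0.04, background=bg)
        expected = np.repeat((bg / bg.max() * 255).astype(np.uint8)[..., None], 3, axis=-1)
        assert np.array_equal(rgb[0], expected)

    def test_hi_maps_to_top_colour_and_mid_to_midscale(self):
        cmap = colormaps["jet"]
        rgb = median_mask_render(self.make_dffstack([0.04, 0.025, 0.10]), 3, 0.01, 0.04)
        top = (np.array(cmap(1.0)[:3]) * 255).astype(np.uint8)
        mid = (np.array(cmap(0.5)[:3]) * 255).astype(np.uint8)
        assert np.array_equal(rgb[0, 5, 5], top)
        assert np.array_equal(rgb[1, 5, 5], mid)
        assert np.array_equal(rgb[2, 5, 5], top)  # above hi saturates

    def test_monotone_colour_position(self):
        values = [0.012, 0.02, 0.03, 0.039]
        stack = self.make_dffstack(values)
        med = stack.data[:, 5, 5]
        pos = np.clip((med - 0.01) / 0.03, 0, 1)
        assert (np.diff(pos) > 0).all()

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            median_mask_render(self.make_dffstack([0.0]), 3, 0.04, 0.01)


class TestPipelineLinearity:
    def test_noiseless_recovery_to_truth(self):
        """End-to-end on a noiseless bleached dendrite scene: bleach correction +
        F0 + dF/F0 reproduce the generator truth to < 1e-6."""
        sc = small_dendrite(bleach_tau=0.2)
        blank = make_blank_trial(sc, bleach_tau=0.2)
        stack = as_stack(sc.rate_movie, sc.frame_interval)
        corrected = bleach_correct(stack, as_stack(blank.rate_movie), baseline_window=(0, 20))
        f0 = compute_f0(corrected, (0, 20))
        ds = dff(corrected, f0)
        r0, r1, c0, c1 = sc.truth["site_rois"][1]
        trace = np.nanmean(ds.data[:, r0:r1, c0:c1], axis=(1, 2))
        assert np.abs(trace - sc.truth["site_dff"][1]).max() < 1e-6


class TestDarkPixelMask:
    def test_threshold_fraction(self):
        f0 = np.ones((10, 10))
        f0[0, :] = 0.01  # dark row
        mask = dark_pixel_mask(f0, fraction=0.1)
        assert not mask[0].any()
        assert mask[1:].all()
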