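from __future__ import annotations

import math

import numpy as np
import pytest
from skimage.measure import label as sk_label
from skimage.morphology import disk
from skimage.transform import rescale

from ctcflow import (DetectionParams, FrameStack, background_model,
                     detect_stack, difference_image, generate, measure,
                     segment, SyntheticSpec)
from ctcflow.detection import estimate_noise_sigma, measure_frame

from oracles import naive_closing, naive_label


def _stack(frames, **kw):
    return FrameStack(frames=np.asarray(frames, dtype=np.uint16), **kw)


class TestBackgroundModel:
    def test_constant_stack_any_mode(self):
        stack = _stack(np.full((4, 6, 6), 42))
        for mode in ("first_frame", "median"):
            bg = background_model(stack, DetectionParams(background_mode=mode))
            np.testing.assert_array_equal(bg, np.full((6, 6), 42))

    def test_first_frame_mode_returns_frame_zero(self):
        frames = np.zeros((3, 4, 4), dtype=np.uint16)
        frames[0] = 100
        bg = background_model(_stack(frames), DetectionParams())
        np.testing.assert_array_equal(bg, np.full((4, 4), 100))

    def test_median_of_0_0_10_is_0(self):
        frames = np.zeros((3, 4, 4), dtype=np.uint16)
        frames[2] = 10
        bg = background_model(_stack(frames),
                              DetectionParams(background_mode="median"))
        np.testing.assert_array_equal(bg, np.zeros((4, 4)))

    def test_explicit_mode_requires_background(self):
        stack = _stack(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError, match="explicit"):
            background_model(stack, DetectionParams(background_mode="explicit"))
        bg = np.full((4, 4), 7, dtype=np.uint16)
        out = background_model(
            stack, DetectionParams(background_mode="explicit", background=bg))
        np.testing.assert_array_equal(out, bg)


class TestDifferenceImage:
    def test_identical_frames_give_zero(self):
        f = np.full((5, 5), 1000, dtype=np.uint16)
        assert difference_image(f, f).sum() == 0

    def test_single_bright_pixel(self):
        bg = np.full((5, 5), 100, dtype=np.uint16)
        frame = bg.copy()
        frame[2, 3] += 50
        diff = difference_image(frame, bg)
        assert diff[2, 3] == 50
        assert diff.sum() == 50

    def test_darker_object_does_not_underflow(self):
        # uint16 subtraction would wrap around; the widened domain must not
        bg = np.full((5, 5), 100, dtype=np.uint16)
        frame = bg.copy()
        frame[1, 1] -= 50
        diff = difference_image(frame, bg)
        oracle = np.abs(frame.astype(np.int64) - bg.astype(np.int64))
        np.testing.assert_array_equal(diff, oracle)
        assert diff[1, 1] == 50

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            difference_image(np.zeros((4, 4)), np.zeros((5, 4)))


def _disk_diff(radius, value=6000, shape=(64, 64), center=None, soft=False):
    r0, c0 = center or (shape[0] // 2, shape[1] // 2)
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
    if soft:
        # one-pixel anti-aliased edge centred on the true boundary
        return np.rint(value * np.clip(radius + 0.5 - dist, 0, 1)).astype(np.int64)
    diff = np.zeros(shape, dtype=np.int64)
    diff[dist <= radius] = value
    return diff


class TestSegment:
    def test_zero_diff_gives_no_components(self):
        labels = segment(np.zeros((32, 32), dtype=np.int64), DetectionParams(), 10.0)
        assert labels.max() == 0
        assert labels.shape == (96, 96)

    def test_disk_area_scales_by_interpolation_factor(self):
        diff = _disk_diff(radius=10, soft=True)
        labels = segment(diff, DetectionParams(), noise_sigma=85.0)
        assert labels.max() == 1
        area = int((labels == 1).sum())
        assert area == pytest.approx(math.pi * (10 * 3) ** 2, rel=0.10)

    def test_two_disks_merge_only_within_closing_reach(self):
        params = DetectionParams(min_area=0)
        # separation beyond twice the closing radius on the upscaled image
        far = _disk_diff(6, shape=(64, 64), center=(20, 20)) + \
              _disk_diff(6, shape=(64, 64), center=(20, 44))
        assert segment(far, params, 85.0).max() == 2
        # gap below 2 x closing radius after upscaling: closing bridges
        near = np.maximum(_disk_diff(6, shape=(64, 64), center=(20, 20)),
                          _disk_diff(6, shape=(64, 64), center=(20, 34)))
        assert segment(near, params, 85.0).max() == 1

    def test_negative_diff_rejected(self):
        with pytest.raises(ValueError):
            segment(np.full((8, 8), -1), DetectionParams(), 1.0)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_naive_pixel_loop_oracle(self, trial):
        """Closing + labelling equals a brute-force implementation on small
        random rasters (component count and pixel partition)."""
        rng = np.random.default_rng(1000 + trial)
        shape = tuple(rng.integers(12, 41, size=2))
        diff = np.zeros(shape, dtype=np.int64)
        for _ in range(rng.integers(1, 5)):
            r, c = rng.integers(0, shape[0]), rng.integers(0, shape[1])
            rad = int(rng.integers(1, 6))
            rr, cc = np.ogrid[:shape[0], :shape[1]]
            diff[(rr - r) ** 2 + (cc - c) ** 2 <= rad ** 2] = 6000
        frac = 0.0 if trial % 2 == 0 else 0.5
        params = DetectionParams(min_area=0, closing_radius=int(rng.integers(0, 4)),
                                 delineation_fraction=frac)
        got = segment(diff, params, noise_sigma=85.0)

        up = rescale(diff.astype(np.float64), 3, order=1, preserve_range=True,
                     anti_aliasing=False)
        binary = up > 4 * 85.0
        if frac > 0:
            # per-trace half-maximum cut, traced with the naive labeller
            comps = naive_label(binary)
            for lbl in range(1, comps.max() + 1):
                sel = comps == lbl
                cut = max(4 * 85.0, frac * up[sel].max())
                binary[sel & (up <= cut)] = False
        if params.closing_radius > 0:
            binary = naive_closing(binary, disk(params.closing_radius).astype(bool))
        want = naive_label(binary)
        assert got.max() == want.max()
        # identical partition up to label numbering
        for lbl in range(1, want.max() + 1):
            got_ids = np.unique(got[want == lbl])
            assert len(got_ids) == 1 and got_ids[0] != 0


class TestMeasure:
    def _measure_up_mask(self, up_mask, pitch=2.8, frame_shape=None, frame=None):
        """Measure a mask given directly at upscaled (x3) resolution."""
        params = DetectionParams(scale_factor=3, min_area=0)
        labels = sk_label(up_mask, connectivity=2)
        if frame is None:
            shape = frame_shape or (up_mask.shape[0] // 3, up_mask.shape[1] // 3)
            frame = np.full(shape, 1000, dtype=np.uint16)
        return measure(labels, 1, frame, pixel_pitch=pitch, params=params)

    def test_filled_circle_is_compact_and_isotropic(self):
        rr, cc = np.ogrid[:192, :192]
        mask = (rr - 96) ** 2 + (cc - 96) ** 2 <= 36 ** 2
        obj = self._measure_up_mask(mask)
        assert obj.solidity >= 0.95
        assert obj.axial_ratio <= 1.1

    def test_two_to_one_ellipse_axial_ratio(self):
        rr, cc = np.ogrid[:192, :192]
        mask = ((rr - 96) / 30.0) ** 2 + ((cc - 96) / 60.0) ** 2 <= 1
        obj = self._measure_up_mask(mask)
        assert obj.axial_ratio == pytest.approx(2.0, rel=0.10)

    def test_disk_diameter_in_physical_units(self):
        rr, cc = np.ogrid[:192, :192]
        for radius, pitch in [(10, 2.8), (15, 1.0)]:
            mask = (rr - 96) ** 2 + (cc - 96) ** 2 <= (3 * radius) ** 2
            obj = self._measure_up_mask(mask, pitch=pitch)
            assert obj.diameter_um == pytest.approx(2 * radius * pitch, rel=0.05)

    def test_single_pixel_component_uses_degenerate_conventions(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        labels = sk_label(mask, connectivity=2)
        obj = measure(labels, 1, np.full((3, 3), 9, dtype=np.uint16),
                      pixel_pitch=2.8, params=DetectionParams(scale_factor=3))
        assert obj.axial_ratio == 1.0
        assert obj.solidity == 1.0
        assert obj.intensity_range == 0.0

    def test_missing_label_raises(self):
        labels = np.zeros((6, 6), dtype=int)
        with pytest.raises(ValueError):
            measure(labels, 3, np.zeros((2, 2), dtype=np.uint16),
                    pixel_pitch=2.8, params=DetectionParams())

    def test_intensity_range_reads_raw_frame_values(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        frame = np.full((6, 6), 100, dtype=np.uint16)
        frame[2, 2] = 160
        frame[3, 3] = 90
        up = np.kron(mask, np.ones((3, 3), dtype=bool))
        obj = self._measure_up_mask(up, frame=frame)
        assert obj.intensity_range == 70.0


class TestStackLevel:
    def test_offset_invariance_of_measured_features(self):
        """Adding a constant to every pixel changes nothing downstream of
        background subtraction."""
        spec = SyntheticSpec(n_cells=2, seed=21, background_level=18000,
                             noise_sigma=0.0)
        stack, _ = generate(spec)
        shifted = FrameStack(frames=stack.frames + np.uint16(500),
                             fps=stack.fps, pixel_pitch=stack.pixel_pitch)
        a = detect_stack(stack)
        b = detect_stack(shifted)
        assert len(a) == len(b)
        for oa, ob in zip(a, b):
            assert oa.diameter_um == pytest.approx(ob.diameter_um, abs=1e-9)
            assert oa.solidity == pytest.approx(ob.solidity, abs=1e-9)
            assert oa.axial_ratio == pytest.approx(ob.axial_ratio, abs=1e-9)

    def test_resolution_invariance_in_physical_units(self):
        """Doubling pixels while halving the pitch leaves um-scale features
        within discretization tolerance."""
        rr, cc = np.ogrid[:60, :60]
        params = DetectionParams(min_area=0)
        objs = []
        for scale, pitch in [(1, 2.8), (2, 1.4)]:
            radius = 8 * scale
            diff = np.zeros((60 * scale, 60 * scale), dtype=np.int64)
            rr, cc = np.ogrid[:60 * scale, :60 * scale]
            diff[(rr - 30 * scale) ** 2 + (cc - 30 * scale) ** 2 <= radius ** 2] = 6000
            labels = segment(diff, params, 85.0, pixel_pitch=pitch)
            frame = np.full((60 * scale, 60 * scale), 100, dtype=np.uint16)
            objs.append(measure(labels, 1, frame, pixel_pitch=pitch, params=params))
        assert objs[0].diameter_um == pytest.approx(objs[1].diameter_um, rel=0.05)
        assert objs[0].area_um2 == pytest.approx(objs[1].area_um2, rel=0.10)

    def test_single_cell_detected_in_each_appearance_moving_downstream(self):
        spec = SyntheticSpec(n_cells=1, seed=13)
        stack, truth = generate(spec)
        dets = detect_stack(stack)
        assert len(dets) == 6
        cols = [d.centroid_col for d in dets]
        assert all(b > a for a, b in zip(cols, cols[1:]))
        assert [d.frame_index for d in dets] == list(range(truth[0].entry_frame,
                                                           truth[0].exit_frame + 1))

    def test_detection_is_deterministic(self, small_scene):
        stack, _ = small_scene
        assert detect_stack(stack) == detect_stack(stack)

    def test_noise_sigma_estimate_tracks_the_difference_noise(self):
        spec = SyntheticSpec(n_cells=0, n_debris=0, n_small_cells=0,
                             noise_sigma=60.0, frame_shape=(128, 128),
                             duration=12 / 6006, seed=2)
        stack, _ = generate(spec)
        bg = background_model(stack, DetectionParams())
        sigma = estimate_noise_sigma(stack, bg)
        # background frame has its own noise -> sqrt(2) x 60
        assert sigma == pytest.approx(60.0 * math.sqrt(2), rel=0.10)
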