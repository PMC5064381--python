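"""Object detection in high-speed brightfield video.

The chain mirrors a classic in-flow counting script: an empty frame is
subtracted from every subsequent frame, the absolute difference is upscaled
x3 with bilinear interpolation, binarized at a noise-scaled threshold,
filled with morphological closing (dilation then erosion, disk structuring
element) and labelled into 8-connected components.  Each component is then
measured for equivalent-circle diameter, solidity (area / convex-hull area),
axial ratio (major / minor axis of the moment-equivalent ellipse) and the
raw interior pixel intensity range — the four features downstream gates act
on.

Both darker- and brighter-than-background objects are detected because the
difference is taken in absolute value (cells under brightfield show dark
outlines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import closing as sk_closing, disk
from skimage.transform import rescale

from .frame_io import FrameStack

#: median(|X|) = 0.6745 sigma for centred Gaussian X; its reciprocal turns a
#: median absolute difference into a robust sigma estimate.
_MAD_TO_SIGMA = 1.0 / 0.674489750196082


@dataclass
class DetectionParams:
    """Tunable knobs of the detection chain.

    background_mode:
        ``first_frame`` (default; the recording starts before release, so
        frame 0 is empty), ``median`` (per-pixel median over a frame
        subsample) or ``explicit`` (caller supplies ``background``).
    scale_factor:
        Integer upscaling factor applied before binarization (default 3).
    binarize_k:
        The binarization threshold is ``binarize_k`` times the robust noise
        sigma of the difference image.
    closing_radius:
        Disk radius, in upscaled pixels, of the closing structuring element.
    min_area:
        Area guard in upscaled px^2; components smaller than this are
        dropped.  ``None`` computes the area of a 6 um disk from the pixel
        pitch at measure time.
    delineation_fraction:
        After detection at ``binarize_k * sigma``, each trace's boundary is
        re-drawn at this fraction of its peak |difference| (half-maximum by
        default), which keeps measured sizes independent of how far the
        contrast sits above the noise threshold.  0 disables the second
        stage.
    """

    background_mode: str = "first_frame"
    background: Optional[np.ndarray] = None
    scale_factor: int = 3
    binarize_k: float = 4.0
    closing_radius: int = 5
    min_area: Optional[float] = None
    delineation_fraction: float = 0.5
    median_subsample: int = 16

    def __post_init__(self) -> None:
        if self.background_mode not in ("first_frame", "median", "explicit"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if self.scale_factor < 1:
            raise ValueError("scale_factor must be >= 1")
        if self.binarize_k <= 0:
            raise ValueError("binarize_k must be positive")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if not (0.0 <= self.delineation_fraction < 1.0):
            raise ValueError("delineation_fraction must lie in [0, 1)")

    def effective_min_area(self, pixel_pitch: float) -> float:
        """Area guard in upscaled px^2 (default: a 6 um-diameter disk)."""
        if self.min_area is not None:
            return self.min_area
        radius_up = 3.0 * self.scale_factor / pixel_pitch  # 3 um in upscaled px
        return math.pi * radius_up**2


@dataclass
class DetectedObject:
    """One connected component in one frame, in physical units.

    ``centroid_row``/``centroid_col`` and ``bbox`` are reported in
    original-resolution pixel coordinates; ``area_um2`` and ``diameter_um``
    fold in the pixel pitch and upscaling factor.
    """

    sample_id: str
    frame_index: int
    centroid_row: float
    centroid_col: float
    area_um2: float
    diameter_um: float
    solidity: float
    axial_ratio: float
    intensity_range: float
    bbox: tuple[float, float, float, float]
    touches_edge: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.solidity <= 1.0 + 1e-9):
            raise ValueError(f"solidity {self.solidity} outside (0, 1]")
        if self.axial_ratio < 1.0 - 1e-9:
            raise ValueError(f"axial_ratio {self.axial_ratio} < 1")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be positive")
        if self.intensity_range < 0:
            raise ValueError("intensity_range must be >= 0")


def background_model(stack: FrameStack, params: DetectionParams) -> np.ndarray:
    """Return the empty-channel background raster for ``stack``."""
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    mode = params.background_mode
    if mode == "first_frame":
        return stack.frames[0]
    if mode == "median":
        step = max(1, stack.n_frames // params.median_subsample)
        sample = stack.frames[::step]
        return np.median(sample, axis=0).astype(stack.frames.dtype)
    if params.background is None:
        raise ValueError("background_mode='explicit' requires params.background")
    bg = np.asarray(params.background)
    if bg.shape != stack.frame_shape:
        raise ValueError(f"explicit background shape {bg.shape} != frame {stack.frame_shape}")
    return bg


def difference_image(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """|frame - background| in a widened integer domain (no wraparound)."""
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError(f"shape mismatch: {frame.shape} vs {background.shape}")
    return np.abs(frame.astype(np.int64) - background.astype(np.int64))


def estimate_noise_sigma(stack: FrameStack, background: np.ndarray, max_frames: int = 8) -> float:
    """Robust noise sigma of the difference image.

    Pools |frame - background| over an evenly spaced frame subsample and
    converts the median absolute difference to a Gaussian-equivalent sigma.
    Transiting objects occupy a negligible pixel fraction, so the median is
    insensitive to them.
    """
    n = stack.n_frames
    idx = np.unique(np.linspace(min(1, n - 1), n - 1, num=min(max_frames, n), dtype=int))
    diffs = [difference_image(stack.frames[i], background) for i in idx]
    return float(np.median(np.concatenate([d.ravel() for d in diffs]))) * _MAD_TO_SIGMA


def segment(
    diff: np.ndarray,
    params: DetectionParams,
    noise_sigma: float,
    pixel_pitch: float = 2.8,
) -> np.ndarray:
    """Upscale, binarize, close and label one difference image.

    Returns the labelled mask at upscaled resolution (0 = background,
    components are 8-connected, areas below the guard removed).
    """
    diff = np.asarray(diff)
    if diff.min() < 0:
        raise ValueError("difference image must be non-negative")
    # Floor keeps a noiseless (sigma=0) stack from binarizing interpolation dust.
    threshold = max(params.binarize_k * noise_sigma, 0.5)
    s = params.scale_factor
    rows, cols = diff.shape
    binary = np.zeros((rows * s, cols * s), dtype=bool)

    # Bilinear interpolation is a convex combination, so an upscaled pixel
    # can exceed the threshold only where one of its corner pixels does.
    # Process each isolated candidate neighbourhood separately; groups are
    # padded beyond the closing reach, so per-patch results equal the
    # whole-frame computation (rescale commutes with integer-offset crops).
    candidates = diff > threshold
    if candidates.any():
        gap = int(np.ceil(2.0 * params.closing_radius / s)) + 3
        grouped, _ = ndi.label(
            ndi.maximum_filter(candidates, size=2 * gap + 1),
            structure=np.ones((3, 3), dtype=bool),
        )
        for sl in ndi.find_objects(grouped):
            r0, r1 = sl[0].start, sl[0].stop
            c0, c1 = sl[1].start, sl[1].stop
            patch = diff[r0:r1, c0:c1].astype(np.float64)
            if s > 1:
                patch = rescale(patch, s, order=1, preserve_range=True,
                                anti_aliasing=False)
            b = patch > threshold
            if b.any() and params.delineation_fraction > 0:
                # Re-draw each trace's boundary at a fraction of its own
                # peak so sizes do not depend on contrast-to-noise ratio.
                comps = sk_label(b, connectivity=2)
                for lbl, comp_sl in enumerate(ndi.find_objects(comps), start=1):
                    if comp_sl is None:
                        continue
                    sel = comps[comp_sl] == lbl
                    vals = patch[comp_sl]
                    cut = params.delineation_fraction * vals[sel].max()
                    if cut > threshold:
                        b[comp_sl][sel & (vals <= cut)] = False
            if params.closing_radius > 0 and b.any():
                b = sk_closing(b, disk(params.closing_radius))
            binary[r0 * s:r1 * s, c0 * s:c1 * s] |= b

    labels = sk_label(binary, connectivity=2)
    min_area = params.effective_min_area(pixel_pitch)
    if min_area > 0 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_area)
        if small.size:
            labels[np.isin(labels, small)] = 0
        labels = sk_label(labels > 0, connectivity=2)
    return labels


def _measure_prop(
    prop,
    frame: np.ndarray,
    *,
    sample_id: str,
    frame_index: int,
    pixel_pitch: float,
    scale_factor: int,
) -> DetectedObject:
    um_per_up_px = pixel_pitch / scale_factor
    area_um2 = prop.area * um_per_up_px**2
    diameter_um = 2.0 * math.sqrt(area_um2 / math.pi)
    minor, major = prop.axis_minor_length, prop.axis_major_length
    axial_ratio = 1.0 if minor <= 1e-12 else max(major / minor, 1.0)
    solidity = min(float(prop.solidity), 1.0)

    # Down-map the upscaled footprint onto original-resolution pixels and
    # take the raw spread there, avoiding interpolation artifacts.
    coords = prop.coords // scale_factor
    rows = np.clip(coords[:, 0], 0, frame.shape[0] - 1)
    cols = np.clip(coords[:, 1], 0, frame.shape[1] - 1)
    raw = frame[rows, cols]
    intensity_range = float(int(raw.max()) - int(raw.min()))

    r0, c0, r1, c1 = prop.bbox
    up_rows, up_cols = scale_factor * frame.shape[0], scale_factor * frame.shape[1]
    touches_edge = r0 == 0 or c0 == 0 or r1 >= up_rows or c1 >= up_cols
    return DetectedObject(
        sample_id=sample_id,
        frame_index=frame_index,
        centroid_row=prop.centroid[0] / scale_factor,
        centroid_col=prop.centroid[1] / scale_factor,
        area_um2=area_um2,
        diameter_um=diameter_um,
        solidity=solidity,
        axial_ratio=axial_ratio,
        intensity_range=intensity_range,
        bbox=(r0 / scale_factor, c0 / scale_factor, r1 / scale_factor, c1 / scale_factor),
        touches_edge=touches_edge,
    )


def measure(
    labels: np.ndarray,
    label_id: int,
    frame: np.ndarray,
    *,
    pixel_pitch: float,
    params: DetectionParams,
    sample_id: str = "",
    frame_index: int = 0,
) -> DetectedObject:
    """Measure one labelled component against the raw original-resolution frame."""
    for prop in regionprops(labels):
        if prop.label == label_id:
            return _measure_prop(
                prop, frame,
                sample_id=sample_id, frame_index=frame_index,
                pixel_pitch=pixel_pitch, scale_factor=params.scale_factor,
            )
    raise ValueError(f"label {label_id} not present in mask")


def measure_frame(
    labels: np.ndarray,
    frame: np.ndarray,
    *,
    pixel_pitch: float,
    params: DetectionParams,
    sample_id: str = "",
    frame_index: int = 0,
) -> list[DetectedObject]:
    """Measure every labelled component in one frame, ordered by label id."""
    return [
        _measure_prop(
            prop, frame,
            sample_id=sample_id, frame_index=frame_index,
            pixel_pitch=pixel_pitch, scale_factor=params.scale_factor,
        )
        for prop in regionprops(labels)
    ]


def detect_stack(stack: FrameStack, params: DetectionParams | None = None) -> list[DetectedObject]:
    """Run the full chain over a stack: frames 1..N-1 against one background.

    Frame 0 is reserved as (or contributes to) the background model.  The
    noise sigma is estimated once from the background residuals and shared
    by all frames, so detections are deterministic and frame-order stable.
    """
    params = params or DetectionParams()
    if stack.n_frames == 0:
        raise ValueError("empty stack")
    bg = background_model(stack, params)
    sigma = estimate_noise_sigma(stack, bg)
    out: list[DetectedObject] = []
    for i in range(1, stack.n_frames):
        diff = difference_image(stack.frames[i], bg)
        labels = segment(diff, params, sigma, pixel_pitch=stack.pixel_pitch)
        if labels.max() == 0:
            continue
        out.extend(
            measure_frame(
                labels, stack.frames[i],
                pixel_pitch=stack.pixel_pitch, params=params,
                sample_id=stack.sample_id, frame_index=i,
            )
        )
    return out
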