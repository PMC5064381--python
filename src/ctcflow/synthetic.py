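"""Ground-truthed synthetic high-speed video of cell release.

The generator emulates what the in-flow camera sees while trapped cells are
released and swept through the viewing window: each cell is an anti-aliased
dark ellipse translating along the column (flow) axis at constant speed,
sized so that it is fully visible in exactly ``appearances_per_cell``
frames and completely outside the frame before and after.  Debris is
rendered as jagged star polygons whose solidity is below 0.7 by
construction, and sub-gate "small cells" fall under the 12 um diameter
gate.  Sensor noise is i.i.d. Gaussian on a flat background; frame 0 is
always object-free so it can serve as the background model.

Objects are laid out on horizontal "lanes" separated by at least twice the
largest object diameter, with entry frames staggered within each lane, so
that simultaneously visible objects are well separated — the regime in
which deduplication is exact and truth counts are recoverable.  A
``min_separation`` of ``None`` requests that default; explicit 0 disables
lane separation entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .frame_io import DEFAULT_FPS, DEFAULT_PIXEL_PITCH, FrameStack


class GenerationError(ValueError):
    """Requested objects cannot be placed in the frame."""


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic release recording.

    Intensity counts are on a 16-bit scale.  Defaults emulate the nominal
    acquisition: 256 x 376 px frames, 6006 fps, ~6 appearances per cell.
    """

    n_cells: int = 10
    diameter_dist: tuple[float, float] = (16.0, 40.0)      # um, uniform
    axial_ratio_dist: tuple[float, float] = (1.0, 1.6)     # uniform
    cell_contrast: float = 6000.0                          # counts, |signal - background|
    appearances_per_cell: int = 6
    n_debris: int = 0
    n_small_cells: int = 0
    small_diameter_dist: tuple[float, float] = (8.0, 10.5)  # um, below the 12 um gate
    debris_radius_dist: tuple[float, float] = (30.0, 45.0)  # um, star outer radius
    background_level: float = 20000.0
    noise_sigma: float = 60.0
    frame_shape: tuple[int, int] = (256, 376)
    fps: float = DEFAULT_FPS
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    duration: Optional[float] = None    # seconds; None -> shortest stack that fits
    min_separation: Optional[float] = None  # px; None -> 2 x max diameter + 6
    dark_cells: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_debris", "n_small_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("diameter_dist", "axial_ratio_dist", "small_diameter_dist",
                     "debris_radius_dist"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds not ordered")
        if self.appearances_per_cell < 1:
            raise ValueError("appearances_per_cell must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.pixel_pitch <= 0 or self.fps <= 0:
            raise ValueError("pixel_pitch and fps must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one rendered object."""

    cell_id: int
    category: str                 # cell | debris | small_cell
    entry_frame: int
    exit_frame: int
    true_diameter: float          # um (equivalent-area for debris)
    true_axial_ratio: float
    centroids: list[tuple[float, float]] = field(default_factory=list)  # (row, col) px per visible frame

    def __post_init__(self) -> None:
        if self.exit_frame < self.entry_frame:
            raise ValueError("exit_frame < entry_frame")

    @property
    def n_appearances(self) -> int:
        return self.exit_frame - self.entry_frame + 1


class _Object:
    """Internal placement record: geometry in px plus a render callback."""

    def __init__(self, category, half_row, half_col, diameter_um, axial_ratio, render):
        self.category = category
        self.half_row = half_row    # half-extent along rows, px
        self.half_col = half_col    # half-extent along cols, px
        self.diameter_um = diameter_um
        self.axial_ratio = axial_ratio
        self.render = render        # render(frame, row_center, col_center)
        self.row = 0.0
        self.entry_frame = 0
        self.start_col = 0.0
        self.velocity = 0.0
        self.n_visible = 0

    def centroid(self, t: int) -> tuple[float, float]:
        return self.row, self.start_col + self.velocity * (t - self.entry_frame)


def _render_ellipse(frame, r0, c0, a_row, a_col, amplitude):
    """Add an anti-aliased axis-aligned ellipse (~1 px soft edge) in place.

    Only the bounding window of the ellipse is touched.
    """
    rows, cols = frame.shape
    r_lo = max(0, int(math.floor(r0 - a_row - 2)))
    r_hi = min(rows, int(math.ceil(r0 + a_row + 3)))
    c_lo = max(0, int(math.floor(c0 - a_col - 2)))
    c_hi = min(cols, int(math.ceil(c0 + a_col + 3)))
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = np.arange(r_lo, r_hi, dtype=np.float64)[:, None]
    cc = np.arange(c_lo, c_hi, dtype=np.float64)[None, :]
    f = np.sqrt(((rr - r0) / a_row) ** 2 + ((cc - c0) / a_col) ** 2)
    signed = (f - 1.0) * min(a_row, a_col)   # approx signed distance, px
    # Half-pixel ramp centred on the boundary: full coverage 0.25 px inside,
    # zero 0.25 px outside.
    frame[r_lo:r_hi, c_lo:c_hi] += amplitude * np.clip(0.5 - 2.0 * signed, 0.0, 1.0)


def _star_vertices(rng, n_spikes, outer_px, inner_frac):
    angles = np.linspace(0.0, 2.0 * math.pi, 2 * n_spikes, endpoint=False)
    angles = angles + rng.uniform(0, 2.0 * math.pi)
    radii = np.where(np.arange(2 * n_spikes) % 2 == 0, outer_px,
                     outer_px * inner_frac)
    radii = radii * rng.uniform(0.9, 1.1, size=2 * n_spikes)
    return np.stack([radii * np.sin(angles), radii * np.cos(angles)], axis=1)


def _polygon_coverage(rows, cols, r0, c0, vertices):
    """Supersampled (2x2) coverage of a polygon centred at (r0, c0)."""
    from skimage.draw import polygon as draw_polygon

    ss = 2
    big = np.zeros((rows * ss, cols * ss), dtype=np.float64)
    rr, cc = draw_polygon((vertices[:, 0] + r0) * ss + (ss - 1) / 2,
                          (vertices[:, 1] + c0) * ss + (ss - 1) / 2,
                          shape=big.shape)
    big[rr, cc] = 1.0
    return big.reshape(rows, ss, cols, ss).mean(axis=(1, 3))


def _place_objects(spec: SyntheticSpec, objects: list[_Object]) -> int:
    """Assign lanes, entry frames and velocities; return total frame count.

    Lanes are rows separated by >= min_separation; objects in one lane get
    disjoint visible windows, and lane phases are staggered so co-visible
    neighbours differ in column as well as row.
    """
    rows, cols = spec.frame_shape
    n_app = spec.appearances_per_cell
    if not objects:
        n_frames = 2
        if spec.duration is not None:
            n_frames = max(n_frames, int(round(spec.duration * spec.fps)))
        return n_frames

    max_half_row = max(o.half_row for o in objects)
    max_half_col = max(o.half_col for o in objects)
    if spec.min_separation is None:
        min_sep = 4.0 * max(max_half_row, max_half_col) + 6.0  # 2 x max diameter + margin
    else:
        min_sep = spec.min_separation

    row_margin = max_half_row + 2.0
    usable = rows - 2.0 * row_margin
    if usable < 0:
        raise GenerationError("objects too tall for the frame")
    n_lanes = 1 if min_sep <= 0 else max(1, int(usable // min_sep) + 1)
    window = n_app + 1  # visible frames + 1 idle frame between lane slots

    for i, obj in enumerate(objects):
        lane = i % n_lanes
        slot = i // n_lanes
        obj.row = row_margin + lane * (min_sep if min_sep > 0 else usable / max(1, n_lanes))
        # Entries are synchronised across lanes: co-visible neighbours then
        # move in phase, so each one's own next appearance is always nearer
        # than any cross-lane detection and greedy linking stays exact.
        obj.entry_frame = 1 + slot * window
        obj.n_visible = n_app
        hc = obj.half_col
        # Side margin keeps visible objects clear of the frame border (and
        # of closing-related border artifacts in the detector).
        m = 4.0
        if n_app == 1:
            v = 2.0 * cols  # any jump that clears the frame in one step
            obj.start_col = cols / 2.0
        else:
            v = (cols - 2.0 * hc - 2.0 * m) / (n_app - 1)
            if v < 2.0 * hc + m + 1.0:
                raise GenerationError(
                    f"object of half-width {hc:.1f} px cannot appear exactly "
                    f"{n_app} times in a {cols}-px-wide frame"
                )
            obj.start_col = hc + m
        obj.velocity = v

    last_entry = max(o.entry_frame for o in objects)
    n_frames = last_entry + n_app + 1
    if spec.duration is not None:
        wanted = int(round(spec.duration * spec.fps))
        if wanted < n_frames:
            raise GenerationError(
                f"duration {spec.duration}s ({wanted} frames) too short; "
                f"need {n_frames} frames for the requested objects"
            )
        n_frames = wanted
    return n_frames


def generate(spec: SyntheticSpec) -> tuple[FrameStack, list[TruthRecord]]:
    """Render one ground-truthed stack.

    Identical specs (including seed) give bit-identical output.  Frame 0 is
    object-free; every object's truth record spans exactly its visible
    frames.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.frame_shape
    pitch = spec.pixel_pitch
    sign = -1.0 if spec.dark_cells else 1.0

    objects: list[_Object] = []

    def add_ellipse(category: str, diameter_um: float, axial_ratio: float) -> None:
        # Equivalent-area ellipse: semi-axes (d/2)*sqrt(q), (d/2)/sqrt(q).
        a_major = diameter_um / 2.0 * math.sqrt(axial_ratio) / pitch
        a_minor = diameter_um / 2.0 / math.sqrt(axial_ratio) / pitch
        # Major axis along rows or columns at random.
        if rng.random() < 0.5:
            a_row, a_col = a_major, a_minor
        else:
            a_row, a_col = a_minor, a_major

        def render(frame, r0, c0, a_row=a_row, a_col=a_col):
            _render_ellipse(frame, r0, c0, a_row, a_col, sign * spec.cell_contrast)

        objects.append(_Object(category, a_row + 1.0, a_col + 1.0,
                               diameter_um, axial_ratio, render))

    for _ in range(spec.n_cells):
        add_ellipse("cell", rng.uniform(*spec.diameter_dist),
                    rng.uniform(*spec.axial_ratio_dist))
    for _ in range(spec.n_small_cells):
        add_ellipse("small_cell", rng.uniform(*spec.small_diameter_dist), 1.0)
    for _ in range(spec.n_debris):
        outer_px = rng.uniform(*spec.debris_radius_dist) / pitch
        n_spikes = int(rng.integers(5, 7))
        verts = _star_vertices(rng, n_spikes, outer_px, inner_frac=0.25)
        # Shoelace area -> equivalent-area diameter for the truth record.
        r, c = verts[:, 0], verts[:, 1]
        area_px2 = 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))
        eq_diam_um = 2.0 * math.sqrt(area_px2 / math.pi) * pitch

        def render(frame, r0, c0, verts=verts):
            frame += sign * spec.cell_contrast * _polygon_coverage(rows, cols, r0, c0, verts)

        half = float(np.abs(verts).max()) + 1.0
        objects.append(_Object("debris", half, half, eq_diam_um, 1.0, render))

    n_frames = _place_objects(spec, objects)

    truth: list[TruthRecord] = []
    visible: dict[int, list[tuple[_Object, float, float]]] = {}
    for cell_id, obj in enumerate(objects):
        centroids = []
        for t in range(obj.entry_frame, obj.entry_frame + obj.n_visible):
            r0, c0 = obj.centroid(t)
            visible.setdefault(t, []).append((obj, r0, c0))
            centroids.append((r0, c0))
        truth.append(TruthRecord(
            cell_id=cell_id, category=obj.category,
            entry_frame=obj.entry_frame,
            exit_frame=obj.entry_frame + obj.n_visible - 1,
            true_diameter=obj.diameter_um,
            true_axial_ratio=obj.axial_ratio,
            centroids=centroids,
        ))

    # Render frame by frame into the final 16-bit array; noise is drawn in
    # frame order so identical specs give bit-identical stacks.
    pixels = np.empty((n_frames, rows, cols), dtype=np.uint16)
    buf = np.empty((rows, cols), dtype=np.float64)
    for t in range(n_frames):
        buf.fill(spec.background_level)
        for obj, r0, c0 in visible.get(t, ()):
            obj.render(buf, r0, c0)
        if spec.noise_sigma > 0:
            buf += rng.normal(0.0, spec.noise_sigma, size=buf.shape)
        np.rint(buf, out=buf)
        np.clip(buf, 0, 65535, out=buf)
        pixels[t] = buf.astype(np.uint16)

    stack = FrameStack(
        frames=pixels, fps=spec.fps, pixel_pitch=pitch, bit_depth=16,
        sample_id=f"synthetic-seed{spec.seed}",
    )
    return stack, truth


def spike_series(
    true_counts: list[int], base_spec: SyntheticSpec
) -> list[tuple[FrameStack, list[TruthRecord]]]:
    """One stack per requested in-gate cell count, emulating a spike-in series.

    Per-stack seeds derive deterministically from the base seed and the
    series index, so the series is reproducible as a whole.
    """
    if any(c <= 0 for c in true_counts):
        raise ValueError("spike-in counts must be positive")
    out = []
    for i, count in enumerate(true_counts):
        seed = int(np.random.SeedSequence(base_spec.seed, spawn_key=(i,))
                   .generate_state(1)[0] % (2**31))
        out.append(generate(replace(base_spec, n_cells=count, seed=seed)))
    return out
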