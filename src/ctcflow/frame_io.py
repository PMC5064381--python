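"""Frame-stack I/O and tabular output.

High-speed brightfield recordings enter the pipeline either as a multi-page
grayscale TIFF or as a directory of numbered single-frame images.  Acquisition
metadata that the image container cannot carry (frame rate, pixel pitch at the
sample plane, blood volume represented by the recording) travels in a flat
``key = value`` sidecar text file with the same basename as the image data.

Pixel coordinates are 0-based ``(row, column)``; rectangles are half-open.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

logger = logging.getLogger(__name__)

#: Frame rate of the high-speed camera (frames/second) used when no sidecar
#: supplies one.
DEFAULT_FPS = 6006.0

#: Micrometres per pixel at the sample plane.  The optical train (10x
#: objective) does not pin this down exactly, so it is a documented default
#: that callers should override when the calibration is known.
DEFAULT_PIXEL_PITCH = 2.8

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


class FormatError(ValueError):
    """Raised when on-disk data does not parse as a frame stack or sidecar."""


@dataclass
class FrameStack:
    """An ordered stack of grayscale frames plus acquisition metadata.

    Parameters
    ----------
    frames:
        ``(n_frames, rows, cols)`` integer array; all frames share one shape
        and dtype.
    fps:
        Acquisition frame rate, frames per second.
    pixel_pitch:
        Micrometres per pixel at the sample plane.
    bit_depth:
        Sensor bit depth (8 or 16).
    sample_id:
        Free-text sample identifier.
    blood_volume:
        Millilitres of whole blood the recording represents (``None`` if
        unknown; required downstream for per-mL rates).
    roi:
        Optional ``(r0, c0, r1, c1)`` half-open rectangle inside the frame.
    extra:
        Unrecognized sidecar keys, preserved on round-trip.
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    bit_depth: int = 16
    sample_id: str = ""
    blood_volume: Optional[float] = None
    roi: Optional[tuple[int, int, int, int]] = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be (n, rows, cols); got shape {self.frames.shape}"
            )
        if not np.issubdtype(self.frames.dtype, np.integer):
            raise FormatError("frames must hold integer intensity counts")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.roi is not None:
            r0, c0, r1, c1 = self.roi
            rows, cols = self.frame_shape
            if not (0 <= r0 <= r1 <= rows and 0 <= c0 <= c1 <= cols):
                raise ValueError(f"roi {self.roi} outside frame bounds {rows}x{cols}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Recording length in seconds (frame count / fps)."""
        return self.n_frames / self.fps


_SIDECAR_FLOAT_KEYS = {"fps", "pixel_pitch", "blood_volume"}
_SIDECAR_INT_KEYS = {"bit_depth"}


def _parse_sidecar(path: Path) -> dict[str, Any]:
    out: dict[str, Any] = {}
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read sidecar {path}: {exc}") from exc
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _SIDECAR_FLOAT_KEYS:
            try:
                out[key] = float(value)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad number for {key}: {value!r}") from exc
        elif key in _SIDECAR_INT_KEYS:
            try:
                out[key] = int(value)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad integer for {key}: {value!r}") from exc
        elif key == "roi":
            parts = value.split(",")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: roi needs 4 integers")
            out[key] = tuple(int(p) for p in parts)
        elif key == "sample_id":
            out[key] = value
        else:
            out.setdefault("extra", {})[key] = value
    return out


def _format_sidecar(stack: FrameStack) -> str:
    lines = [
        f"fps = {stack.fps:g}",
        f"pixel_pitch = {stack.pixel_pitch:g}",
        f"bit_depth = {stack.bit_depth}",
    ]
    if stack.sample_id:
        lines.append(f"sample_id = {stack.sample_id}")
    if stack.blood_volume is not None:
        lines.append(f"blood_volume = {stack.blood_volume:g}")
    if stack.roi is not None:
        lines.append("roi = " + ",".join(str(v) for v in stack.roi))
    for key, value in stack.extra.items():
        lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def _frame_index(path: Path) -> int:
    """Embedded integer used to order image-sequence frames.

    The *last* run of digits in the stem is taken as the frame number, so
    ``frame_10`` sorts after ``frame_2`` regardless of filesystem listing.
    """
    matches = re.findall(r"\d+", path.stem)
    if not matches:
        raise FormatError(f"frame filename {path.name!r} carries no frame index")
    return int(matches[-1])


def _default_sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / "sidecar.txt"
    return path.with_suffix(".txt")


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> FrameStack:
    """Read a frame stack from a multi-page TIFF or a numbered image directory.

    Metadata comes from ``sidecar`` if given, else from a same-basename
    sidecar next to the data if one exists, else from defaults (fps 6006,
    bit depth inferred from the pixel dtype) with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such frame stack: {path}")

    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES),
            key=_frame_index,
        )
        if not files:
            raise FileNotFoundError(f"directory {path} holds no PNG/TIFF frames")
        frames = []
        for p in files:
            img = np.asarray(iio.imread(p))
            if img.ndim != 2:
                raise FormatError(f"{p} is not single-channel grayscale")
            frames.append(img)
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise FormatError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        pixels = np.stack(frames)
    else:
        pixels = tifffile.imread(path)
        if pixels.ndim == 2:
            pixels = pixels[None]
        if pixels.ndim != 3:
            raise FormatError(f"{path} is not a grayscale multi-page TIFF")
    if pixels.shape[0] == 0:
        raise FormatError(f"{path} holds no frames")

    meta: dict[str, Any] = {}
    sidecar_path = Path(sidecar) if sidecar is not None else _default_sidecar_path(path)
    if sidecar is not None and not sidecar_path.exists():
        raise FileNotFoundError(f"no such sidecar: {sidecar_path}")
    if sidecar_path.exists():
        meta = _parse_sidecar(sidecar_path)
    else:
        logger.warning(
            "no sidecar for %s; assuming fps=%g, pixel_pitch=%g um/px",
            path, DEFAULT_FPS, DEFAULT_PIXEL_PITCH,
        )
    meta.setdefault("bit_depth", 16 if pixels.dtype.itemsize > 1 else 8)
    return FrameStack(frames=pixels, **meta)


def write_stack(stack: FrameStack, path: str | Path) -> None:
    """Write ``stack`` as a multi-page TIFF plus sidecar; inverse of read_stack."""
    if stack.n_frames == 0:
        raise ValueError("refusing to write an empty stack")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    _default_sidecar_path(path).write_text(_format_sidecar(stack))


def records_to_frame(records: Sequence[Any]) -> pd.DataFrame:
    """Convert a homogeneous list of record dataclasses into a DataFrame.

    Column order follows dataclass field order; tuple-valued fields are
    exploded into one column per element (e.g. ``bbox`` -> ``bbox_0`` ...).
    """
    if not records:
        return pd.DataFrame()
    first_type = type(records[0])
    if not all(type(r) is first_type for r in records):
        raise TypeError("record list is not homogeneous")
    if not dataclasses.is_dataclass(first_type):
        raise TypeError(f"records must be dataclasses, got {first_type.__name__}")
    rows = []
    for rec in records:
        row: dict[str, Any] = {}
        for f in dataclasses.fields(rec):
            value = getattr(rec, f.name)
            if isinstance(value, tuple):
                for i, v in enumerate(value):
                    row[f"{f.name}_{i}"] = v
            else:
                row[f.name] = value
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(records: Sequence[Any], path: str | Path, header: list[str] | None = None) -> None:
    """Write records to CSV with a header row and >=6 significant digits.

    An empty list with an explicit ``header`` yields a header-only CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records)
    if df.empty and header is not None:
        df = pd.DataFrame(columns=header)
    df.to_csv(path, index=False, float_format="%.8g")
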