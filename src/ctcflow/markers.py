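"""Rule-based per-cell classifiers.

Two independent rule sets:

* Immunofluorescence: CK / CD45 / DAPI marker flags plus nuclear morphology
  classify each event as CTC, WBC or debris.  CD45 dominates (doubly
  stained CK+/CD45+ events are activated granulocytes, i.e. WBCs); events
  positive only for DAPI are CTCs when the nucleus is large (> 9 um) with a
  high nuclear-to-cytoplasmic area ratio and not lobulated.

* ALK break-apart FISH: red and green probe spots flanking the locus are
  paired by proximity.  Overlapping red-green pairs read as fused (yellow)
  signals from an intact locus; split pairs or lone spots indicate
  rearrangement.  Two fused copies is the normal diploid pattern; three or
  more copies is polysomy of 2p.  A sample is ALK-positive when at least
  15% of interpretable nuclei carry a rearrangement.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


class MarkerClass(str, enum.Enum):
    CTC = "CTC"
    WBC = "WBC"
    DEBRIS = "DEBRIS"


class FishCategory(str, enum.Enum):
    NEGATIVE = "NEGATIVE"
    NEGATIVE_POLYSOMY = "NEGATIVE_POLYSOMY"
    POSITIVE = "POSITIVE"
    POSITIVE_POLYSOMY = "POSITIVE_POLYSOMY"
    UNINTERPRETABLE = "UNINTERPRETABLE"


@dataclass
class MarkerCell:
    """One immunostained event with marker flags and optional nuclear metrics."""

    cell_id: str
    dapi_pos: bool
    ck_pos: bool
    cd45_pos: bool
    nucleus_diameter: Optional[float] = None  # um
    nc_ratio: Optional[float] = None          # nuclear / cell area, in [0, 1]
    lobular_nucleus: bool = False
    debris_morphology: bool = False

    def __post_init__(self) -> None:
        if self.nucleus_diameter is not None and self.nucleus_diameter <= 0:
            raise ValueError("nucleus_diameter must be positive when given")
        if self.nc_ratio is not None and not (0.0 <= self.nc_ratio <= 1.0):
            raise ValueError("nc_ratio must lie in [0, 1] when given")


@dataclass
class FishCell:
    """Red/green probe spot coordinates for one nucleus (image pixels)."""

    cell_id: str
    red_spots: list[tuple[float, float]] = field(default_factory=list)
    green_spots: list[tuple[float, float]] = field(default_factory=list)
    interpretable: bool = True

    def __post_init__(self) -> None:
        for spots in (self.red_spots, self.green_spots):
            for x, y in spots:
                if not (math.isfinite(x) and math.isfinite(y)):
                    raise ValueError("spot coordinates must be finite")


@dataclass
class FishCall:
    category: FishCategory
    n_fused: int
    n_split: int

    @property
    def rearranged(self) -> bool:
        return self.category in (FishCategory.POSITIVE, FishCategory.POSITIVE_POLYSOMY)


class UnclassifiableCellError(ValueError):
    """A DAPI-only cell without any nuclear metric cannot be classified."""


def classify_marker_cell(
    cell: MarkerCell,
    nucleus_cutoff: float = 9.0,
    nc_cutoff: float = 0.5,
) -> MarkerClass:
    """Classify one immunostained event as CTC, WBC or DEBRIS.

    Precedence: debris morphology -> DEBRIS; CD45+ (any CK) -> WBC;
    CK+/CD45- -> CTC; DAPI-only -> CTC iff the nucleus is large
    (> ``nucleus_cutoff`` um), not lobulated and the N:C ratio is at least
    ``nc_cutoff``; remaining DAPI- events -> DEBRIS.  For DAPI-only events
    with only one of the two nuclear metrics available, the available
    metric decides; with neither, the event is unclassifiable.
    """
    if cell.debris_morphology:
        return MarkerClass.DEBRIS
    if cell.cd45_pos:
        return MarkerClass.WBC
    if cell.ck_pos:
        return MarkerClass.CTC
    if cell.dapi_pos:
        if cell.nucleus_diameter is None and cell.nc_ratio is None:
            raise UnclassifiableCellError(
                f"DAPI-only cell {cell.cell_id!r} has neither nucleus_diameter nor nc_ratio"
            )
        if cell.lobular_nucleus:
            return MarkerClass.WBC
        large_nucleus = cell.nucleus_diameter is None or cell.nucleus_diameter > nucleus_cutoff
        large_nc = cell.nc_ratio is None or cell.nc_ratio >= nc_cutoff
        return MarkerClass.CTC if (large_nucleus and large_nc) else MarkerClass.WBC
    return MarkerClass.DEBRIS


def pair_spots(
    red_spots: Sequence[tuple[float, float]],
    green_spots: Sequence[tuple[float, float]],
) -> list[tuple[int, int, float]]:
    """Greedy red-green pairing by ascending pairwise distance.

    Repeatedly takes the globally closest unclaimed (red, green) pair; ties
    break by (red index, green index).  Returns ``(red_idx, green_idx,
    distance)`` triples; ``min(n_red, n_green)`` pairs are formed.
    """
    pairs = sorted(
        (math.hypot(rx - gx, ry - gy), i, j)
        for i, (rx, ry) in enumerate(red_spots)
        for j, (gx, gy) in enumerate(green_spots)
    )
    used_r: set[int] = set()
    used_g: set[int] = set()
    out = []
    for d, i, j in pairs:
        if i in used_r or j in used_g:
            continue
        out.append((i, j, d))
        used_r.add(i)
        used_g.add(j)
    return out


def classify_fish_cell(cell: FishCell, fusion_distance: float = 5.0) -> FishCall:
    """Classify one nucleus from its break-apart probe signal pattern.

    Paired red-green signals within ``fusion_distance`` px count as fused
    (yellow) copies of an intact locus; pairs beyond it, and lone red or
    green spots, each count as one split (rearrangement-consistent) signal.
    One or more split signals -> POSITIVE; fused-only patterns are NEGATIVE
    (two copies) or NEGATIVE_POLYSOMY (three or more); with fewer than two
    total copies, or when the nucleus was flagged uninterpretable upstream,
    the call is UNINTERPRETABLE.
    """
    if fusion_distance < 0:
        raise ValueError("fusion_distance must be >= 0")
    pairs = pair_spots(cell.red_spots, cell.green_spots)
    n_fused = sum(1 for _, _, d in pairs if d <= fusion_distance)
    n_split_pairs = len(pairs) - n_fused
    n_unpaired = (len(cell.red_spots) - len(pairs)) + (len(cell.green_spots) - len(pairs))
    n_split = n_split_pairs + n_unpaired
    copies = n_fused + n_split

    if not cell.interpretable or copies <= 1:
        category = FishCategory.UNINTERPRETABLE
    elif n_split >= 1:
        category = (FishCategory.POSITIVE_POLYSOMY if copies >= 3
                    else FishCategory.POSITIVE)
    elif copies == 2:
        category = FishCategory.NEGATIVE
    else:
        category = FishCategory.NEGATIVE_POLYSOMY
    return FishCall(category=category, n_fused=n_fused, n_split=n_split)


def call_sample_fish(
    calls: Sequence[FishCall], fraction_threshold: float = 15.0
) -> tuple[float, bool]:
    """Sample-level ALK call from per-nucleus calls.

    Returns ``(percent rearranged among interpretable nuclei, positive)``;
    the sample is positive when the fraction reaches ``fraction_threshold``
    (inclusive).  Uninterpretable nuclei are excluded from the denominator.
    """
    interpretable = [c for c in calls if c.category is not FishCategory.UNINTERPRETABLE]
    if not interpretable:
        raise ValueError("no interpretable nuclei")
    fraction = 100.0 * sum(c.rearranged for c in interpretable) / len(interpretable)
    return fraction, fraction >= fraction_threshold
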