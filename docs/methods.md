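# Methods

## The measurement problem

Size-selective microfluidic enrichment releases a small population of large
circulating cells (candidate tumor cells, among other large rare cells)
from whole blood into a clean buffer stream.  As the cells sweep past a
fixed viewing window they are filmed by a high-speed brightfield camera
(nominally 256 × 376 px frames at 6006 frames/s for 15 s), and each cell is
seen about six times before it leaves the window.  `ctcflow` turns such a
recording into a per-millilitre count of large circulating cells, and adds
two rule-based classifiers for the downstream assays that consume the
collected cells: CK/CD45/DAPI immunofluorescence classification and ALK
break-apart FISH signal-pattern calls.

## Detection chain

For each recording one background raster is chosen (by default frame 0 —
flow is stopped before release begins, so the first frame is empty; a
per-pixel median mode is available for robustness).  Each subsequent frame
is processed as:

1. **Background subtraction.** `|frame − background|` in a widened integer
   domain, so both darker-than-background absorption and brighter edges
   register and nothing wraps around.
2. **Upscaling.** The difference image is enlarged ×3 with bilinear
   interpolation before binarization, which gives sub-original-pixel
   boundary placement.
3. **Binarization.** The detection threshold is `k·σ` (default `k = 4`)
   where σ is a robust noise scale of the difference image: the per-pixel
   median absolute difference, pooled over a frame subsample and converted
   to a Gaussian-equivalent sigma.  The median is insensitive to the tiny
   pixel fraction occupied by transiting objects, so the threshold can be
   estimated once per recording, including from frames that contain cells.
4. **Boundary delineation.** Pixels above `k·σ` mark a trace, but that
   threshold sits far below the contrast of a well-focused cell, so the
   binarized boundary would land at the foot of the interpolation ramp and
   inflate every radius by about one original pixel.  Each detected trace
   is therefore re-cut at `delineation_fraction` (default 0.5, i.e. full
   width at half maximum) of its own peak difference.  Sizing then no
   longer depends on the contrast-to-noise ratio; setting the fraction to 0
   restores plain single-threshold behaviour.  Known limitation: two
   *touching* objects of very different contrast share one trace, and the
   dimmer one can be under-segmented.
5. **Morphological closing** with a disk of radius 5 (upscaled pixels)
   fills the hollow traces that dark-outlined cells produce.
6. **Connected components** (8-connectivity).  Components smaller than the
   area of a 6 µm disk are discarded as noise; components touching the
   frame edge are kept but flagged.

Each component is measured in physical units using the pixel pitch at the
sample plane: area (µm²), equivalent-circle diameter `2·sqrt(area/π)`,
solidity (area / convex-hull area), axial ratio (major/minor axis of the
moment-equivalent ellipse; defined as 1 for degenerate single-pixel
components), and the intensity range (max − min of the *raw*
original-resolution pixels under the component footprint, so interpolation
cannot manufacture spread).  The centroid is reported in original-frame
coordinates.

The per-frame work is done inside isolated candidate neighbourhoods found
at original resolution (bilinear interpolation is a convex combination, so
an upscaled pixel can only exceed the threshold near an original pixel that
does).  Neighbourhoods are padded beyond the closing reach, which makes the
result identical to whole-frame processing while keeping a mostly-empty
6006 fps frame cheap.

## Gating and deduplication

Four accept intervals, trained in the original workflow on in-flow images
of A549 lung-carcinoma cells, select cell-like objects:

| feature          | interval      | bounds     |
|------------------|---------------|------------|
| diameter         | (12, 55) µm   | exclusive  |
| solidity         | [0.7, 1]      | inclusive  |
| axial ratio      | [1, 1.8]      | inclusive  |
| intensity range  | [0, 20000]    | inclusive  |

The diameter bounds are exclusive and the rest inclusive, following the two
phrasings the source criteria use.  Gate order (diameter → solidity →
axial ratio → intensity) affects only the per-gate rejection tallies that
are logged, never the surviving set.

A cell appears in ~6 consecutive frames, so raw gated detections overcount
roughly six-fold.  Deduplication is greedy nearest-neighbour linking: per
frame, each open track predicts its position (last position plus last
velocity, zero for singletons) and claims the nearest unclaimed detection
within `max_displacement`; claims resolve globally in ascending
(distance, track id, detection order), which makes the result deterministic
and independent of within-frame input order.  Tracks idle for more than
`max_frame_gap` frames (default 2) close.  `max_displacement` defaults to
`frame_cols / appearances × 1.5` ≈ 94 px: a cell crosses the window in
about `appearances` frames, and the 1.5 factor absorbs velocity spread.  A
divide-by-appearances fallback estimator (`count_by_appearance`) is kept
for cross-checking; tracking is the default.  The unique-cell count divided
by the blood volume the recording represents gives cells/mL.

## Cohort statistics

Healthy donors define the reference: threshold = mean + 2 × sample SD
(n−1 denominator; the source does not state the denominator and this is
the documented choice).  A sample is positive strictly above the threshold
(a tie is negative).  The published thresholds for the three enumeration
routes — 3.15 cells/mL (automated in-flow), 7.7 (well plate), 1.46
(immunofluorescence) — ship as presets because the underlying per-donor
rates are not published as numbers.  Spike-in concordance is summarised by
a through-origin fit `slope = Σxy/Σx²` with R² defined as the squared
Pearson correlation of the pairs (the source pairs an R² with a
through-origin fit without defining it; this is the documented reading).
Recovery rate is 100 × counted/seeded.

## Rule-based classifiers

**Immunofluorescence.**  Precedence: debris morphology → DEBRIS; CD45+
(regardless of CK) → WBC (doubly stained CK+/CD45+ events behave as
activated granulocytes); CK+/CD45− → CTC; DAPI-only events are CTC when
the nucleus is large (> 9 µm), not lobulated, and the N:C area ratio is
high (≥ 0.5 — the criterion says only "large", so the cutoff is exposed in
config); remaining DAPI− events are DEBRIS.  A DAPI-only event carrying
neither nuclear metric is unclassifiable and raises; if only one metric is
present the available one decides.

**ALK break-apart FISH.**  Red and green probe spots are paired greedily by
ascending pairwise distance (deterministic, index tie-break); a pair within
`fusion_distance` (default 5 px, roughly one signal width — conventions use
"closer than one signal width" and no number is published) is a fused
(yellow) copy of an intact locus.  Far pairs and lone spots each count as
one split, rearrangement-consistent signal.  Calls: any split signal →
POSITIVE (POSITIVE_POLYSOMY at ≥ 3 total copies); fused-only patterns →
NEGATIVE at exactly 2 copies, NEGATIVE_POLYSOMY at ≥ 3; fewer than 2 total
copies, or an upstream quality flag, → UNINTERPRETABLE.  The
fewer-than-two-copies guard runs *before* the split rule: a nucleus showing
a single probe signal in total is an unresolvable pattern, not evidence of
rearrangement.  Greedy pairing equals the matching whose sorted distance
sequence is lexicographically minimal, which is what the exhaustive test
oracle enumerates.  A sample is ALK-positive when ≥ 15% (inclusive) of
interpretable nuclei are rearranged.

## Synthetic recordings

The generator produces ground-truthed stacks that emulate release:

* **Cells** are anti-aliased ellipses (half-pixel soft edge), darker than
  background by `cell_contrast` (default 6000 counts on a 20000-count
  background — a strongly absorbing cell on a 16-bit sensor), translating
  along the column (flow) axis at constant speed chosen so each is fully
  visible in exactly `appearances_per_cell` frames (default 6) and fully
  outside the frame before and after.  Diameters are uniform on (16, 40) µm
  (comfortably inside the gate), axial ratios on (1.0, 1.6).
* **Sub-gate cells** are the same at 8–10.5 µm — detectable (above the 6 µm
  area guard) but below the 12 µm gate.
* **Debris** is rendered as jagged star polygons (5–6 spikes, inner radius
  25% of outer, outer radius 30–45 µm) whose solidity stays below 0.7 after
  closing by construction.
* **Noise** is i.i.d. Gaussian (σ = 60 counts) on a flat background; frame 0
  is always object-free so it can serve as the background model.

Objects are laid out on horizontal lanes separated by at least twice the
largest object diameter, entries synchronised across lanes and staggered
within a lane so windows never overlap.  In this regime every object's next
appearance is strictly nearer to its own track than any neighbour, so
greedy linking is provably exact and truth counts are recoverable — which
is what the deduplication tests rely on.  What this deliberately does not
model: optical physics (defocus, diffraction), cell deformation, velocity
profiles across the channel, overlapping cells, illumination drift.
Passing tests therefore demonstrate algorithmic correctness on idealised
imagery, not robustness to real-world acquisition artifacts.

Stacks are kept short (tens to ~1000 frames): the full 15 s × 6006 fps ≈
90,090-frame recording is generation-prohibitive at desk scale and adds
nothing to the logic under test — object density per frame, not total
duration, is what stresses the pipeline.

## Reproducing the concordance experiment

`scripts/acceptance.py` regenerates a spike-in series with true in-gate
counts {10, 25, 50, 100, 200, 400, 600} (mirroring the 10–600 cells spiked
into 5 mL of PBS in the original validation), runs detect → gate → track on
each stack and reports the through-origin slope of algorithm counts on true
counts.  The reference behaviour is a near-unity slope (published value
1.02 with R² = 0.97 against well-plate counts); the synthetic re-creation
typically yields slope 1.00 with R² = 1.0 because the idealised imagery
removes the manual-count noise present in the wet experiment.

## Numerical choices and conventions

* Coordinates are 0-based (row, column); rectangles half-open; image
  sequence frames are ordered by the last integer embedded in the filename.
* Default pixel pitch is 2.8 µm/px.  The optical train (10× objective,
  8.5 µm depth of focus) does not determine µm/px, so every physical-unit
  feature depends on this documented, user-overridable calibration value.
* Binarization uses strict `>`; the threshold has a floor of 0.5 counts so
  a noiseless recording does not binarize interpolation dust.
* Bilinear was chosen for the ×3 upscaling; the original description says
  only "with interpolation".  Scaling precedes binarization, as written.
* Sample seeds for series generation derive from `SeedSequence(base, i)`,
  so a series is reproducible as a whole and each member independently.
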