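"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a result with naive enumeration or pixel loops so the
production code path is checked against something it shares no logic with.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# morphology: naive pixel-loop closing and labelling
# ---------------------------------------------------------------------------

def naive_dilation(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Binary dilation; pixels outside the image count as background."""
    rows, cols = mask.shape
    fr, fc = footprint.shape
    ar, ac = fr // 2, fc // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            hit = False
            for i in range(fr):
                for j in range(fc):
                    if not footprint[i, j]:
                        continue
                    rr, cc = r + i - ar, c + j - ac
                    if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]:
                        hit = True
                        break
                if hit:
                    break
            out[r, c] = hit
    return out


def naive_erosion(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Binary erosion; pixels outside the image count as foreground."""
    rows, cols = mask.shape
    fr, fc = footprint.shape
    ar, ac = fr // 2, fc // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            ok = True
            for i in range(fr):
                for j in range(fc):
                    if not footprint[i, j]:
                        continue
                    rr, cc = r + i - ar, c + j - ac
                    if 0 <= rr < rows and 0 <= cc < cols and not mask[rr, cc]:
                        ok = False
                        break
                if not ok:
                    break
            out[r, c] = ok
    return out


def naive_closing(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return naive_erosion(naive_dilation(mask, footprint), footprint)


def naive_label(mask: np.ndarray) -> np.ndarray:
    """8-connected component labelling by breadth-first flood fill."""
    rows, cols = mask.shape
    labels = np.zeros((rows, cols), dtype=int)
    current = 0
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            nr, nc = rr + dr, cc + dc
                            if (0 <= nr < rows and 0 <= nc < cols
                                    and mask[nr, nc] and labels[nr, nc] == 0):
                                labels[nr, nc] = current
                                stack.append((nr, nc))
    return labels


# ---------------------------------------------------------------------------
# tracking: exhaustive optimal frame-to-frame assignment
# ---------------------------------------------------------------------------

def optimal_assignment_track_count(
    frames: list[list[tuple[float, float]]], max_displacement: float
) -> int:
    """Track count under exhaustive minimum-total-distance linking.

    Open tracks carry only their last position; per frame every injective
    assignment of tracks to detections (links farther than
    ``max_displacement`` forbidden) is enumerated and the one with minimal
    total distance wins.  Unassigned detections open new tracks.
    """
    open_positions: list[tuple[float, float]] = []
    n_tracks = 0
    for dets in frames:
        # best = (most links, then least total distance)
        best_key, best_pairs = (0, 0.0), []
        k = min(len(open_positions), len(dets))
        for size in range(k + 1):
            for track_subset in itertools.combinations(range(len(open_positions)), size):
                for det_perm in itertools.permutations(range(len(dets)), size):
                    cost = 0.0
                    ok = True
                    for ti, dj in zip(track_subset, det_perm):
                        d = math.dist(open_positions[ti], dets[dj])
                        if d > max_displacement:
                            ok = False
                            break
                        cost += d
                    if ok and (-size, cost) < (-best_key[0], best_key[1]):
                        best_key = (size, cost)
                        best_pairs = list(zip(track_subset, det_perm))
        assigned_tracks = {ti for ti, _ in best_pairs}
        assigned_dets = {dj for _, dj in best_pairs}
        new_positions = []
        for ti, dj in best_pairs:
            new_positions.append(dets[dj])
        for ti in range(len(open_positions)):
            if ti not in assigned_tracks:
                new_positions.append(open_positions[ti])
        for dj in range(len(dets)):
            if dj not in assigned_dets:
                new_positions.append(dets[dj])
                n_tracks += 1
        open_positions = new_positions
    return n_tracks


# ---------------------------------------------------------------------------
# FISH: exhaustive matching oracle
# ---------------------------------------------------------------------------

def brute_force_fish(
    reds: list[tuple[float, float]],
    greens: list[tuple[float, float]],
    fusion_distance: float,
    interpretable: bool = True,
) -> tuple[str, int, int]:
    """Classify by enumerating *all* complete red-green matchings.

    The matching whose ascending distance sequence is lexicographically
    smallest is selected (the fixed point of greedy closest-pair picking),
    then the signal-pattern rules are applied: pairs within
    ``fusion_distance`` are fused, everything else (far pairs, lone spots)
    is split; split >= 1 -> positive; fused-only patterns negative; fewer
    than 2 total copies -> uninterpretable.  Returns (category name,
    n_fused, n_split).
    """
    n_r, n_g = len(reds), len(greens)
    m = min(n_r, n_g)
    best_key = None
    best = []
    if n_r <= n_g:
        for green_perm in itertools.permutations(range(n_g), m):
            dists = sorted(
                math.dist(reds[i], greens[j]) for i, j in enumerate(green_perm)
            )
            if best_key is None or tuple(dists) < best_key:
                best_key = tuple(dists)
                best = dists
    else:
        for red_perm in itertools.permutations(range(n_r), m):
            dists = sorted(
                math.dist(reds[i], greens[j]) for j, i in enumerate(red_perm)
            )
            if best_key is None or tuple(dists) < best_key:
                best_key = tuple(dists)
                best = dists

    n_fused = sum(1 for d in best if d <= fusion_distance)
    n_split = (len(best) - n_fused) + (n_r - m) + (n_g - m)
    copies = n_fused + n_split
    if not interpretable or copies <= 1:
        category = "UNINTERPRETABLE"
    elif n_split >= 1:
        category = "POSITIVE_POLYSOMY" if copies >= 3 else "POSITIVE"
    elif copies == 2:
        category = "NEGATIVE"
    else:
        category = "NEGATIVE_POLYSOMY"
    return category, n_fused, n_split


# ---------------------------------------------------------------------------
# regression: independent least-squares through the origin
# ---------------------------------------------------------------------------

def lstsq_origin_slope(x, y) -> float:
    """Through-origin slope via numpy's general least-squares solver."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return float(coef[0])
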