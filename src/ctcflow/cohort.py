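"""Cohort-level statistics for large-cell counts.

Healthy donors set the reference level: a sample is called positive when its
per-mL rate exceeds the healthy mean + 2 standard deviations.  Spike-in
validation series are summarised by a through-origin regression of the
algorithm count on the reference count, whose slope near 1 and squared
Pearson correlation quantify concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Healthy-cohort thresholds (cells/mL of whole blood) published for the
#: three enumeration routes; usable for classification without recomputing
#: the underlying donor rates.
HEALTHY_THRESHOLD_PRESETS: dict[str, float] = {
    "automated": 3.15,          # in-flow automated counting
    "wellplate": 7.7,           # well-plate counting after DAPI staining
    "immunofluorescence": 1.46, # CK/CD45/DAPI classified CTCs
}


@dataclass
class RegressionFit:
    """Through-origin fit y = slope * x with squared Pearson correlation."""

    slope: float
    r_squared: float
    n_pairs: int


@dataclass
class CohortResult:
    healthy_rates: list[float]
    threshold: float
    sample_calls: list[tuple[str, float, bool]]
    positivity_fraction: float


def healthy_threshold(rates: Sequence[float]) -> float:
    """mean + 2 * sample standard deviation (n-1 denominator) of donor rates."""
    rates = np.asarray(rates, dtype=float)
    if rates.size < 2:
        raise ValueError("need at least 2 healthy rates for mean + 2SD")
    return float(rates.mean() + 2.0 * rates.std(ddof=1))


def call_positive(rate: float, threshold: float) -> bool:
    """Strictly above threshold; a rate equal to the threshold is negative."""
    if rate < 0 or threshold < 0:
        raise ValueError("rate and threshold must be non-negative")
    return rate > threshold


def regress_origin(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Through-origin least squares: slope = sum(xy) / sum(x^2).

    ``r_squared`` is the squared Pearson correlation of the paired values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all x are zero; through-origin slope undefined")
    slope = float(np.dot(x, y)) / sxx
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: constant x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionFit(slope=slope, r_squared=r * r, n_pairs=int(x.size))


def positivity_fraction(calls: Sequence[bool]) -> float:
    """Percent of positive calls, reported to 1 decimal (7/9 -> 77.8)."""
    if len(calls) == 0:
        raise ValueError("no calls")
    return round(100.0 * sum(bool(c) for c in calls) / len(calls), 1)


def recovery_rate(counted: float, seeded: float) -> float:
    """Percent of seeded cells counted back after slide processing."""
    if seeded <= 0:
        raise ValueError("seeded must be positive")
    if counted < 0:
        raise ValueError("counted must be >= 0")
    return 100.0 * counted / seeded


def analyze_cohort(
    healthy: Sequence[tuple[str, float]],
    patients: Sequence[tuple[str, float]],
    threshold: float | None = None,
) -> CohortResult:
    """Threshold the patient rates against the healthy cohort.

    ``threshold`` overrides the computed mean + 2SD (e.g. a preset from
    :data:`HEALTHY_THRESHOLD_PRESETS`).
    """
    healthy_rates = [r for _, r in healthy]
    if threshold is None:
        threshold = healthy_threshold(healthy_rates)
    calls = [(sid, rate, call_positive(rate, threshold)) for sid, rate in patients]
    frac = positivity_fraction([c for _, _, c in calls]) if calls else 0.0
    return CohortResult(
        healthy_rates=healthy_rates,
        threshold=threshold,
        sample_calls=calls,
        positivity_fraction=frac,
    )
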