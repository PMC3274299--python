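"""Scoring automated detections against manual annotations.

The error typology follows the counting study's usage: a Type-1 error is an
animal present in the frame but missed by the automation; a Type-2 error is
a detection where no animal is present.  An image is "correct" only when it
has neither kind of error, and the percent of correct images summarizes a
series.  Coverage and fractal-dimension time series from manual and
automated processing are compared with the Pearson product-moment
correlation and a simple overestimation-event count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MatchResult",
    "ErrorTally",
    "match_detections",
    "tally_errors",
    "compare_series",
    "overestimation_events",
]

DEFAULT_MATCH_RADIUS = 50.0


@dataclass
class MatchResult:
    """Per-image assignment between automated and manual centroids."""

    matched: list[tuple[int, int]]  # (manual index, auto index)
    unmatched_manual: list[int]  # Type-1 events (missed animals)
    unmatched_auto: list[int]  # Type-2 events (spurious detections)

    @property
    def type1(self) -> int:
        return len(self.unmatched_manual)

    @property
    def type2(self) -> int:
        return len(self.unmatched_auto)

    @property
    def correct(self) -> bool:
        return self.type1 == 0 and self.type2 == 0


@dataclass
class ErrorTally:
    """Series-level error bookkeeping."""

    n_images: int
    correct_images: int
    type1: int
    type2: int

    @property
    def correct_pct(self) -> float:
        return 100.0 * self.correct_images / self.n_images


def match_detections(
    auto: list[tuple[float, float]],
    manual: list[tuple[float, float]],
    match_radius: float = DEFAULT_MATCH_RADIUS,
) -> MatchResult:
    """Greedy nearest-first one-to-one matching within ``match_radius`` pixels.

    All manual-auto pairs within the radius are ranked by distance and
    consumed greedily; leftovers on the manual side are misses (Type-1),
    on the automated side spurious detections (Type-2).
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    a = np.asarray(auto, dtype=float).reshape(-1, 2)
    m = np.asarray(manual, dtype=float).reshape(-1, 2)
    pairs = []
    for mi in range(len(m)):
        for ai in range(len(a)):
            d = float(np.hypot(*(m[mi] - a[ai])))
            if d <= match_radius:
                pairs.append((d, mi, ai))
    pairs.sort()
    used_m: set[int] = set()
    used_a: set[int] = set()
    matched = []
    for _, mi, ai in pairs:
        if mi in used_m or ai in used_a:
            continue
        matched.append((mi, ai))
        used_m.add(mi)
        used_a.add(ai)
    return MatchResult(
        matched=matched,
        unmatched_manual=[i for i in range(len(m)) if i not in used_m],
        unmatched_auto=[i for i in range(len(a)) if i not in used_a],
    )


def tally_errors(per_image: list[MatchResult]) -> ErrorTally:
    """Sum per-image matches into a series tally.

    An image counts as correct only with zero errors of either type.
    """
    if not per_image:
        raise ValueError("empty image series")
    return ErrorTally(
        n_images=len(per_image),
        correct_images=sum(r.correct for r in per_image),
        type1=sum(r.type1 for r in per_image),
        type2=sum(r.type2 for r in per_image),
    )


def compare_series(a, b) -> float:
    """Pearson product-moment correlation between two equal-length series."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero-variance series has no defined correlation")
    return float(stats.pearsonr(a, b).statistic)


def overestimation_events(manual, auto) -> tuple[int, float]:
    """Count indices where the manual estimate exceeds the automated one.

    Returns ``(count, percentage of the series length)``.
    """
    manual = np.asarray(manual, dtype=float)
    auto = np.asarray(auto, dtype=float)
    if manual.shape != auto.shape:
        raise ValueError("series lengths differ")
    count = int(np.sum(manual > auto))
    return count, float(100.0 * count / len(manual))
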