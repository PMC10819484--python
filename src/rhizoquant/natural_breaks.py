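"""Exact one-dimensional natural-breaks (Fisher--Jenks) classification.

Natural-breaks classification partitions the sorted values of a 1-D sample
into ``k`` contiguous classes so that the total within-class sum of squared
deviations (SSD) from the class means is globally minimal.  It is the
standard "Natural Breaks (Jenks)" reclassification rule of GIS raster
tooling, here used to reclassify micrograph pixel intensities before
root-hair extraction.

The solver is Fisher's exact dynamic programme over the *distinct* sorted
values with their multiplicities, O(k * d**2) for d distinct values, so a
megapixel image with few distinct intensities (e.g. 8-bit data, or data
binned to a fixed histogram) is still cheap.  Among partitions of equal
minimal SSD the lexicographically smallest break vector is returned, which
makes the classification fully deterministic.

Conventions
-----------
* ``breaks`` holds the k-1 lower bounds of classes 1..k-1 (the smallest
  member of each class after the first), in ascending order.
* Class intervals are left-closed / right-open; a value equal to a break
  belongs to the *higher* class; values beyond the data range clamp to the
  first / last class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "BreaksResult",
    "jenks_breaks",
    "jenks_breaks_histogram",
    "classify_value",
]


@dataclass(frozen=True)
class BreaksResult:
    """Outcome of a natural-breaks classification.

    Attributes
    ----------
    k:
        Number of classes.
    breaks:
        Ascending tuple of ``k - 1`` boundary values; ``breaks[i]`` is the
        smallest data value assigned to class ``i + 1``.
    within_class_ssd:
        Total within-class sum of squared deviations of the optimal
        partition (in squared value units).
    """

    k: int
    breaks: tuple[float, ...]
    within_class_ssd: float

    def class_of(self, v: float | np.ndarray) -> int | np.ndarray:
        """Class index of ``v`` (vectorised).

        Values below the first break map to 0, values at or above the last
        break map to ``k - 1``; a value equal to a break takes the higher
        class index.
        """
        idx = np.searchsorted(np.asarray(self.breaks), v, side="right")
        if np.isscalar(v) or np.ndim(v) == 0:
            return int(idx)
        return idx


def classify_value(v: float, result: BreaksResult) -> int:
    """Class index of a single value under a fitted :class:`BreaksResult`."""
    return int(result.class_of(v))


def _segment_stats(values: np.ndarray, counts: np.ndarray):
    """Weighted prefix sums enabling O(1) SSD of any contiguous segment."""
    w = counts.astype(np.float64)
    x = values.astype(np.float64)
    s0 = np.concatenate(([0.0], np.cumsum(w)))
    s1 = np.concatenate(([0.0], np.cumsum(w * x)))
    s2 = np.concatenate(([0.0], np.cumsum(w * x * x)))

    def ssd(i, j):
        """SSD of distinct values i..j inclusive; i, j may be arrays."""
        n = s0[j + 1] - s0[i]
        t1 = s1[j + 1] - s1[i]
        t2 = s2[j + 1] - s2[i]
        out = t2 - t1 * t1 / n
        # guard tiny negative round-off on pure segments
        return np.maximum(out, 0.0)

    return ssd


def _fisher_dp(values: np.ndarray, counts: np.ndarray, k: int) -> BreaksResult:
    """Exact DP over sorted distinct ``values`` with multiplicities ``counts``.

    Uses a suffix formulation so the optimal partition can be rebuilt
    front-to-back, taking the smallest feasible first boundary at every
    step -- this realises the lexicographically-smallest-breaks tie rule.
    """
    d = len(values)
    ssd = _segment_stats(values, counts)

    # S[j, i] = minimal SSD of partitioning values[i:] into j classes.
    S = np.full((k + 1, d + 1), np.inf)
    S[0, d] = 0.0
    idx = np.arange(d)
    S[1, :d] = ssd(idx, d - 1)
    for j in range(2, k + 1):
        # class starting at i may end at e in [i, d - (j - 1) - 1]
        for i in range(d - j + 1):
            e = np.arange(i, d - j + 1)
            cand = ssd(i, e) + S[j - 1, e + 1]
            S[j, i] = cand.min()

    total = float(S[k, 0])

    # Forward reconstruction: smallest end index achieving the optimum at
    # each step => lexicographically smallest break vector.
    breaks: list[float] = []
    i = 0
    for j in range(k, 1, -1):
        e = np.arange(i, d - j + 1)
        cand = ssd(i, e) + S[j - 1, e + 1]
        end = int(e[int(np.argmin(cand))])
        breaks.append(float(values[end + 1]))
        i = end + 1
    return BreaksResult(k=k, breaks=tuple(breaks), within_class_ssd=total)


def jenks_breaks(values: Iterable[float], k: int) -> BreaksResult:
    """Optimal k-class natural-breaks partition of ``values``.

    Parameters
    ----------
    values:
        Non-empty sample (any order; duplicates allowed).
    k:
        Number of classes, ``1 <= k <=`` number of distinct values.

    Returns
    -------
    BreaksResult
        The partition of the sorted values into ``k`` contiguous classes
        minimising the total within-class SSD.

    Raises
    ------
    ValueError
        On an empty sample, non-finite values, or ``k`` outside its range.
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("jenks_breaks requires a non-empty sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("jenks_breaks requires finite values")
    distinct, counts = np.unique(arr, return_counts=True)
    if not 1 <= k <= distinct.size:
        raise ValueError(
            f"k={k} outside valid range 1..{distinct.size} (distinct values)"
        )
    return _fisher_dp(distinct, counts, k)


def jenks_breaks_histogram(
    histogram: Mapping[float, int] | Sequence[tuple[float, int]], k: int
) -> BreaksResult:
    """Natural breaks from a value -> count histogram.

    Exactly equivalent to :func:`jenks_breaks` on the expanded value list
    when the bin values are the exact data values; when intensities were
    binned beforehand the result is the optimal partition *of the binned
    values* (an approximation to the unbinned optimum).
    """
    items = sorted(histogram.items()) if isinstance(histogram, Mapping) else sorted(histogram)
    vals = np.asarray([v for v, c in items], dtype=np.float64)
    cnts = np.asarray([c for v, c in items], dtype=np.int64)
    keep = cnts > 0
    vals, cnts = vals[keep], cnts[keep]
    if vals.size == 0:
        raise ValueError("histogram has no non-empty bins")
    if not 1 <= k <= vals.size:
        raise ValueError(f"k={k} outside valid range 1..{vals.size} (non-empty bins)")
    return _fisher_dp(vals, cnts, k)
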