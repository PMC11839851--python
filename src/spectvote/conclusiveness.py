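"""Inconclusive intervals on the sigmoid output.

An inconclusive interval is an asymmetric interval around the 0.5 decision
threshold, determined on a validation set so that it contains a predefined
target proportion of validation cases with equally many below and above
the threshold.  Test cases whose sigmoid falls inside the interval are
flagged "inconclusive"; all others are "certain".

Conventions (the construction is only specified up to these choices):

* k = round(target * n / 2), rounded half-up, cases per side;
* sigmoid values exactly at 0.5 count as "below" (matching the <= 0.5
  decision rule);
* ties in distance-to-threshold are broken by input order;
* interval bounds sit at the midpoint between the outermost included case
  and the nearest excluded case on that side; when a whole side is
  included the bound sits on the outermost included value itself;
* membership is inclusive: lower <= s <= upper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the 50 target proportions 0.2%, 0.4%, ..., 10.0%
GRID_TARGETS: tuple[float, ...] = tuple(round(0.002 * i, 3) for i in range(1, 51))


@dataclass(frozen=True)
class InconclusiveInterval:
    lower: float
    upper: float
    target_proportion: float
    n_below: int
    n_above: int
    clipped: bool = False  # a side had fewer cases than requested

    @property
    def empty(self) -> bool:
        return self.n_below == 0 and self.n_above == 0

    def contains(self, sigmoids: np.ndarray) -> np.ndarray:
        s = np.asarray(sigmoids, dtype=float)
        if self.empty:
            return np.zeros(s.shape, dtype=bool)
        return (s >= self.lower) & (s <= self.upper)


def determine_interval(
    validation_sigmoids, target_proportion: float
) -> InconclusiveInterval:
    """Equal-sided inconclusive interval for one target proportion."""
    s = np.asarray(validation_sigmoids, dtype=float)
    if s.size == 0:
        raise ValueError("validation sigmoids must be non-empty")
    if not 0.0 < target_proportion <= 1.0:
        raise ValueError("target proportion must be in (0, 1]")
    n = s.size
    k = int(np.floor(target_proportion * n / 2.0 + 0.5))  # round half-up
    if k == 0:
        return InconclusiveInterval(0.5, 0.5, target_proportion, 0, 0)

    below_idx = np.flatnonzero(s <= 0.5)
    above_idx = np.flatnonzero(s > 0.5)

    def side(idx: np.ndarray, sign: float):
        """Select the k cases closest to 0.5; return (bound, count, clipped)."""
        if idx.size == 0:
            return 0.5, 0, True
        dist = sign * (0.5 - s[idx])  # >= 0 on the "below" side when sign=+1
        order = idx[np.argsort(dist, kind="stable")]
        take = min(k, order.size)
        outermost = s[order[take - 1]]
        if take < order.size:
            nearest_excluded = s[order[take]]
            bound = 0.5 * (outermost + nearest_excluded)
        else:
            bound = outermost  # whole side included
        return float(bound), take, take < k

    lower, n_below, clip_b = side(below_idx, +1.0)
    upper, n_above, clip_a = side(above_idx, -1.0)
    return InconclusiveInterval(
        lower, upper, target_proportion, n_below, n_above, clip_b or clip_a
    )


@dataclass
class IntervalGrid:
    intervals: list[InconclusiveInterval]

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)


def build_grid(validation_sigmoids, targets=GRID_TARGETS) -> IntervalGrid:
    """One interval per grid target; nested by construction."""
    return IntervalGrid([determine_interval(validation_sigmoids, t) for t in targets])


def classify_certainty(test_sigmoids, interval: InconclusiveInterval) -> np.ndarray:
    """Boolean mask: True = inconclusive, False = certain."""
    return interval.contains(test_sigmoids)


def observed_proportion(test_sigmoids, interval: InconclusiveInterval) -> float:
    flags = classify_certainty(test_sigmoids, interval)
    return float(flags.mean()) if flags.size else 0.0


def interval_range_coverage(interval: InconclusiveInterval) -> float:
    """Width of the interval as a percentage of the sigmoid range (0, 1)."""
    if interval.empty or interval.upper <= interval.lower:
        return 0.0
    return (interval.upper - interval.lower) * 100.0


def grid_table(grid: IntervalGrid, method: str = "", realization: int = 0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": method,
            "realization": realization,
            "target_proportion": [iv.target_proportion for iv in grid],
            "lower": [iv.lower for iv in grid],
            "upper": [iv.upper for iv in grid],
            "n_below": [iv.n_below for iv in grid],
            "n_above": [iv.n_above for iv in grid],
            "clipped": [iv.clipped for iv in grid],
        }
    )
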