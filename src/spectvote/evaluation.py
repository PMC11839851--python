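"""Performance metrics and statistical comparisons.

Covers: balanced accuracy by certainty stratum, the certainty-curve AUC
(balanced accuracy in certain cases vs. observed proportion of
inconclusive cases, trapezoid-integrated over 0.2-10 % and scaled to the
maximum possible area), observed-vs-target regression through the origin,
the distance-from-threshold contrast between reader-consistent and
reader-discrepant cases, and the corrected resampled paired t-test of
Nadeau & Bengio for metrics measured on K overlapping random splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .conclusiveness import IntervalGrid, classify_certainty

#: default integration range for the certainty-curve AUC (fractions)
AUC_RANGE: tuple[float, float] = (0.002, 0.10)

#: default test-to-train size ratio for the 60/20/20 design
DEFAULT_RHO = 0.2 / 0.6


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @classmethod
    def from_predictions(cls, labels, predictions) -> "ConfusionCounts":
        y = np.asarray(labels).astype(int)
        p = np.asarray(predictions).astype(int)
        return cls(
            tp=int(((y == 1) & (p == 1)).sum()),
            fn=int(((y == 1) & (p == 0)).sum()),
            tn=int(((y == 0) & (p == 0)).sum()),
            fp=int(((y == 0) & (p == 1)).sum()),
        )


def balanced_accuracy(counts: ConfusionCounts) -> float | None:
    """100 * (sensitivity + specificity) / 2; None if a class is absent."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0 or neg == 0:
        return None
    sens = counts.tp / pos
    spec = counts.tn / neg
    return 100.0 * (sens + spec) / 2.0


@dataclass
class CertaintyCurve:
    """(observed inconclusive proportion, BA certain, BA inconclusive) points."""

    points: list[tuple[float, float | None, float | None]]
    method: str = ""
    realization: int = 0

    def defined(self) -> list[tuple[float, float]]:
        return [(x, y) for x, y, _ in self.points if y is not None]


def build_certainty_curve(
    sigmoids,
    labels,
    grid: IntervalGrid,
    method: str = "",
    realization: int = 0,
) -> CertaintyCurve:
    """Balanced accuracy in certain / inconclusive strata per grid interval.

    The abscissa is the proportion of inconclusive cases actually observed
    in the evaluated set, not the validation target.  Duplicate abscissae
    are collapsed keeping the last (largest-target) point.  Undefined
    balanced accuracies (single-class strata) are kept as gaps.
    """
    s = np.asarray(sigmoids, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.size != y.size:
        raise ValueError("labels must cover all cases")
    pred = (s > 0.5).astype(int)
    seen: dict[float, tuple] = {}
    overall = balanced_accuracy(ConfusionCounts.from_predictions(y, pred))
    seen[0.0] = (0.0, overall, None)
    for interval in grid:
        inc = classify_certainty(s, interval)
        prop = float(inc.mean())
        ba_cert = (
            balanced_accuracy(ConfusionCounts.from_predictions(y[~inc], pred[~inc]))
            if (~inc).any()
            else None
        )
        ba_inc = (
            balanced_accuracy(ConfusionCounts.from_predictions(y[inc], pred[inc]))
            if inc.any()
            else None
        )
        seen[prop] = (prop, ba_cert, ba_inc)
    points = [seen[p] for p in sorted(seen)]
    return CertaintyCurve(points, method, realization)


def certainty_auc(curve: CertaintyCurve, auc_range: tuple[float, float] = AUC_RANGE) -> float:
    """Trapezoid AUC of BA(certain) over the observed-proportion range,
    scaled so that constant 100 % balanced accuracy gives AUC = 100."""
    lo, hi = auc_range
    pts = curve.defined()
    if len(pts) < 2:
        raise ValueError("need at least 2 defined curve points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    # interpolate onto the range endpoints; constant extension at the edges
    xs = np.unique(np.concatenate([[lo], x[(x > lo) & (x < hi)], [hi]]))
    ys = np.interp(xs, x, y)
    area = np.trapezoid(ys, xs)
    return float(area / (hi - lo))


def regression_through_origin(target_proportions, observed_proportions) -> float:
    """Least-squares slope of observed on target with no intercept."""
    x = np.asarray(target_proportions, dtype=float)
    y = np.asarray(observed_proportions, dtype=float)
    if x.size == 0 or x.size != y.size:
        raise ValueError("inputs must be equal-length and non-empty")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all target proportions are zero")
    return float(np.sum(x * y) / sxx)


def distance_by_consistency(sigmoids, unanimous_flags) -> pd.DataFrame:
    """Mean |sigmoid - 0.5| with normal-approximation 95 % CI per group.

    Groups: "consistent" (unanimous reader votes) vs "discrepant".
    Groups without members are omitted from the table.
    """
    s = np.asarray(sigmoids, dtype=float)
    u = np.asarray(unanimous_flags, dtype=bool)
    dist = np.abs(s - 0.5)
    rows = []
    for name, mask in (("consistent", u), ("discrepant", ~u)):
        if not mask.any():
            continue
        d = dist[mask]
        se = d.std(ddof=1) / np.sqrt(d.size) if d.size > 1 else 0.0
        rows.append(
            {
                "group": name,
                "n": int(d.size),
                "mean_distance": float(d.mean()),
                "ci95_lower": float(d.mean() - 1.96 * se),
                "ci95_upper": float(d.mean() + 1.96 * se),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PairedComparison:
    metric: str
    t_corrected: float
    df: int
    p_two_sided: float
    rho: float
    mean_difference: float
    differences: np.ndarray = field(repr=False, default=None)


def nadeau_bengio_ttest(
    differences, rho: float = DEFAULT_RHO, metric: str = ""
) -> PairedComparison:
    """Corrected resampled paired t-test over K random-split realizations.

    t = mean(d) / sqrt((1/K + rho) * var(d)), with the unbiased sample
    variance and rho the test-to-train size ratio; the correction inflates
    the variance to account for the overlap between the K training sets.
    Two-sided p from Student's t with K - 1 degrees of freedom.  As
    rho -> 0 the statistic reduces to the classical paired t.
    """
    d = np.asarray(differences, dtype=float)
    k = d.size
    if k < 2:
        raise ValueError("need at least 2 paired differences")
    if rho <= 0:
        raise ValueError("rho must be positive")
    mean = float(d.mean())
    var = float(d.var(ddof=1))
    if var == 0.0:
        if mean == 0.0:
            return PairedComparison(metric, 0.0, k - 1, 1.0, rho, 0.0, d)
        import warnings

        warnings.warn("zero variance with nonzero mean difference; p degenerates to 0")
        return PairedComparison(metric, np.inf if mean > 0 else -np.inf, k - 1, 0.0, rho, mean, d)
    t = mean / np.sqrt((1.0 / k + rho) * var)
    p = 2.0 * stats.t.sf(abs(t), df=k - 1)
    return PairedComparison(metric, float(t), k - 1, float(p), rho, mean, d)
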