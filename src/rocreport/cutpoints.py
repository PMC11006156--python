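"""Optimal cutoff selection: the five method families.

Outcome-oriented selectors operate on the empirical ROC curve (Youden's J,
closest-top-left distance, constrained maximization, minimum p-value);
biomarker-oriented cutoffs come from the pooled marker distribution
(mean / median / mode); and a manual cutoff is passed through unchanged.

All argmax/argmin ties are broken toward the smallest threshold, which
makes every selector deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import BiomarkerDataset
from .errors import DegenerateDataError, InfeasibleConstraintError
from .roc import GREATER, ROCCurve, _operating_points, candidate_thresholds

__all__ = [
    "CutpointResult",
    "youden",
    "closest_topleft",
    "constrained_max",
    "min_pvalue",
    "biomarker_oriented",
    "manual_cutoff",
    "marker_mode",
]


@dataclass
class CutpointResult:
    """A selected threshold, the method that chose it and its criterion value.

    ``criterion_value`` is J for youden, the squared corner distance d for
    closest_topleft, the Pearson chi-square statistic for min_pvalue, the
    achieved value of the maximized metric for constrained selection, and
    the threshold itself for biomarker-oriented / manual cutoffs.
    """

    method: str
    threshold: float
    criterion_value: float
    p_value: float | None = None
    constraint: tuple[str, float] | None = None
    sensitivity: float | None = None
    specificity: float | None = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "threshold": self.threshold,
            "criterion_value": self.criterion_value,
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
        if self.constraint is not None:
            d["constraint"] = {"metric": self.constraint[0], "min_value": self.constraint[1]}
        if self.sensitivity is not None:
            d["sensitivity"] = self.sensitivity
            d["specificity"] = self.specificity
        return d


def _argbest(values: np.ndarray, thresholds: np.ndarray, maximize: bool) -> int:
    """Index of the best value; ties broken toward the smallest threshold.

    ``thresholds`` is ascending, so the first index attaining the optimum
    is the smallest-threshold winner.
    """
    best = values.max() if maximize else values.min()
    return int(np.nonzero(values == best)[0][0])


def youden(curve: ROCCurve) -> CutpointResult:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1."""
    j = curve.sensitivities + curve.specificities - 1.0
    i = _argbest(j, curve.thresholds, maximize=True)
    return CutpointResult(
        method="youden",
        threshold=float(curve.thresholds[i]),
        criterion_value=float(j[i]),
        sensitivity=float(curve.sensitivities[i]),
        specificity=float(curve.specificities[i]),
    )


def closest_topleft(curve: ROCCurve) -> CutpointResult:
    """Threshold minimizing d = (1 - sens)^2 + (1 - spec)^2."""
    d = (1.0 - curve.sensitivities) ** 2 + (1.0 - curve.specificities) ** 2
    i = _argbest(d, curve.thresholds, maximize=False)
    return CutpointResult(
        method="closest_topleft",
        threshold=float(curve.thresholds[i]),
        criterion_value=float(d[i]),
        sensitivity=float(curve.sensitivities[i]),
        specificity=float(curve.specificities[i]),
    )


def constrained_max(
    curve: ROCCurve, constrain_metric: str, min_value: float
) -> CutpointResult:
    """Maximize the complementary metric subject to constrain_metric >= bound.

    Mirrors the "maximized" selector: e.g. with a minimum specificity of
    0.7, return the operating point of highest sensitivity among those
    with specificity >= 0.7.
    """
    if constrain_metric not in ("sensitivity", "specificity"):
        raise ValueError("constrain_metric must be 'sensitivity' or 'specificity'")
    if not 0 < min_value <= 1:
        raise ValueError("min_value must be in (0, 1]")
    if constrain_metric == "specificity":
        constrained, target = curve.specificities, curve.sensitivities
        method = "max_sens_constrained"
    else:
        constrained, target = curve.sensitivities, curve.specificities
        method = "max_spec_constrained"
    ok = constrained >= min_value
    if not ok.any():
        raise InfeasibleConstraintError(
            f"no operating point has {constrain_metric} >= {min_value}"
        )
    masked = np.where(ok, target, -np.inf)
    i = _argbest(masked, curve.thresholds, maximize=True)
    return CutpointResult(
        method=method,
        threshold=float(curve.thresholds[i]),
        criterion_value=float(target[i]),
        constraint=(constrain_metric, float(min_value)),
        sensitivity=float(curve.sensitivities[i]),
        specificity=float(curve.specificities[i]),
    )


def min_pvalue(data: BiomarkerDataset, direction: str = GREATER) -> CutpointResult:
    """Minimum-p-value cutoff: maximize the 2x2 Pearson chi-square.

    Every candidate midpoint dichotomizes the marker; the resulting
    predicted-vs-actual table's Pearson chi-square (1 df, no continuity
    correction) is computed, and the threshold with the largest statistic
    (smallest p) wins.  The +/-inf sentinels are excluded because their
    tables have a zero margin.  The selected p-value is reported raw:
    this procedure is known to inflate the Type I error rate and the
    report carries a caveat to that effect.
    """
    pos, neg = data.positives, data.negatives
    if pos.size == 0 or neg.size == 0:
        raise DegenerateDataError("both classes must be non-empty")
    thr = candidate_thresholds(data.marker)[1:-1]  # interior midpoints only
    if thr.size == 0:
        raise DegenerateDataError(
            "all contingency tables degenerate: fewer than 2 distinct marker values"
        )
    sens, spec = _operating_points(pos, neg, thr, direction)
    m, n = pos.size, neg.size
    tp = np.round(sens * m)
    fn = m - tp
    tn = np.round(spec * n)
    fp = n - tn
    total = float(m + n)
    # margins are all positive at interior midpoints
    chi2 = (
        total * (tp * tn - fp * fn) ** 2
        / ((tp + fp) * (fn + tn) * (tp + fn) * (fp + tn))
    )
    i = _argbest(chi2, thr, maximize=True)
    stat = float(chi2[i])
    return CutpointResult(
        method="min_pvalue",
        threshold=float(thr[i]),
        criterion_value=stat,
        p_value=float(stats.chi2.sf(stat, df=1)),
        sensitivity=float(sens[i]),
        specificity=float(spec[i]),
    )


def marker_mode(x: np.ndarray) -> float:
    """Mode of a marker sample.

    If any value repeats, the most frequent value wins (smallest on ties).
    For an all-distinct continuous sample, the midpoint of the modal bin of
    a Freedman-Diaconis histogram is returned (first bin on ties).
    """
    x = np.asarray(x, dtype=float)
    values, counts = np.unique(x, return_counts=True)
    if counts.max() > 1:
        return float(values[np.argmax(counts)])  # argmax -> first = smallest
    edges = np.histogram_bin_edges(x, bins="fd")
    hist, edges = np.histogram(x, bins=edges)
    k = int(np.argmax(hist))
    return float((edges[k] + edges[k + 1]) / 2.0)


def biomarker_oriented(data: BiomarkerDataset, statistic: str) -> CutpointResult:
    """Cutoff from the pooled marker distribution: mean, median or mode."""
    x = data.marker
    if statistic == "mean":
        c = float(np.mean(x))
    elif statistic == "median":
        c = float(np.median(x))
    elif statistic == "mode":
        c = marker_mode(x)
    else:
        raise ValueError("statistic must be 'mean', 'median' or 'mode'")
    return CutpointResult(method=statistic, threshold=c, criterion_value=c)


def manual_cutoff(data: BiomarkerDataset, threshold: float) -> CutpointResult:
    """Pass a user-chosen cutoff through; performance is computed downstream."""
    threshold = float(threshold)
    if not np.isfinite(threshold):
        raise ValueError("manual threshold must be finite")
    return CutpointResult(method="manual", threshold=threshold, criterion_value=threshold)
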