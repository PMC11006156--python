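"""Empirical ROC curve construction, trapezoidal AUC and its confidence interval.

The curve is built over candidate thresholds placed at the midpoints of
consecutive distinct marker values, with -inf/+inf sentinels providing the
two trivial operating points (sens=1, spec=0) and (sens=0, spec=1).  With
``greater_is_positive`` a subject is called positive iff marker > c, so a
candidate midpoint can never tie with an observed value.

The default confidence interval is the DeLong nonparametric interval: the
variance of the empirical AUC is estimated from placement values and a
Wald interval auc +/- z * SE is clipped to [0, 1].  A stratified
percentile bootstrap is available as an alternative for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import BiomarkerDataset
from .errors import DegenerateDataError, InsufficientDataError

GREATER = "greater_is_positive"
LESS = "less_is_positive"


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class ROCCurve:
    """Ordered operating points plus AUC and its confidence interval."""

    thresholds: np.ndarray  # ascending, with -inf/+inf sentinels
    sensitivities: np.ndarray
    specificities: np.ndarray
    direction: str
    auc: float
    auc_ci_lower: float
    auc_ci_upper: float
    ci_level: float
    n_positive: int
    n_negative: int
    ci_method: str = "delong"

    @property
    def points(self) -> list[ROCPoint]:
        return [
            ROCPoint(float(t), float(s), float(p))
            for t, s, p in zip(self.thresholds, self.sensitivities, self.specificities)
        ]

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "auc": self.auc,
            "auc_ci_lower": self.auc_ci_lower,
            "auc_ci_upper": self.auc_ci_upper,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "points": [
                {
                    # sentinel thresholds as strings so the JSON stays strict
                    "threshold": (
                        p.threshold if np.isfinite(p.threshold)
                        else ("-inf" if p.threshold < 0 else "inf")
                    ),
                    "sensitivity": p.sensitivity,
                    "specificity": p.specificity,
                }
                for p in self.points
            ],
        }


def candidate_thresholds(marker: np.ndarray) -> np.ndarray:
    """Midpoints of consecutive distinct marker values with +/-inf sentinels."""
    v = np.unique(np.asarray(marker, dtype=float))
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _operating_points(pos, neg, thresholds, direction):
    pos = np.sort(np.asarray(pos, dtype=float))
    neg = np.sort(np.asarray(neg, dtype=float))
    m, n = pos.size, neg.size
    if direction == GREATER:
        # positive call: marker > c
        sens = (m - np.searchsorted(pos, thresholds, side="right")) / m
        spec = np.searchsorted(neg, thresholds, side="right") / n
    elif direction == LESS:
        # positive call: marker < c
        sens = np.searchsorted(pos, thresholds, side="left") / m
        spec = (n - np.searchsorted(neg, thresholds, side="left")) / n
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return sens.astype(float), spec.astype(float)


def _trapezoid_auc(sens: np.ndarray, spec: np.ndarray) -> float:
    fpr = 1.0 - np.asarray(spec, dtype=float)
    tpr = np.asarray(sens, dtype=float)
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def auc_trapezoid(curve: ROCCurve) -> float:
    """Trapezoidal area over (1 - specificity, sensitivity).

    Equals the Mann-Whitney statistic U / (n_pos * n_neg) with ties
    weighted 1/2 (checked as a property in the test suite).
    """
    return _trapezoid_auc(curve.sensitivities, curve.specificities)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """Empirical AUC and its DeLong variance via midrank placements."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = pos.size, neg.size
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    r_pos, r_neg = all_r[:m], all_r[m:]
    auc = (r_pos.sum() - m * (m + 1) / 2.0) / (m * n)
    # placement values: V10_i = P(pos_i beats a random negative), V01_j sym.
    v10 = (r_pos - stats.rankdata(pos)) / n
    v01 = 1.0 - (r_neg - stats.rankdata(neg)) / m
    s10 = v10.var(ddof=1)
    s01 = v01.var(ddof=1)
    return float(auc), float(s10 / m + s01 / n)


def auc_ci_delong(
    data: BiomarkerDataset,
    level: float = 0.95,
    direction: str = GREATER,
) -> tuple[float, float]:
    """DeLong Wald confidence interval for the empirical AUC, clipped to [0, 1]."""
    pos, neg = _oriented(data, direction)
    if pos.size < 2 or neg.size < 2:
        raise InsufficientDataError(
            "DeLong interval needs at least 2 observations per class "
            f"(got {pos.size} positive, {neg.size} negative)"
        )
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    auc, var = _delong_variance(pos, neg)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0)))


def auc_ci_bootstrap(
    data: BiomarkerDataset,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
    direction: str = GREATER,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap interval for the empirical AUC."""
    pos, neg = _oriented(data, direction)
    if pos.size < 2 or neg.size < 2:
        raise InsufficientDataError("bootstrap needs at least 2 observations per class")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        p = rng.choice(pos, size=pos.size, replace=True)
        q = rng.choice(neg, size=neg.size, replace=True)
        aucs[b], _ = _delong_variance(p, q)  # rank formula, variance unused
    lo, hi = np.quantile(aucs, [(1 - level) / 2.0, 0.5 + level / 2.0])
    return float(lo), float(hi)


def _oriented(data: BiomarkerDataset, direction: str):
    """Positive/negative marker arrays with larger meaning 'more positive'."""
    pos, neg = data.positives, data.negatives
    if direction == LESS:
        return -pos, -neg
    if direction == GREATER:
        return pos, neg
    raise ValueError(f"unknown direction {direction!r}")


def build_roc(
    data: BiomarkerDataset,
    direction: str | None = None,
    ci_level: float = 0.95,
    ci_method: str = "delong",
) -> ROCCurve:
    """Build the empirical ROC curve of ``data``.

    When ``direction`` is not given it is auto-detected as the orientation
    giving AUC >= 0.5 (the detected choice is recorded on the curve).
    """
    pos, neg = data.positives, data.negatives
    if pos.size == 0 or neg.size == 0:
        raise DegenerateDataError(
            "ROC analysis needs both classes non-empty "
            f"(got {pos.size} positive, {neg.size} negative)"
        )
    thr = candidate_thresholds(data.marker)

    if direction is None:
        sens_g, spec_g = _operating_points(pos, neg, thr, GREATER)
        auc_g = _trapezoid_auc(sens_g, spec_g)
        direction = GREATER if auc_g >= 0.5 else LESS

    sens, spec = _operating_points(pos, neg, thr, direction)
    auc = _trapezoid_auc(sens, spec)

    if pos.size >= 2 and neg.size >= 2:
        if ci_method == "delong":
            lo, hi = auc_ci_delong(data, level=ci_level, direction=direction)
        elif ci_method == "bootstrap":
            lo, hi = auc_ci_bootstrap(data, level=ci_level, direction=direction)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    else:
        lo, hi = 0.0, 1.0  # a singleton class cannot support a variance estimate

    return ROCCurve(
        thresholds=thr,
        sensitivities=sens,
        specificities=spec,
        direction=direction,
        auc=auc,
        auc_ci_lower=lo,
        auc_ci_upper=hi,
        ci_level=ci_level,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
        ci_method=ci_method,
    )


def plot_roc(curve: ROCCurve, path, highlight_threshold: float | None = None):
    """Write the ROC plot: specificity on a reversed x-axis, sensitivity on y.

    The operating point closest to ``highlight_threshold`` is marked with a
    red dot (the selected optimum).  The output format follows the file
    extension; pass a list of paths to write several formats.
    """
    from matplotlib.figure import Figure

    fig = Figure(figsize=(5, 5))
    ax = fig.add_subplot(111)
    order = np.argsort(curve.thresholds)
    spec = curve.specificities[order]
    sens = curve.sensitivities[order]
    ax.plot(spec, sens, color="#1f77b4", lw=1.5)
    ax.plot([1, 0], [0, 1], color="grey", lw=0.8, ls="--")
    if highlight_threshold is not None:
        i = int(np.nanargmin(np.abs(curve.thresholds - highlight_threshold)))
        ax.plot(
            curve.specificities[i], curve.sensitivities[i],
            "o", color="red", ms=8, zorder=5,
        )
        ax.annotate(
            f"c = {curve.thresholds[i]:.3f}",
            (curve.specificities[i], curve.sensitivities[i]),
            textcoords="offset points", xytext=(8, -12), fontsize=9,
        )
    ax.set_xlim(1.02, -0.02)  # reversed: specificity 1 at the left
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("Specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(f"ROC curve (AUC = {curve.auc:.4f})")
    paths = [path] if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__") else list(path)
    for p in paths:
        fig.savefig(p, dpi=150, bbox_inches="tight")
    return paths
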