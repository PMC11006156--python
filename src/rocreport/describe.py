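"""Descriptive statistics and the Distribution / Class Distribution figures.

Summaries use the sample standard deviation (n - 1 denominator),
linear-interpolation quartiles and Tukey 1.5 * IQR whiskers.  Density
overlays use a Gaussian kernel with Silverman's bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cutpoints import marker_mode
from .data_io import BiomarkerDataset
from .errors import DegenerateDataError, InsufficientDataError


@dataclass
class MarkerSummary:
    mean: float
    sd: float
    median: float
    mode: float
    minimum: float
    maximum: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean, "sd": self.sd, "median": self.median,
            "mode": self.mode, "min": self.minimum, "max": self.maximum,
            "n": self.n,
        }


@dataclass
class ClassSummary:
    """Per-class boxplot statistics for one original outcome label."""

    label: str
    mean: float
    minimum: float
    maximum: float
    n: int
    q1: float
    q2: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]

    def to_dict(self) -> dict:
        return {
            "label": self.label, "mean": self.mean, "min": self.minimum,
            "max": self.maximum, "n": self.n,
            "quartiles": [self.q1, self.q2, self.q3],
            "whiskers": [self.whisker_low, self.whisker_high],
            "outliers": self.outliers,
        }


def summarize_marker(data: BiomarkerDataset) -> MarkerSummary:
    """Pooled-marker descriptives: mean, sd (n-1), median, mode, range."""
    x = data.marker
    if x.size < 2:
        raise InsufficientDataError("need at least 2 observations")
    return MarkerSummary(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        median=float(np.median(x)),
        mode=marker_mode(x),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        n=int(x.size),
    )


def _class_summary(x: np.ndarray, label: str) -> ClassSummary:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return ClassSummary(
        label=label,
        mean=float(np.mean(x)),
        minimum=float(np.min(x)),
        maximum=float(np.max(x)),
        n=int(x.size),
        q1=float(q1), q2=float(q2), q3=float(q3),
        whisker_low=float(np.min(inside)),
        whisker_high=float(np.max(inside)),
        outliers=sorted(float(v) for v in x[(x < lo_fence) | (x > hi_fence)]),
    )


def summarize_classes(data: BiomarkerDataset) -> tuple[ClassSummary, ClassSummary]:
    """(negative-class, positive-class) boxplot summaries."""
    neg, pos = data.negatives, data.positives
    if neg.size == 0 or pos.size == 0:
        raise DegenerateDataError("both classes must be non-empty")
    return (
        _class_summary(neg, data.negative_label),
        _class_summary(pos, data.positive_label),
    )


def _kde(x: np.ndarray):
    return stats.gaussian_kde(x, bw_method="silverman")


def class_densities(data: BiomarkerDataset, gridsize: int = 512):
    """Per-class Silverman-KDE densities on a shared grid.

    Returns (grid, negative density, positive density); the element-wise
    minimum integrates to the density overlap between the classes.
    """
    x = data.marker
    pad = 0.1 * (x.max() - x.min() + 1e-12)
    grid = np.linspace(x.min() - pad, x.max() + pad, gridsize)
    return grid, _kde(data.negatives)(grid), _kde(data.positives)(grid)


def density_overlap(data: BiomarkerDataset, gridsize: int = 512) -> float:
    """Integral of min(f_neg, f_pos): 0 = disjoint classes, 1 = identical."""
    grid, f_neg, f_pos = class_densities(data, gridsize)
    return float(np.trapezoid(np.minimum(f_neg, f_pos), grid))


def render_distribution_figure(data: BiomarkerDataset, summary: MarkerSummary, path):
    """Histogram of the pooled marker with a red density curve overlaid."""
    from matplotlib.figure import Figure

    x = data.marker
    fig = Figure(figsize=(6, 4))
    ax = fig.add_subplot(111)
    ax.hist(x, bins="fd", density=True, color="#9ecae1", edgecolor="white")
    grid = np.linspace(x.min(), x.max(), 512)
    ax.plot(grid, _kde(x)(grid), color="red", lw=1.8)
    ax.axvline(summary.mean, color="black", lw=0.8, ls=":")
    ax.set_xlabel(data.marker_name)
    ax.set_ylabel("Density")
    ax.set_title(
        f"{data.marker_name}: mean {summary.mean:.2f}, "
        f"sd {summary.sd:.2f}, median {summary.median:.2f}"
    )
    paths = [path] if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__") else list(path)
    for p in paths:
        fig.savefig(p, dpi=150, bbox_inches="tight")
    return paths


def render_class_figure(
    data: BiomarkerDataset,
    summaries: tuple[ClassSummary, ClassSummary],
    path,
):
    """Boxplots per class (top) and overlaid class densities (bottom)."""
    from matplotlib.figure import Figure

    neg_s, pos_s = summaries
    fig = Figure(figsize=(6, 7))
    ax1 = fig.add_subplot(211)
    ax1.boxplot(
        [data.negatives, data.positives],
        tick_labels=[neg_s.label, pos_s.label],
        whis=1.5,
    )
    ax1.set_ylabel(data.marker_name)
    ax1.set_title(f"{data.marker_name} by {data.outcome_name} class")

    ax2 = fig.add_subplot(212)
    grid, f_neg, f_pos = class_densities(data)
    ax2.plot(grid, f_neg, label=neg_s.label, color="#1f77b4")
    ax2.plot(grid, f_pos, label=pos_s.label, color="#d62728")
    ax2.fill_between(grid, np.minimum(f_neg, f_pos), color="grey", alpha=0.3)
    ax2.set_xlabel(data.marker_name)
    ax2.set_ylabel("Density")
    ax2.legend()
    paths = [path] if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__") else list(path)
    for p in paths:
        fig.savefig(p, dpi=150, bbox_inches="tight")
    return paths
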