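"""End-to-end analysis: data -> curve -> cutoff -> performance -> report inputs.

``run_analysis`` accepts the selector vocabulary of the tool's method
menu: ``youden_topleft`` (with index ``youden`` or ``closest.topleft``),
``cutoff`` (manual value), ``maximized`` (constrained metric + bound) and
``min_pvalue_approach``; the biomarker-oriented statistics ``mean`` /
``median`` / ``mode`` are accepted as methods too.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import cutpoints as cp
from .data_io import BiomarkerDataset
from .describe import (
    ClassSummary,
    MarkerSummary,
    summarize_classes,
    summarize_marker,
)
from .metrics import PerformanceTable, performance_row
from .roc import ROCCurve, build_roc

METHODS = ("youden_topleft", "cutoff", "maximized", "min_pvalue_approach",
           "mean", "median", "mode")
INDICES = ("youden", "closest.topleft")


@dataclass
class AnalysisResult:
    data: BiomarkerDataset
    curve: ROCCurve
    cutpoint: cp.CutpointResult
    table: PerformanceTable
    marker_summary: MarkerSummary
    class_summaries: tuple[ClassSummary, ClassSummary]


def run_analysis(
    data: BiomarkerDataset,
    method: str = "youden_topleft",
    index: str = "youden",
    cutoff_value: float | None = None,
    constrain_metric: str | None = None,
    min_constraint: float | None = None,
    direction: str | None = None,
    ci_level: float = 0.95,
    ci_method: str = "delong",
) -> AnalysisResult:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid methods: {METHODS}")
    curve = build_roc(data, direction=direction, ci_level=ci_level,
                      ci_method=ci_method)
    if method == "youden_topleft":
        if index not in INDICES:
            raise ValueError(f"unknown index {index!r}; valid indices: {INDICES}")
        cut = cp.youden(curve) if index == "youden" else cp.closest_topleft(curve)
    elif method == "cutoff":
        if cutoff_value is None:
            raise ValueError("method 'cutoff' requires cutoff_value")
        cut = cp.manual_cutoff(data, cutoff_value)
    elif method == "maximized":
        if constrain_metric is None or min_constraint is None:
            raise ValueError(
                "method 'maximized' requires constrain_metric and min_constraint"
            )
        cut = cp.constrained_max(curve, constrain_metric, min_constraint)
    elif method == "min_pvalue_approach":
        cut = cp.min_pvalue(data, direction=curve.direction)
    else:  # mean / median / mode
        cut = cp.biomarker_oriented(data, method)
    table = performance_row(data, cut, curve)
    return AnalysisResult(
        data=data,
        curve=curve,
        cutpoint=cut,
        table=table,
        marker_summary=summarize_marker(data),
        class_summaries=summarize_classes(data),
    )


def prompt_context(result: AnalysisResult) -> dict:
    """Placeholder values for the report prompts.

    Rates and thresholds are rounded to 3 decimals (prose precision); the
    AUC to 4.  Values equal the performance-table / summary values after
    this documented rounding — nothing is recomputed.
    """
    t = result.table
    s = result.marker_summary
    neg_s, pos_s = result.class_summaries
    r3 = lambda v: "NA" if v is None else round(v, 3)
    return {
        "marker": result.data.marker_name,
        "outcome": result.data.outcome_name,
        "auc": round(t.auc, 4),
        "threshold": r3(t.threshold),
        "sensitivity": r3(t.sensitivity),
        "specificity": r3(t.specificity),
        "ppv": r3(t.ppv),
        "npv": r3(t.npv),
        "accuracy": r3(t.accuracy),
        "ci_lower": r3(t.ci_lower),
        "ci_upper": r3(t.ci_upper),
        "mean": r3(s.mean),
        "sd": r3(s.sd),
        "median": r3(s.median),
        "mode": r3(s.mode),
        "minimum": r3(s.minimum),
        "maximum": r3(s.maximum),
        "pos_label": result.data.positive_label,
        "neg_label": result.data.negative_label,
        "pos_mean": r3(pos_s.mean),
        "pos_min": r3(pos_s.minimum),
        "pos_max": r3(pos_s.maximum),
        "neg_mean": r3(neg_s.mean),
        "neg_min": r3(neg_s.minimum),
        "neg_max": r3(neg_s.maximum),
    }
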