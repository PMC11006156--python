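"""Confusion matrices and the diagnostic performance table.

A positive call is ``marker > c`` under ``greater_is_positive`` (strict:
equality at a manual threshold is classified negative; candidate midpoint
thresholds can never equal an observed value) and ``marker < c`` under
``less_is_positive``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cutpoints import CutpointResult
from .data_io import BiomarkerDataset
from .roc import GREATER, LESS, ROCCurve


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_positive

    @property
    def specificity(self) -> float:
        return self.tn / self.n_negative

    @property
    def ppv(self) -> float | None:
        """Positive predictive value; None when nothing is called positive."""
        called = self.tp + self.fp
        return None if called == 0 else self.tp / called

    @property
    def npv(self) -> float | None:
        called = self.tn + self.fn
        return None if called == 0 else self.tn / called

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


@dataclass
class PerformanceTable:
    """One row of the Table panel: threshold, rates, predictive values, AUC."""

    threshold: float
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    accuracy: float
    auc: float
    ci_lower: float
    ci_upper: float

    _FIELDS = (
        "threshold", "sensitivity", "specificity", "ppv", "npv",
        "accuracy", "auc", "ci_lower", "ci_upper",
    )

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in self._FIELDS}

    def rounded(self, ndigits: int = 2) -> dict:
        """Rendered values at table precision; unavailable entries -> 'NA'."""
        out = {}
        for f in self._FIELDS:
            v = getattr(self, f)
            out[f] = "NA" if v is None else round(v, ndigits)
        return out

    def render_text(self, ndigits: int = 2) -> str:
        """The aligned Table panel row."""
        headers = ["Threshold", "Sensitivity", "Specificity", "PPV", "NPV",
                   "Accuracy", "AUC", "CI:LB", "CI:UB"]
        vals = [str(v) for v in self.rounded(ndigits).values()]
        widths = [max(len(h), len(v)) for h, v in zip(headers, vals)]
        head = "  ".join(h.ljust(w) for h, w in zip(headers, widths))
        row = "  ".join(v.ljust(w) for v, w in zip(vals, widths))
        return head + "\n" + row

    def to_csv_row(self) -> str:
        return ",".join(
            "NA" if getattr(self, f) is None else repr(float(getattr(self, f)))
            for f in self._FIELDS
        )


def confusion_at(
    data: BiomarkerDataset, threshold: float, direction: str = GREATER
) -> ConfusionMatrix:
    """Cross-classify predictions at ``threshold`` against the true classes."""
    x = data.marker
    if direction == GREATER:
        called = x > threshold
    elif direction == LESS:
        called = x < threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    pos = data.outcome == 1
    return ConfusionMatrix(
        tp=int(np.sum(called & pos)),
        fp=int(np.sum(called & ~pos)),
        tn=int(np.sum(~called & ~pos)),
        fn=int(np.sum(~called & pos)),
    )


def table_from_confusion(
    cm: ConfusionMatrix, threshold: float, auc: float,
    ci_lower: float, ci_upper: float,
) -> PerformanceTable:
    return PerformanceTable(
        threshold=float(threshold),
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        ppv=cm.ppv,
        npv=cm.npv,
        accuracy=cm.accuracy,
        auc=float(auc),
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
    )


def performance_row(
    data: BiomarkerDataset, cut: CutpointResult, curve: ROCCurve
) -> PerformanceTable:
    """The full performance row at the selected cutoff.

    Rates are recomputed from the confusion matrix at the threshold; the
    AUC and its interval are copied from the curve.
    """
    cm = confusion_at(data, cut.threshold, direction=curve.direction)
    return table_from_confusion(
        cm, cut.threshold, curve.auc, curve.auc_ci_lower, curve.auc_ci_upper
    )
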