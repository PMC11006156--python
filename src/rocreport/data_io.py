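"""Reading, validating and previewing biomarker/outcome tables.

Input is an RFC-4180-style comma-separated file (UTF-8, mandatory header
row) holding one continuous biomarker column and one binary outcome
column.  Rows with a missing marker or outcome are dropped whole (and
counted); the preview's missing-data percentage is cell-based because it
describes the raw table, not the analysis subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ColumnNotFoundError,
    EmptyInputError,
    MarkerParseError,
    OutcomeCardinalityError,
)

#: Tokens treated as missing (case-insensitive, surrounding blanks ignored).
MISSING_TOKENS = frozenset({"", "na", "nan"})


def _is_missing(token: str) -> bool:
    return token.strip().lower() in MISSING_TOKENS


@dataclass
class BiomarkerDataset:
    """Validated (marker, outcome) pairs ready for ROC analysis.

    ``outcome`` is encoded 0 = negative/control, 1 = positive/case;
    ``positive_label`` / ``negative_label`` keep the original label text.
    """

    marker_name: str
    outcome_name: str
    marker: np.ndarray
    outcome: np.ndarray
    positive_label: str
    negative_label: str
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        if self.marker.shape != self.outcome.shape:
            raise ValueError("marker and outcome must be parallel sequences")
        if self.marker.size < 2:
            raise ValueError("need at least 2 observations after missing-value removal")
        if not set(np.unique(self.outcome)) <= {0, 1}:
            raise ValueError("outcome must be encoded 0/1")

    @property
    def n_total(self) -> int:
        return int(self.marker.size)

    @property
    def n_positive(self) -> int:
        return int(self.outcome.sum())

    @property
    def n_negative(self) -> int:
        return int(self.n_total - self.outcome.sum())

    @property
    def positives(self) -> np.ndarray:
        return self.marker[self.outcome == 1]

    @property
    def negatives(self) -> np.ndarray:
        return self.marker[self.outcome == 0]

    def to_frame(self) -> pd.DataFrame:
        labels = np.where(self.outcome == 1, self.positive_label, self.negative_label)
        return pd.DataFrame({self.marker_name: self.marker, self.outcome_name: labels})

    def to_csv(self, path) -> None:
        """Write back to the standard CSV layout (original label text)."""
        self.to_frame().to_csv(path, index=False)


@dataclass
class DataPreview:
    """The Data Preview panel quantities: head/tail rows and missingness."""

    columns: list[str]
    head_rows: list[list[str]]
    tail_rows: list[list[str]]
    n_observations: int
    n_labels: int
    missing_pct: float

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "head_rows": self.head_rows,
            "tail_rows": self.tail_rows,
            "n_observations": self.n_observations,
            "n_labels": self.n_labels,
            "missing_pct": self.missing_pct,
        }


def _read_raw(path) -> pd.DataFrame:
    """Read the CSV as strings so missing-token handling is explicit."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, sep=",")
    return df


def read_dataset(
    path,
    marker_column: str,
    outcome_column: str,
    positive_label: str | None = None,
) -> BiomarkerDataset:
    """Read and validate a biomarker/outcome CSV.

    Rows with a missing marker or outcome cell are dropped and counted in
    ``n_dropped_missing``.  The outcome must have exactly two distinct
    labels after dropping; they are encoded to {0, 1}.  If
    ``positive_label`` is not given, label "1" is positive when the labels
    are {0, 1}, otherwise the lexicographically larger label.
    """
    df = _read_raw(path)
    if df.shape[0] == 0:
        raise EmptyInputError(f"no data rows in {path}")
    for col in (marker_column, outcome_column):
        if col not in df.columns:
            raise ColumnNotFoundError(
                f"column {col!r} not found; available: {list(df.columns)}"
            )

    markers: list[float] = []
    labels: list[str] = []
    n_dropped = 0
    for i, (m_tok, o_tok) in enumerate(
        zip(df[marker_column].tolist(), df[outcome_column].tolist())
    ):
        if _is_missing(m_tok) or _is_missing(o_tok):
            n_dropped += 1
            continue
        try:
            markers.append(float(m_tok))
        except ValueError:
            # data row i is line i+2 of the file (header is line 1)
            raise MarkerParseError(
                f"non-numeric marker value {m_tok!r} in data row {i + 1} "
                f"(file line {i + 2})"
            ) from None
        labels.append(o_tok.strip())

    distinct = sorted(set(labels))
    if len(distinct) != 2:
        raise OutcomeCardinalityError(
            f"outcome column {outcome_column!r} has {len(distinct)} distinct "
            f"label(s) after dropping missing rows ({distinct}); exactly 2 required"
        )

    if positive_label is None:
        positive_label = "1" if set(distinct) == {"0", "1"} else distinct[-1]
    else:
        positive_label = str(positive_label)
        if positive_label not in distinct:
            raise OutcomeCardinalityError(
                f"positive_label {positive_label!r} not among observed labels {distinct}"
            )
    negative_label = next(l for l in distinct if l != positive_label)

    outcome = np.array([1 if l == positive_label else 0 for l in labels], dtype=int)
    return BiomarkerDataset(
        marker_name=marker_column,
        outcome_name=outcome_column,
        marker=np.array(markers, dtype=float),
        outcome=outcome,
        positive_label=positive_label,
        negative_label=negative_label,
        n_dropped_missing=n_dropped,
    )


def from_arrays(
    marker,
    outcome,
    marker_name: str = "marker",
    outcome_name: str = "outcome",
    positive_label: str = "1",
    negative_label: str = "0",
) -> BiomarkerDataset:
    """Build a dataset directly from numeric arrays (outcome already 0/1)."""
    return BiomarkerDataset(
        marker_name=marker_name,
        outcome_name=outcome_name,
        marker=np.asarray(marker, dtype=float),
        outcome=np.asarray(outcome, dtype=int),
        positive_label=positive_label,
        negative_label=negative_label,
    )


def preview(path, outcome_column: str | None = None) -> DataPreview:
    """Summarize a raw CSV: first/last 4 rows, counts and missing percentage.

    ``missing_pct`` is 100 x (missing cells) / (total cells) over the whole
    table.  ``n_labels`` counts distinct non-missing values of
    ``outcome_column`` (the last column when not given).  Files with fewer
    than 8 rows yield overlapping head/tail slices.
    """
    df = _read_raw(path)
    if df.shape[0] == 0:
        raise EmptyInputError(f"no data rows in {path}")

    missing = df.map(_is_missing)
    missing_pct = 100.0 * float(missing.to_numpy().sum()) / float(df.size)

    out_col = outcome_column if outcome_column is not None else df.columns[-1]
    if out_col not in df.columns:
        raise ColumnNotFoundError(f"column {out_col!r} not found")
    out_vals = [v.strip() for v in df[out_col].tolist() if not _is_missing(v)]
    n_labels = len(set(out_vals))

    rows = df.to_numpy().tolist()
    return DataPreview(
        columns=list(df.columns),
        head_rows=[list(map(str, r)) for r in rows[:4]],
        tail_rows=[list(map(str, r)) for r in rows[-4:]],
        n_observations=int(df.shape[0]),
        n_labels=n_labels,
        missing_pct=missing_pct,
    )
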