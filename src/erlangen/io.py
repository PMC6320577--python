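"""Cohort CSV schema, validated reading/writing, and cohort scoring.

A single CSV schema serves both real-format and synthetic data: one row per
subject, UTF-8, comma-separated, empty field = missing.  Scoring appends the
columns ``amyloid_severity``, ``tau_severity``, ``es_score``,
``es_category5`` and ``es_category3``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import BiomarkerPanel, ReferencePanel, ScoringError

__all__ = [
    "COHORT_COLUMNS",
    "SCORE_COLUMNS",
    "CohortReadResult",
    "CohortFormatError",
    "read_cohort_csv",
    "write_cohort_csv",
    "score_cohort",
]

COHORT_COLUMNS = [
    "id", "group", "age", "female", "apoe4", "mmse",
    "abeta42", "abeta40", "abeta42_40_ratio", "tau", "ptau181",
    "followup_years", "event",
]
SCORE_COLUMNS = ["amyloid_severity", "tau_severity", "es_score",
                 "es_category5", "es_category3"]

_FLOAT_COLS = ["age", "female", "apoe4", "mmse", "abeta42", "abeta40",
               "abeta42_40_ratio", "tau", "ptau181", "followup_years", "event"]
_POSITIVE_COLS = ["abeta42", "abeta40", "abeta42_40_ratio", "tau", "ptau181"]


class CohortFormatError(ValueError):
    """Malformed cohort file (header, duplicate ids)."""


@dataclass
class CohortReadResult:
    """Validated cohort rows plus the per-row rejection report."""

    frame: pd.DataFrame
    errors: list[tuple[int, str]]   # (1-based data line number, reason)


def read_cohort_csv(path) -> CohortReadResult:
    """Read and validate a cohort CSV.

    A malformed header or duplicate subject ids abort with
    :class:`CohortFormatError`; invalid cells reject only their row, and
    every rejection is reported with its data line number.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != COHORT_COLUMNS:
        raise CohortFormatError(
            f"header mismatch: expected {COHORT_COLUMNS}, got {list(raw.columns)}"
        )
    errors: list[tuple[int, str]] = []
    rows = []
    for pos, row in enumerate(raw.itertuples(index=False), start=1):
        parsed = {"id": row.id, "group": row.group or None}
        bad = None
        if not row.id:
            bad = "missing id"
        for col in _FLOAT_COLS:
            cell = getattr(row, col)
            if cell == "":
                parsed[col] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                bad = bad or f"unparseable {col}: {cell!r}"
                continue
            if col in _POSITIVE_COLS and not v > 0:
                bad = bad or f"non-positive concentration {col}: {cell}"
            elif col == "followup_years" and not v > 0:
                bad = bad or f"non-positive followup_years: {cell}"
            elif col in ("female", "apoe4", "event") and v not in (0.0, 1.0):
                bad = bad or f"{col} must be 0/1: {cell}"
            parsed[col] = v
        if bad:
            errors.append((pos, bad))
        else:
            rows.append(parsed)
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if frame["id"].duplicated().any():
        dupes = frame.loc[frame["id"].duplicated(), "id"].unique().tolist()
        raise CohortFormatError(f"duplicate subject ids: {dupes}")
    return CohortReadResult(frame, errors)


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    """Write a cohort (or scored cohort) CSV; missing values become empty fields."""
    cols = COHORT_COLUMNS + [c for c in SCORE_COLUMNS if c in frame.columns]
    out = frame.reindex(columns=cols)
    out.to_csv(path, index=False, na_rep="")


def score_cohort(frame: pd.DataFrame, refs: ReferencePanel | None = None
                 ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Score every subject; returns the augmented frame and unscoreable ids.

    Unscoreable subjects (a whole biomarker group missing) keep their row
    with empty score columns and are reported as ``(id, reason)`` pairs.
    """
    if refs is None:
        refs = ReferencePanel.default()
    from .scoring import erlangen_score

    out = frame.copy()
    cols = {c: [] for c in SCORE_COLUMNS}
    failures: list[tuple[str, str]] = []
    marker_cols = ["abeta42", "abeta40", "abeta42_40_ratio", "tau", "ptau181"]
    values = frame[marker_cols].to_numpy(dtype=float)
    ids = frame["id"].astype(str).tolist()
    for i in range(len(frame)):
        try:
            panel = BiomarkerPanel(**{
                c: (None if np.isnan(v) else float(v))
                for c, v in zip(marker_cols, values[i])
            })
            res = erlangen_score(panel, refs)
        except ScoringError as exc:
            failures.append((ids[i], str(exc)))
            for c in SCORE_COLUMNS:
                cols[c].append(np.nan)
            continue
        cols["amyloid_severity"].append(res.amyloid_severity)
        cols["tau_severity"].append(res.tau_severity)
        cols["es_score"].append(res.score)
        cols["es_category5"].append(res.category5)
        cols["es_category3"].append(res.category3)
    for c in SCORE_COLUMNS:
        out[c] = cols[c]
    return out, failures
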