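"""Dermatologists' subjective severity scoring.

Each photo is scored by one or more raters on five parameters — color,
distribution, depth, elasticity, roughness — with 0 (normal skin) to 3
(obvious striae) points per parameter.  A rater's sum therefore lies in
[0, 15].  The average of the per-rater sums maps to a severity category:

====================  ==========
average of sum        category
====================  ==========
<= 1                  invalid
(1, 5)                mild
[5, 10)               moderate
[10, 15]              severe
====================  ==========

The printed integer bands (1-4 / 5-9 / 10-15) are closed over integers;
fractional averages fall in the half-open intervals above, which preserves
every integer assignment while keeping values such as 4.5 well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "PARAMETERS",
    "ScoreSheet",
    "SubjectiveResult",
    "rater_sum",
    "categorize",
    "aggregate",
    "aggregate_sums",
    "read_score_sheets",
    "score_results_frame",
]

PARAMETERS = ("color", "distribution", "depth", "elasticity", "roughness")

CATEGORY_INVALID = "invalid"
CATEGORY_MILD = "mild"
CATEGORY_MODERATE = "moderate"
CATEGORY_SEVERE = "severe"


@dataclass(frozen=True)
class ScoreSheet:
    """All raters' five-parameter scores for one photo."""

    photo_id: str
    scores: Mapping[str, tuple[int, int, int, int, int]]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("a score sheet needs at least one rater")
        for rater, vals in self.scores.items():
            rater_sum(vals)  # validates arity and range


@dataclass(frozen=True)
class SubjectiveResult:
    photo_id: str
    rater_sums: Mapping[str, int]
    average_of_sum: float
    category: str

    @property
    def average_display(self) -> float:
        """The average rounded to 2 decimals, as printed on report sheets."""
        return round(self.average_of_sum, 2)


def rater_sum(scores: Sequence[int]) -> int:
    """Sum of one rater's five parameter scores, each in {0, 1, 2, 3}."""
    if len(scores) != len(PARAMETERS):
        raise ValueError(f"expected {len(PARAMETERS)} scores, got {len(scores)}")
    out = 0
    for name, s in zip(PARAMETERS, scores):
        if int(s) != s or not 0 <= int(s) <= 3:
            raise ValueError(f"score for {name!r} must be an integer in 0..3, got {s}")
        out += int(s)
    return out


def categorize(average_of_sum: float) -> str:
    """Severity category of an average-of-sum value in [0, 15]."""
    v = float(average_of_sum)
    if not 0.0 <= v <= 15.0:
        raise ValueError(f"average of sum must lie in [0, 15], got {v}")
    if v <= 1.0:
        return CATEGORY_INVALID
    if v < 5.0:
        return CATEGORY_MILD
    if v < 10.0:
        return CATEGORY_MODERATE
    return CATEGORY_SEVERE


def aggregate_sums(photo_id: str, sums: Mapping[str, int]) -> SubjectiveResult:
    """Aggregate pre-computed per-rater sums into a subjective result."""
    if not sums:
        raise ValueError("need at least one rater sum")
    for rater, s in sums.items():
        if not 0 <= s <= 15:
            raise ValueError(f"rater {rater!r} sum {s} outside [0, 15]")
    avg = sum(sums.values()) / len(sums)
    return SubjectiveResult(
        photo_id=photo_id,
        rater_sums=dict(sums),
        average_of_sum=avg,
        category=categorize(avg),
    )


def aggregate(sheet: ScoreSheet) -> SubjectiveResult:
    """Per-rater sums, average of sum and severity category of one sheet."""
    return aggregate_sums(
        sheet.photo_id, {rater: rater_sum(vals) for rater, vals in sheet.scores.items()}
    )


def read_score_sheets(path) -> list[ScoreSheet]:
    """Read a score-sheet CSV: photo_id,rater_id,color,distribution,depth,elasticity,roughness.

    Malformed rows are reported with their line numbers (header = line 1).
    """
    df = pd.read_csv(path, dtype={"photo_id": str, "rater_id": str})
    missing = [c for c in ("photo_id", "rater_id", *PARAMETERS) if c not in df.columns]
    if missing:
        raise ValueError(f"score-sheet CSV missing columns: {missing}")
    if df.empty:
        raise ValueError(f"score-sheet CSV is empty: {path}")
    errors = []
    sheets: dict[str, dict[str, tuple[int, ...]]] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            vals = tuple(int(row[p]) for p in PARAMETERS)
            rater_sum(vals)
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        sheets.setdefault(str(row["photo_id"]), {})[str(row["rater_id"])] = vals
    if errors:
        raise ValueError("malformed score-sheet rows:\n" + "\n".join(errors))
    return [ScoreSheet(photo_id=pid, scores=raters) for pid, raters in sheets.items()]


def score_results_frame(sheets: Sequence[ScoreSheet]) -> pd.DataFrame:
    """Results table (photo_id, avg_of_sum, category) for a batch of sheets."""
    rows = []
    for sheet in sheets:
        res = aggregate(sheet)
        rows.append(
            {"photo_id": res.photo_id, "avg_of_sum": res.average_display,
             "category": res.category}
        )
    return pd.DataFrame(rows)
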