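"""Scoring of the Satisfaction With Life Scale (SWLS).

The SWLS is a five-item measure of global life satisfaction; each item is
answered on a 7-point agreement scale (1 = strongly disagree … 7 = strongly
agree) and the total score is the plain sum, ranging 5-35.  A modified
four-item form drops the fifth item ("If I could live my life over, I would
change almost nothing"), which performs poorly in traumatic-injury
populations.  This module implements both forms:

* the *directly derived* score — the ordinary 5-item sum,
* the *prorated* score — the 4-item sum plus the 4-item mean, i.e.
  ``1.25 × sum4``, which expresses a 4-item administration on the 5-item
  metric, at the individual or at the group level,
* the published category cutoffs for interpreting a 5-35 score, and
* the static 25-row crosswalk from every possible 4-item sum to its
  5-item equivalent.

Prorated scores are quarter-point multiples; ``1.25 × integer`` is exact in
binary floating point, so plain floats carry them without rounding error.
Rounding to one decimal is applied only when formatting for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "LIKERT_MIN",
    "LIKERT_MAX",
    "SCALE_MIN",
    "SCALE_MAX",
    "PRORATION_FACTOR",
    "CATEGORIES",
    "Category",
    "ItemResponses",
    "ScorePair",
    "validate_responses",
    "sum4",
    "direct_score",
    "prorated_score",
    "score_pair",
    "group_prorated_mean",
    "classify",
    "crosswalk_table",
]

LIKERT_MIN = 1
LIKERT_MAX = 7
SCALE_MIN = 5
SCALE_MAX = 35
#: A 4-item sum times this factor lands on the 5-item metric
#: (sum4 + sum4/4 = 1.25 * sum4).
PRORATION_FACTOR = 1.25


@dataclass(frozen=True)
class Category:
    """One interpretive satisfaction band for a 5-35 SWLS score.

    ``lo``/``hi`` give the half-open interval [lo, hi) covered by the band
    (the top band is closed at 35).  The published cutoffs are stated for
    integer scores (31-35, 26-30, 20-25, 15-19, 10-14, 5-9); the half-open
    extension assigns fractional prorated scores in the gaps (e.g. 25.5) to
    the band below, while every integer keeps its published assignment.
    """

    ordinal_rank: int
    label: str
    lo: float
    hi: float

    def __contains__(self, score: float) -> bool:
        if self.ordinal_rank == len(CATEGORIES):
            return self.lo <= score <= self.hi
        return self.lo <= score < self.hi


CATEGORIES: tuple[Category, ...] = (
    Category(1, "extremely dissatisfied", 5, 10),
    Category(2, "dissatisfied", 10, 15),
    Category(3, "slightly dissatisfied", 15, 20),
    Category(4, "neutral or slightly satisfied", 20, 26),
    Category(5, "satisfied", 26, 31),
    Category(6, "extremely satisfied", 31, 35),
)


@dataclass(frozen=True)
class ItemResponses:
    """A single respondent's validated SWLS item answers (4 or 5 items)."""

    items: tuple[int, ...]

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class ScorePair:
    """A respondent's directly derived and prorated scores side by side."""

    prorated_score: float
    sum4: int
    direct_score: int | None = None


def _check_entry(value, index: int) -> int:
    # bool is an Integral subclass; it is never a Likert response
    if isinstance(value, bool) or not isinstance(value, Integral):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"missing entry at index {index}")
        raise ValueError(f"non-integer entry at index {index}: {value!r}")
    value = int(value)
    if not LIKERT_MIN <= value <= LIKERT_MAX:
        raise ValueError(f"value out of range at index {index}: {value}")
    return value


def validate_responses(raw: Sequence) -> ItemResponses:
    """Validate a raw 4- or 5-entry response sequence.

    Entries must be integers in [1, 7]; nothing is coerced, and any
    missing, non-integer or out-of-range entry raises ``ValueError``
    naming the offending index.
    """
    raw = list(raw)
    if len(raw) not in (4, 5):
        raise ValueError(f"expected 4 or 5 items, got {len(raw)}")
    return ItemResponses(tuple(_check_entry(v, i) for i, v in enumerate(raw)))


def _as_responses(r: Union[ItemResponses, Sequence]) -> ItemResponses:
    return r if isinstance(r, ItemResponses) else validate_responses(r)


def sum4(r: Union[ItemResponses, Sequence]) -> int:
    """Sum of items 1-4 (item 5 of a 5-item record is ignored)."""
    r = _as_responses(r)
    return int(np.sum(r.items[:4]))


def direct_score(r: Union[ItemResponses, Sequence]) -> int:
    """Directly derived 5-item total: the plain sum, in [5, 35]."""
    r = _as_responses(r)
    if r.n_items != 5:
        raise ValueError(f"direct score requires 5 items, got {r.n_items}")
    return int(np.sum(r.items))


def prorated_score(r: Union[ItemResponses, Sequence]) -> float:
    """Prorated 5-item-metric score from items 1-4.

    Adds the mean of the four retained items to their sum, i.e. returns
    ``1.25 * sum4`` exactly.  A 5-item record uses its first four entries
    only; item 5 is never consulted.
    """
    return PRORATION_FACTOR * sum4(r)


def score_pair(r: Union[ItemResponses, Sequence]) -> ScorePair:
    """Both scores for one respondent; direct score absent for 4-item rows."""
    r = _as_responses(r)
    s4 = sum4(r)
    direct = int(np.sum(r.items)) if r.n_items == 5 else None
    return ScorePair(prorated_score=PRORATION_FACTOR * s4, sum4=s4, direct_score=direct)


def group_prorated_mean(sums4: Union[float, Iterable[float]]) -> float:
    """Group-level proration: 1.25 × the mean 4-item sum.

    Accepts either a collection of per-respondent 4-item sums or an
    already-computed group mean of the 4-item sum.  By linearity this equals
    the mean of the individual prorated scores.
    """
    if np.isscalar(sums4):
        mean4 = float(sums4)
    else:
        arr = np.asarray(list(sums4), dtype=float)
        if arr.size == 0:
            raise ValueError("empty input: group mean undefined")
        mean4 = float(arr.mean())
    return PRORATION_FACTOR * mean4


def classify(score: float) -> Category:
    """Satisfaction category for a score on the 5-item metric (5-35)."""
    if not SCALE_MIN <= score <= SCALE_MAX:
        raise ValueError(f"score {score} outside [{SCALE_MIN}, {SCALE_MAX}]")
    for cat in CATEGORIES:
        if score in cat:
            return cat
    raise AssertionError("category bands must partition [5, 35]")  # pragma: no cover


def crosswalk_table() -> pd.DataFrame:
    """Static 4-item → 5-item linking table.

    One row per possible 4-item sum (4…28) with the exact prorated
    equivalent, its one-decimal display form, and the satisfaction category.
    """
    rows = []
    for s4 in range(4, 29):
        exact = PRORATION_FACTOR * s4
        rows.append(
            {
                "sum4": s4,
                "prorated_exact": exact,
                "prorated_1dp": round(exact, 1),
                "category": classify(exact).label,
            }
        )
    return pd.DataFrame(rows)
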