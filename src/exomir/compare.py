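"""Two-library comparison: repertoire overlap, fold changes, qPCR arithmetic.

Counts are first normalized to reads-per-million against each library's
total, then expressed as a fold change (library B over library A).  A
feature is *up* when the fold exceeds the threshold (default 2), *down*
when it falls below the reciprocal, otherwise *unchanged*; a feature absent
from both libraries is flagged *absent*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .novel import NovelCandidate
from .quantify import normalize_rpm

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
ABSENT = "absent"


@dataclass(frozen=True)
class OverlapSummary:
    count_a_only: int
    count_b_only: int
    count_shared: int

    @property
    def size_a(self) -> int:
        return self.count_a_only + self.count_shared

    @property
    def size_b(self) -> int:
        return self.count_b_only + self.count_shared


@dataclass(frozen=True)
class ComparisonRow:
    feature_id: str
    norm_expr_a: float
    norm_expr_b: float
    fold_change: float  # b over a; math.inf when a = 0 and b > 0
    regulation: str


@dataclass(frozen=True)
class QpcrMeasurement:
    """Cycle thresholds for a target and its endogenous control."""

    target_id: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("cycle thresholds must be positive and finite")


def overlap_sets(ids_a: Iterable, ids_b: Iterable) -> OverlapSummary:
    """Exact set arithmetic over two feature repertoires."""
    a, b = set(ids_a), set(ids_b)
    shared = a & b
    return OverlapSummary(len(a - b), len(b - a), len(shared))


def fold_change(
    feature_id: str,
    count_a: int,
    total_a: int,
    count_b: int,
    total_b: int,
    threshold: float = 2.0,
) -> ComparisonRow:
    """RPM-normalized fold change of B over A with a regulation call."""
    if threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    rpm_a = normalize_rpm(count_a, total_a)
    rpm_b = normalize_rpm(count_b, total_b)
    if count_a == 0 and count_b == 0:
        return ComparisonRow(feature_id, rpm_a, rpm_b, math.nan, ABSENT)
    if count_a == 0:
        return ComparisonRow(feature_id, rpm_a, rpm_b, math.inf, UP)
    fold = rpm_b / rpm_a
    if fold > threshold:
        reg = UP
    elif fold < 1 / threshold:
        reg = DOWN
    else:
        reg = UNCHANGED
    return ComparisonRow(feature_id, rpm_a, rpm_b, fold, reg)


def candidate_count_rows(
    candidates: Sequence[NovelCandidate], library_a: str, library_b: str
) -> list[tuple[str, int, int]]:
    """(candidate_id, count_a, count_b) triples from novel candidates."""
    return [
        (c.candidate_id, c.counts.get(library_a, 0), c.counts.get(library_b, 0))
        for c in candidates
    ]


def classify_common_novel(
    rows: Iterable[tuple[str, int, int]],
    total_a: int,
    total_b: int,
    threshold: float = 2.0,
) -> tuple[int, int, int]:
    """Tally regulation classes over candidates detected in both libraries.

    ``rows`` are (feature_id, count_a, count_b) triples, one per candidate
    locus; multi-locus candidates carry one row per locus with identical
    counts and are tallied per locus, matching how per-locus candidate IDs
    are reported.  Rows with a zero count in either library are not part of
    the common set.  Returns (n_up, n_down, n_unchanged); the tally is
    invariant to row order.
    """
    n_up = n_down = n_unchanged = 0
    for feature_id, count_a, count_b in rows:
        if count_a <= 0 or count_b <= 0:
            continue
        row = fold_change(feature_id, count_a, total_a, count_b, total_b, threshold)
        if row.regulation == UP:
            n_up += 1
        elif row.regulation == DOWN:
            n_down += 1
        else:
            n_unchanged += 1
    return n_up, n_down, n_unchanged


def relative_expression(m: QpcrMeasurement) -> float:
    """2^-dCt relative quantification, dCt = Ct(target) - Ct(control)."""
    return 2.0 ** -(m.ct_target - m.ct_reference)
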