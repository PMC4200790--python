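"""Hierarchical small-RNA class annotation and composition summaries.

Each sequence tag is assigned to exactly one class by walking a priority
list: structured ncRNA contaminants first (rRNA, tRNA, snRNA), then known
miRNA precursors (via the tolerant isomiR matcher), then genomic repeats and
mRNA fragments; anything left is *unannotated* and feeds novel-miRNA
prediction.  Matching for the non-miRNA classes is exact sense-strand
substring containment in the packaged reference sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .preprocess import LibrarySummary, ReadTag, MAX_TAG_LENGTH, MIN_TAG_LENGTH
from .quantify import PrecursorRecord, align_to_precursor
from .util import percent

MIRNA_CLASS = "miRNA"
UNANNOTATED = "unannotated"
DEFAULT_PRIORITY = ("rRNA", "tRNA", "snRNA", MIRNA_CLASS, "repeat", "mRNA")

# Separator outside the DNA alphabet so substring search cannot straddle
# two concatenated reference sequences.
_SEP = "#"


@dataclass
class ClassIndex:
    """Substring index over class references plus the precursor set.

    ``class_refs`` maps class name -> list of (id, sequence); the miRNA
    class is served by the isomiR matcher over ``precursors`` instead of
    plain containment.
    """

    class_refs: Mapping[str, Sequence[tuple[str, str]]]
    precursors: Sequence[PrecursorRecord] = ()
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    max_shift: int = 4
    max_mismatches: int = 1
    _haystacks: dict[str, str] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        indexed = set(self.class_refs) | {MIRNA_CLASS}
        missing = [c for c in self.priority if c not in indexed]
        if missing:
            raise ValueError(f"priority names unindexed classes: {missing}")
        if len(set(self.priority)) != len(self.priority):
            raise ValueError("priority must list each class once")
        for cls, refs in self.class_refs.items():
            self._haystacks[cls] = _SEP + _SEP.join(seq for _, seq in refs) + _SEP

    def _matches(self, sequence: str, cls: str) -> bool:
        if cls == MIRNA_CLASS:
            probe = ReadTag(sequence, 1)
            return any(
                align_to_precursor(
                    probe, p, max_shift=self.max_shift, max_mismatches=self.max_mismatches
                )
                for p in self.precursors
            )
        return sequence in self._haystacks.get(cls, "")

    def classify(self, sequence: str) -> str:
        """First matching class in priority order, else ``unannotated``."""
        for cls in self.priority:
            if self._matches(sequence, cls):
                return cls
        return UNANNOTATED


def classify_tag(tag: ReadTag, index: ClassIndex) -> str:
    if not MIN_TAG_LENGTH <= len(tag.sequence) <= MAX_TAG_LENGTH:
        raise ValueError("tag outside the 15-32 nt range; filter first")
    return index.classify(tag.sequence)


def composition_from_counts(
    class_counts: Mapping[str, tuple[int, int]],
    unique_total: int,
    read_total: int,
    order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Composition table from per-class (unique, total-read) counts.

    Percentages are taken against the library-level unique-tag and retained
    read totals and rounded half-up to two decimals, the way sequencing
    summary tables are printed.
    """
    if unique_total <= 0 or read_total <= 0:
        raise ZeroDivisionError("library totals must be positive")
    classes = list(order) if order is not None else sorted(class_counts)
    rows = []
    for cls in classes:
        u, t = class_counts.get(cls, (0, 0))
        rows.append(
            {
                "class": cls,
                "unique_count": u,
                "unique_pct": percent(u, unique_total),
                "total_count": t,
                "total_pct": percent(t, read_total),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def composition_table(
    classified: Iterable[tuple[ReadTag, str]],
    summary: LibrarySummary,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Table of per-class unique-tag and read counts with percentages.

    Covers every priority class plus the unannotated bin, so the unique and
    total columns sum to the classified tag/read totals (partition
    invariant).
    """
    uniques: Counter[str] = Counter()
    totals: Counter[str] = Counter()
    n_tags = 0
    n_reads = 0
    for tag, cls in classified:
        uniques[cls] += 1
        totals[cls] += tag.count
        n_tags += 1
        n_reads += tag.count
    order = list(priority) + [UNANNOTATED]
    counts = {cls: (uniques.get(cls, 0), totals.get(cls, 0)) for cls in order}
    if summary.trimmed_read_count == 0:
        # empty library: all-zero table, no percentages to take
        return pd.DataFrame(
            [
                {"class": c, "unique_count": 0, "unique_pct": 0.0,
                 "total_count": 0, "total_pct": 0.0}
                for c in order
            ]
        ).set_index("class")
    return composition_from_counts(
        counts,
        unique_total=summary.unique_tag_count or n_tags,
        read_total=summary.trimmed_read_count or n_reads,
        order=order,
    )


def length_distribution(
    tags: Iterable[ReadTag],
    min_len: int = MIN_TAG_LENGTH,
    max_len: int = MAX_TAG_LENGTH,
) -> dict[int, tuple[int, int]]:
    """Histogram over 15-32 nt: length -> (unique tags, total reads)."""
    hist = {L: [0, 0] for L in range(min_len, max_len + 1)}
    for tag in tags:
        L = len(tag.sequence)
        if L not in hist:
            raise ValueError(f"tag length {L} outside histogram range")
        hist[L][0] += 1
        hist[L][1] += tag.count
    return {L: (u, t) for L, (u, t) in hist.items()}
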