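"""Raw-read cleanup: 3' adapter trimming, length filtering and tag collapsing.

Single-end small-RNA libraries are sequenced through the insert into the 3'
adapter, so the usable insert is the read prefix before the first adapter
occurrence.  Identical inserts are then collapsed into unique *sequence tags*
carrying their read count, and rarely-seen tags are dropped as likely noise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

MIN_TAG_LENGTH = 15
MAX_TAG_LENGTH = 32
DEFAULT_MIN_COUNT = 2


@dataclass(frozen=True)
class ReadTag:
    """A unique small-RNA insert sequence with its collapsed read count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("tag count must be non-negative")


@dataclass(frozen=True)
class LibrarySummary:
    """Library-level read accounting.

    clean_read_count
        Reads entering the pipeline (post base-calling quality filter).
    trimmed_read_count
        Reads surviving adapter trimming and the 15-32 nt length filter.
    unique_tag_count
        Distinct insert sequences among the trimmed reads.
    """

    clean_read_count: int
    trimmed_read_count: int
    unique_tag_count: int

    def __post_init__(self) -> None:
        if not (self.unique_tag_count <= self.trimmed_read_count <= self.clean_read_count):
            raise ValueError("inconsistent library summary counts")


def trim_adapter(read_sequence: str, adapter: str) -> str | None:
    """Return the insert preceding the leftmost 3' adapter occurrence.

    The adapter may run off the end of the read, so a match of its first
    ``k`` bases, ``k = min(len(adapter), bases remaining)``, counts as an
    occurrence.  Returns ``None`` when no occurrence is found (the insert
    boundary cannot be confirmed) or for an empty read.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    if not read_sequence:
        return None
    n = len(read_sequence)
    for i in range(n):
        k = min(len(adapter), n - i)
        if read_sequence[i : i + k] == adapter[:k]:
            return read_sequence[:i]
    return None


def filter_length(sequence: str, min_len: int = MIN_TAG_LENGTH, max_len: int = MAX_TAG_LENGTH) -> bool:
    """True iff the insert is within the retained size range (15-32 nt)."""
    return min_len <= len(sequence) <= max_len


def collapse_tags(sequences: Iterable[str]) -> list[ReadTag]:
    """Group identical inserts into tags, sorted by descending count then sequence."""
    counts = Counter(sequences)
    return [
        ReadTag(seq, c)
        for seq, c in sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    ]


def filter_tags(tags: Sequence[ReadTag], min_count: int = DEFAULT_MIN_COUNT) -> list[ReadTag]:
    """Retain tags observed at least ``min_count`` times."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [t for t in tags if t.count >= min_count]


def preprocess_reads(
    read_sequences: Iterable[str],
    adapter: str,
    *,
    min_len: int = MIN_TAG_LENGTH,
    max_len: int = MAX_TAG_LENGTH,
) -> tuple[list[ReadTag], LibrarySummary]:
    """Full cleanup of a library: trim, length-filter, collapse.

    Returns all tags (pre count-filter, so counts still sum to the trimmed
    read total) together with the library accounting.
    """
    clean = 0
    inserts: list[str] = []
    for read in read_sequences:
        clean += 1
        insert = trim_adapter(read, adapter)
        if insert is not None and filter_length(insert, min_len, max_len):
            inserts.append(insert)
    tags = collapse_tags(inserts)
    summary = LibrarySummary(
        clean_read_count=clean,
        trimmed_read_count=len(inserts),
        unique_tag_count=len(tags),
    )
    return tags, summary
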