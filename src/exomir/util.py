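"""Shared sequence helpers (DNA alphabet, as read off the sequencer)."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

DNA_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T only)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def validate_dna(sequence: str) -> None:
    if not set(sequence) <= set(DNA_ALPHABET):
        bad = sorted(set(sequence) - set(DNA_ALPHABET))
        raise ValueError(f"non-ACGT symbols in sequence: {bad}")


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings.

    With ``limit`` set, returns early with ``limit + 1`` once the distance
    exceeds it (the caller only cares that the bound was broken).
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if limit is not None and d > limit:
                return d
    return d


def percent(count: int, total: int, decimals: int = 2) -> float:
    """count / total as a percentage, rounded half-up to ``decimals``.

    Half-up (not banker's) rounding matches how sequencing summary tables
    are conventionally printed.
    """
    if total <= 0:
        raise ZeroDivisionError("percentage with non-positive denominator")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, ROUND_HALF_UP))
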