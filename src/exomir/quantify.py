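"""Known-miRNA identification, isomiR calling and expression normalization.

A mature miRNA is rarely sequenced as a single exact sequence: Drosha/Dicer
cleavage wobble and occasional substitutions produce *isomiRs* — variants
whose 5'/3' ends sit within a few nucleotides of the annotated mature ends.
Here a tag is accepted as an isomiR of a mature region when it lies fully
within the mature region extended by ``max_shift`` (default 4 nt) on either
side and differs from the precursor by at most ``max_mismatches`` (default 1)
substitution.  Per (miRNA, arm) the isomiRs are aggregated into a profile:
total counts, the most abundant variant as representative, the seed, and
reads-per-million normalized expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .preprocess import ReadTag
from .util import hamming

MAX_END_SHIFT = 4
MAX_MISMATCHES = 1
SEED_START = 1  # 0-based; seed = positions 2-7 in 1-based mature coordinates
SEED_END = 7


@dataclass(frozen=True)
class MatureRegion:
    """A mature miRNA annotated on a precursor (0-based half-open offsets)."""

    arm: str  # "5p" or "3p"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")
        if not 0 <= self.start < self.end:
            raise ValueError("invalid mature region bounds")


@dataclass(frozen=True)
class PrecursorRecord:
    """A pre-miRNA hairpin anchored to the genome.

    ``start``/``end`` are 1-based inclusive genomic positions; ``sequence``
    is the sense-strand precursor sequence (already reverse-complemented for
    minus-strand precursors), and mature regions are offsets into it.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str
    sequence: str
    matures: tuple[MatureRegion, ...]

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("precursor end before start")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        arms = [m.arm for m in self.matures]
        if len(arms) != len(set(arms)):
            raise ValueError("at most one mature region per arm")
        for m in self.matures:
            if m.end > len(self.sequence):
                raise ValueError("mature region outside precursor")

    def mature(self, arm: str) -> MatureRegion:
        for m in self.matures:
            if m.arm == arm:
                return m
        raise KeyError(f"{self.id} has no {arm} mature")

    def mature_sequence(self, arm: str) -> str:
        m = self.mature(arm)
        return self.sequence[m.start : m.end]

    @property
    def coordinate(self) -> str:
        return f"{self.chromosome}:{self.start}..{self.end}: {self.strand}"


@dataclass(frozen=True)
class IsomiRRecord:
    """One mature-variant sequence anchored to a precursor arm.

    ``offset5``/``offset3`` are the signed distances of the variant's ends
    from the annotated mature ends (negative 5' offset = extension upstream).
    """

    mirna_id: str
    arm: str
    sequence: str
    offset5: int
    offset3: int
    mismatches: int
    count: int
    is_reference: bool
    is_most_abundant: bool = False

    def __post_init__(self) -> None:
        if abs(self.offset5) > MAX_END_SHIFT or abs(self.offset3) > MAX_END_SHIFT:
            raise ValueError("isomiR end offsets exceed the +/-4 nt window")
        if self.mismatches > MAX_MISMATCHES:
            raise ValueError("isomiR mismatch count exceeds 1")


@dataclass(frozen=True)
class MiRNAProfile:
    """Per-(miRNA, arm) aggregate over its isomiRs."""

    mirna_id: str
    arm: str
    reference_mature_sequence: str
    seed: str
    isomirs: tuple[IsomiRRecord, ...]
    total_count: int
    representative_sequence: str
    reference_is_most_abundant: bool
    normalized_expression: float
    identified: bool  # at least one perfectly matching (0-mismatch) isomiR

    @property
    def key(self) -> str:
        return f"{self.mirna_id}-{self.arm}"


def extract_seed(mature_sequence: str) -> str:
    """Seed hexamer: positions 2-7 (1-based) of the mature sequence."""
    if len(mature_sequence) < SEED_END:
        raise ValueError("mature sequence shorter than 7 nt has no seed")
    return mature_sequence[SEED_START:SEED_END]


def normalize_rpm(count: int, library_total: int) -> float:
    """Reads-per-million: count / library total x 1,000,000."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return count / library_total * 1_000_000


def align_to_precursor(
    tag: ReadTag,
    precursor: PrecursorRecord,
    *,
    max_shift: int = MAX_END_SHIFT,
    max_mismatches: int = MAX_MISMATCHES,
) -> list[IsomiRRecord]:
    """All isomiR placements of ``tag`` on ``precursor``'s mature regions.

    A placement is valid when the tag lies fully inside
    ``[mature_start - max_shift, mature_end + max_shift)`` (clipped to the
    precursor) and its Hamming distance to the precursor there is at most
    ``max_mismatches``.
    """
    seq = tag.sequence
    L = len(seq)
    out: list[IsomiRRecord] = []
    prec = precursor.sequence
    for m in precursor.matures:
        lo = max(0, m.start - max_shift)
        hi = min(len(prec), m.end + max_shift)
        if L > hi - lo:
            continue
        window = prec[lo:hi]
        # A tag with <=1 mismatch must contain one exact half; cheap prefilter
        # that rejects nearly all unrelated tags before the placement scan.
        if max_mismatches <= 1 and seq[: L // 2] not in window and seq[L // 2 :] not in window:
            continue
        reference = prec[m.start : m.end]
        for p in range(lo, hi - L + 1):
            d = hamming(seq, prec[p : p + L], limit=max_mismatches)
            if d <= max_mismatches:
                out.append(
                    IsomiRRecord(
                        mirna_id=precursor.id,
                        arm=m.arm,
                        sequence=seq,
                        offset5=p - m.start,
                        offset3=(p + L) - m.end,
                        mismatches=d,
                        count=tag.count,
                        is_reference=(seq == reference),
                    )
                )
    return out


def assign_isomirs(
    tags: Iterable[ReadTag],
    precursors: Sequence[PrecursorRecord],
    *,
    max_shift: int = MAX_END_SHIFT,
    max_mismatches: int = MAX_MISMATCHES,
) -> list[IsomiRRecord]:
    """Assign each miRNA-classified tag to exactly one (precursor, arm).

    Ties are broken by fewest mismatches, then smallest total end shift
    ``|offset5| + |offset3|``, then lexicographically smallest precursor id,
    then 5p before 3p.  A tag with no candidate placement signals an
    upstream misclassification and raises ``ValueError``.
    """
    assigned: list[IsomiRRecord] = []
    for tag in tags:
        candidates: list[IsomiRRecord] = []
        for prec in precursors:
            candidates.extend(
                align_to_precursor(tag, prec, max_shift=max_shift, max_mismatches=max_mismatches)
            )
        if not candidates:
            raise ValueError(f"tag {tag.sequence} has no precursor placement")
        best = min(
            candidates,
            key=lambda c: (
                c.mismatches,
                abs(c.offset5) + abs(c.offset3),
                c.mirna_id,
                c.arm != "5p",
            ),
        )
        assigned.append(best)
    return assigned


def profile_mirna(
    isomirs: Iterable[IsomiRRecord],
    precursors: Mapping[str, PrecursorRecord] | Sequence[PrecursorRecord],
    library_total: int,
) -> list[MiRNAProfile]:
    """Aggregate assigned isomiRs into per-(miRNA, arm) expression profiles.

    The representative sequence is the most abundant isomiR (count ties
    broken by lexicographic order for determinism); a miRNA counts as
    *identified* in the library only if at least one perfectly matching
    (0-mismatch) isomiR supports it, while tolerant 1-mismatch reads still
    contribute counts.
    """
    if library_total <= 0:
        raise ValueError("library total must be positive")
    if not isinstance(precursors, Mapping):
        precursors = {p.id: p for p in precursors}
    groups: dict[tuple[str, str], list[IsomiRRecord]] = {}
    for rec in isomirs:
        groups.setdefault((rec.mirna_id, rec.arm), []).append(rec)

    profiles: list[MiRNAProfile] = []
    for (pid, arm), records in sorted(groups.items()):
        top = sorted(records, key=lambda r: (-r.count, r.sequence))[0]
        flagged = tuple(
            replace(r, is_most_abundant=(r is top)) for r in records
        )
        total = sum(r.count for r in records)
        reference = precursors[pid].mature_sequence(arm)
        profiles.append(
            MiRNAProfile(
                mirna_id=pid,
                arm=arm,
                reference_mature_sequence=reference,
                seed=extract_seed(reference),
                isomirs=flagged,
                total_count=total,
                representative_sequence=top.sequence,
                reference_is_most_abundant=top.is_reference,
                normalized_expression=normalize_rpm(total, library_total),
                identified=any(r.mismatches == 0 for r in records),
            )
        )
    return profiles


def filter_low_expression(
    profiles: Iterable[MiRNAProfile], min_count: int = 2
) -> list[MiRNAProfile]:
    """Drop profiles supported by fewer than ``min_count`` raw reads.

    The threshold applies to raw counts, keeping the rule scale-free across
    library sizes.
    """
    return [p for p in profiles if p.total_count >= min_count]


def isomir_report(profile: MiRNAProfile, precursor: PrecursorRecord) -> dict:
    """Structured repertoire report for one miRNA hairpin.

    Mirrors the classic per-hairpin annotation block: precursor identity and
    genomic location, its folded structure, every isomiR with counts, the
    reference and most-abundant rows, and per-arm totals.
    """
    from .novel import fold_nussinov  # deferred: novel imports quantify types

    if not profile.isomirs:
        raise ValueError("cannot report an empty profile")
    fold = fold_nussinov(precursor.sequence)
    arm_totals: dict[str, int] = {}
    for rec in profile.isomirs:
        arm_totals[rec.arm] = arm_totals.get(rec.arm, 0) + rec.count
    reference_rows = [r for r in profile.isomirs if r.is_reference]
    return {
        "precursor_id": precursor.id,
        "location": precursor.coordinate,
        "structure": fold.structure,
        "isomirs": [
            {
                "sequence": r.sequence,
                "arm": r.arm,
                "offset5": r.offset5,
                "offset3": r.offset3,
                "mismatches": r.mismatches,
                "count": r.count,
                "is_reference": r.is_reference,
                "is_most_abundant": r.is_most_abundant,
            }
            for r in profile.isomirs
        ],
        "reference": {
            "sequence": profile.reference_mature_sequence,
            "count": sum(r.count for r in reference_rows),
        },
        "most_abundant": {
            "sequence": profile.representative_sequence,
            "count": max(r.count for r in profile.isomirs),
        },
        "arm_totals": arm_totals,
    }
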