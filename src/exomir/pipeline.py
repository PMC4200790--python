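"""End-to-end orchestration: reads in, tables out, two-library comparison."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import compare as cmp
from .annotate import DEFAULT_PRIORITY, ClassIndex, MIRNA_CLASS, UNANNOTATED, composition_table, length_distribution
from .novel import HairpinParams, NovelCandidate, NovelParams, call_novel
from .preprocess import (
    DEFAULT_MIN_COUNT,
    LibrarySummary,
    MAX_TAG_LENGTH,
    MIN_TAG_LENGTH,
    ReadTag,
    filter_tags,
    preprocess_reads,
)
from .quantify import MiRNAProfile, PrecursorRecord, assign_isomirs, filter_low_expression, profile_mirna


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole pipeline (all with working defaults)."""

    adapter: str = "TCGTATGCCGTCTTCTGCTTG"
    min_count: int = DEFAULT_MIN_COUNT
    min_len: int = MIN_TAG_LENGTH
    max_len: int = MAX_TAG_LENGTH
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    max_shift: int = 4
    max_mismatches: int = 1
    low_expression_min_count: int = 2
    fold_threshold: float = 2.0
    normalization_total: str = "trimmed"  # or "clean"
    novel: NovelParams = field(default_factory=NovelParams)

    def __post_init__(self) -> None:
        if self.normalization_total not in ("trimmed", "clean"):
            raise ValueError("normalization_total must be 'trimmed' or 'clean'")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "PipelineConfig":
        """Build from a flat key-value mapping (e.g. a parsed config file)."""
        kwargs = {}
        simple = {
            "adapter", "min_count", "min_len", "max_len", "max_shift",
            "max_mismatches", "low_expression_min_count", "fold_threshold",
            "normalization_total",
        }
        for key in simple & set(data):
            kwargs[key] = data[key]
        if "priority" in data:
            kwargs["priority"] = tuple(data["priority"])
        novel_keys = {"flank", "min_support"}
        hairpin_keys = {"min_stem_paired", "min_read_paired_frac", "max_bulge", "min_loop"}
        if novel_keys & set(data) or hairpin_keys & set(data):
            hp = HairpinParams(**{k: data[k] for k in hairpin_keys & set(data)})
            kwargs["novel"] = NovelParams(
                hairpin=hp, **{k: data[k] for k in novel_keys & set(data)}
            )
        return cls(**kwargs)


@dataclass
class LibraryResult:
    """Everything the pipeline derives from one library."""

    name: str
    summary: LibrarySummary
    tags: list[ReadTag]  # retained (count-filtered) tags
    classes: dict[str, str]  # tag sequence -> class
    composition: pd.DataFrame
    length_dist: dict[int, tuple[int, int]]
    profiles: list[MiRNAProfile]  # post low-expression filter
    all_profiles: list[MiRNAProfile]
    unannotated: list[ReadTag]

    @property
    def identified_mirnas(self) -> set[str]:
        return {p.key for p in self.profiles if p.identified}

    def normalization_total(self, mode: str) -> int:
        return (
            self.summary.trimmed_read_count
            if mode == "trimmed"
            else self.summary.clean_read_count
        )


def run_library(
    name: str,
    read_sequences: Iterable[str],
    precursors: Sequence[PrecursorRecord],
    class_refs: Mapping[str, Sequence[tuple[str, str]]],
    config: PipelineConfig = PipelineConfig(),
) -> LibraryResult:
    """Process one library: clean, collapse, annotate, quantify."""
    all_tags, summary = preprocess_reads(
        read_sequences, config.adapter, min_len=config.min_len, max_len=config.max_len
    )
    tags = filter_tags(all_tags, config.min_count)
    index = ClassIndex(
        class_refs,
        precursors,
        config.priority,
        max_shift=config.max_shift,
        max_mismatches=config.max_mismatches,
    )
    classified = [(t, index.classify(t.sequence)) for t in tags]
    composition = composition_table(classified, summary, config.priority)
    ldist = length_distribution(tags, config.min_len, config.max_len)
    mirna_tags = [t for t, c in classified if c == MIRNA_CLASS]
    isomirs = assign_isomirs(
        mirna_tags,
        precursors,
        max_shift=config.max_shift,
        max_mismatches=config.max_mismatches,
    )
    total = (
        summary.trimmed_read_count
        if config.normalization_total == "trimmed"
        else summary.clean_read_count
    )
    all_profiles = profile_mirna(isomirs, precursors, max(total, 1))
    profiles = filter_low_expression(all_profiles, config.low_expression_min_count)
    return LibraryResult(
        name=name,
        summary=summary,
        tags=tags,
        classes={t.sequence: c for t, c in classified},
        composition=composition,
        length_dist=ldist,
        profiles=profiles,
        all_profiles=all_profiles,
        unannotated=[t for t, c in classified if c == UNANNOTATED],
    )


def predict_novel(
    results: Sequence[LibraryResult],
    genome: Mapping[str, str],
    config: PipelineConfig = PipelineConfig(),
) -> list[NovelCandidate]:
    """Novel-candidate calling over the unannotated bins of all libraries."""
    tags_by_library = {r.name: r.unannotated for r in results}
    return call_novel(tags_by_library, genome, config.novel)


@dataclass
class ComparisonResult:
    known_overlap: cmp.OverlapSummary
    rows: list[cmp.ComparisonRow]
    novel_tally: tuple[int, int, int] | None


def compare_libraries(
    a: LibraryResult,
    b: LibraryResult,
    config: PipelineConfig = PipelineConfig(),
    candidates: Sequence[NovelCandidate] | None = None,
) -> ComparisonResult:
    """Repertoire overlap and per-miRNA fold changes between two libraries."""
    overlap = cmp.overlap_sets(a.identified_mirnas, b.identified_mirnas)
    total_a = a.normalization_total(config.normalization_total)
    total_b = b.normalization_total(config.normalization_total)
    counts_a = {p.key: p.total_count for p in a.profiles}
    counts_b = {p.key: p.total_count for p in b.profiles}
    rows = [
        cmp.fold_change(
            key,
            counts_a.get(key, 0),
            max(total_a, 1),
            counts_b.get(key, 0),
            max(total_b, 1),
            config.fold_threshold,
        )
        for key in sorted(set(counts_a) | set(counts_b))
    ]
    tally = None
    if candidates is not None:
        tally = cmp.classify_common_novel(
            cmp.candidate_count_rows(candidates, a.name, b.name),
            max(total_a, 1),
            max(total_b, 1),
            config.fold_threshold,
        )
    return ComparisonResult(overlap, rows, tally)
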