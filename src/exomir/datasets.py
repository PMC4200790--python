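"""Bundled example dataset: published small-RNA profiling of an esophageal
cancer cell line (EC9706) and the exosomes it secretes.

The raw reads of that experiment were never deposited, so the package ships
the *printed* summary tables instead: library-level read accounting, the
per-class composition, the top-ranked known miRNAs of each compartment
(with arm, seed and representative sequence), and the novel-miRNA
candidates detected in both compartments with per-library counts.  These
tables drive the worked comparison example and the desk-checkable parts of
the test suite.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotate import composition_from_counts

CELLS = "cells"
EXOSOMES = "exosomes"


def _read(name: str) -> pd.DataFrame:
    with resources.files("exomir.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_library_totals() -> pd.DataFrame:
    """Clean / adapter-trimmed / unique-tag totals per library."""
    return _read("ec9706_library_totals.tsv").set_index("library")


def load_class_counts() -> pd.DataFrame:
    """Per-class unique-tag and total-read counts per library."""
    return _read("ec9706_class_counts.tsv")


def load_known_profiles() -> pd.DataFrame:
    """Top-ranked known miRNAs per library with seed and sequence."""
    return _read("ec9706_top_known_mirnas.tsv")


def load_novel_candidates() -> pd.DataFrame:
    """Novel-miRNA candidate loci detected in both libraries.

    One row per candidate locus; a multi-locus consensus sequence appears
    once per locus with identical counts.
    """
    return _read("ec9706_novel_candidates.tsv")


def load_novel_exosome_top() -> pd.DataFrame:
    """Top novel miRNAs of the exosome library (most-abundant isomiR shown)."""
    return _read("ec9706_top_novel_exosome.tsv")


def load_repertoire_sizes() -> dict[str, int]:
    """Known/novel miRNA repertoire sizes and overlaps per compartment."""
    df = _read("ec9706_repertoire_sizes.tsv")
    return dict(zip(df["metric"], df["value"].astype(int)))


def library_totals(mode: str = "trimmed") -> tuple[int, int]:
    """(cells, exosomes) read totals used for RPM normalization.

    ``mode`` selects the adapter-trimmed (default) or pre-trim clean-read
    totals as the normalization denominator.
    """
    col = {"trimmed": "trimmed_reads", "clean": "clean_reads"}[mode]
    totals = load_library_totals()
    return int(totals.loc[CELLS, col]), int(totals.loc[EXOSOMES, col])


def composition(library: str) -> pd.DataFrame:
    """Recompute the composition percentages from the bundled counts."""
    counts = load_class_counts()
    totals = load_library_totals()
    sub = counts[counts["library"] == library]
    class_counts = {
        row["class"]: (int(row["unique_count"]), int(row["total_count"]))
        for _, row in sub.iterrows()
    }
    return composition_from_counts(
        class_counts,
        unique_total=int(totals.loc[library, "unique_tags"]),
        read_total=int(totals.loc[library, "trimmed_reads"]),
        order=list(sub["class"]),
    )


def novel_count_rows() -> list[tuple[str, int, int]]:
    """(candidate_id, cells count, exosomes count) per candidate locus."""
    df = load_novel_candidates()
    return [
        (row.candidate_id, int(row.cells_count), int(row.exosomes_count))
        for row in df.itertuples(index=False)
    ]
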