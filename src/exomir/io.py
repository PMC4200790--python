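"""Readers and writers for the pipeline's standard formats.

FASTA/FASTQ go through Biopython; tables are UTF-8 TSV with header rows.
Precursors travel as a FASTA of hairpin sequences plus a TSV of genomic
coordinates and mature-region offsets (one row per mature).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .novel import NovelCandidate
from .preprocess import ReadTag
from .quantify import IsomiRRecord, MatureRegion, MiRNAProfile, PrecursorRecord
from .synthetic import SimulationTruth


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(path, items: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq_sequences(path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fastq")]


def write_precursors(precursors: Sequence[PrecursorRecord], fasta_path, tsv_path) -> None:
    write_fasta(fasta_path, [(p.id, p.sequence) for p in precursors])
    rows = [
        {
            "id": p.id,
            "chromosome": p.chromosome,
            "start": p.start,
            "end": p.end,
            "strand": p.strand,
            "arm": m.arm,
            "mature_start": m.start,
            "mature_end": m.end,
        }
        for p in precursors
        for m in p.matures
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_precursors(fasta_path, tsv_path) -> list[PrecursorRecord]:
    seqs = read_fasta(fasta_path)
    table = pd.read_csv(tsv_path, sep="\t")
    precursors = []
    for pid, group in table.groupby("id", sort=True):
        first = group.iloc[0]
        matures = tuple(
            MatureRegion(r.arm, int(r.mature_start), int(r.mature_end))
            for r in group.itertuples()
        )
        precursors.append(
            PrecursorRecord(
                str(pid),
                str(first.chromosome),
                int(first.start),
                int(first.end),
                str(first.strand),
                seqs[str(pid)],
                matures,
            )
        )
    return precursors


def write_class_refs(class_refs: Mapping[str, Sequence[tuple[str, str]]], directory) -> None:
    os.makedirs(directory, exist_ok=True)
    for cls, refs in sorted(class_refs.items()):
        write_fasta(os.path.join(directory, f"{cls}.fa"), refs)


def read_class_refs(directory) -> dict[str, list[tuple[str, str]]]:
    out: dict[str, list[tuple[str, str]]] = {}
    for name in sorted(os.listdir(directory)):
        if name.endswith(".fa"):
            cls = name[:-3]
            out[cls] = list(read_fasta(os.path.join(directory, name)).items())
    return out


def write_truth(truth: SimulationTruth, path) -> None:
    rows = [
        {
            "read_id": o.read_id,
            "class": o.class_name,
            "parent_id": o.parent_id,
            "offset5": o.offset5,
            "offset3": o.offset3,
            "mismatch_pos": o.mismatch_pos,
            "insert": o.insert,
        }
        for o in truth.reads
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def tags_to_frame(tags: Sequence[ReadTag]) -> pd.DataFrame:
    return pd.DataFrame({"sequence": [t.sequence for t in tags], "count": [t.count for t in tags]})


PROFILE_COLUMNS = [
    "mirna_id", "arm", "seed", "reference_mature_sequence",
    "representative_sequence", "reference_is_most_abundant", "identified",
    "total_count", "normalized_expression",
]

ISOMIR_COLUMNS = [
    "mirna_id", "arm", "sequence", "offset5", "offset3", "mismatches",
    "count", "is_reference", "is_most_abundant",
]


def profiles_to_frame(profiles: Sequence[MiRNAProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": p.mirna_id,
                "arm": p.arm,
                "seed": p.seed,
                "reference_mature_sequence": p.reference_mature_sequence,
                "representative_sequence": p.representative_sequence,
                "reference_is_most_abundant": p.reference_is_most_abundant,
                "identified": p.identified,
                "total_count": p.total_count,
                "normalized_expression": p.normalized_expression,
            }
            for p in profiles
        ],
        columns=PROFILE_COLUMNS,
    )


def isomirs_to_frame(isomirs: Sequence[IsomiRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "arm": r.arm,
                "sequence": r.sequence,
                "offset5": r.offset5,
                "offset3": r.offset3,
                "mismatches": r.mismatches,
                "count": r.count,
                "is_reference": r.is_reference,
                "is_most_abundant": r.is_most_abundant,
            }
            for r in isomirs
        ],
        columns=ISOMIR_COLUMNS,
    )


def candidates_to_frame(
    candidates: Sequence[NovelCandidate], libraries: Sequence[str]
) -> pd.DataFrame:
    """Novel-candidate table: id, precursor coordinate, consensus, counts."""
    return pd.DataFrame(
        [
            {
                "candidate_id": c.candidate_id,
                "precursor_coordinate": c.coordinate,
                "consensus_mature_sequence": c.consensus_mature_sequence,
                "length": len(c.consensus_mature_sequence),
                "arm": c.arm,
                "n_loci": len(c.loci),
                **{f"{lib}_count": c.counts.get(lib, 0) for lib in libraries},
            }
            for c in candidates
        ],
        columns=[
            "candidate_id", "precursor_coordinate", "consensus_mature_sequence",
            "length", "arm", "n_loci", *[f"{lib}_count" for lib in libraries],
        ],
    )


def write_structures(candidates: Sequence[NovelCandidate], path) -> None:
    """Dot-bracket structure file: id, sequence, structure per candidate."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.candidate_id} {c.coordinate}\n")
            fh.write(c.precursor_sequence + "\n")
            fh.write(c.fold.structure + "\n")


def isomir_report_to_frame(report: dict) -> pd.DataFrame:
    """Per-isomiR rows of a repertoire report (round-trips through TSV)."""
    return pd.DataFrame(report["isomirs"])


def write_isomir_report(report: dict, path) -> None:
    isomir_report_to_frame(report).to_csv(path, sep="\t", index=False)


def read_isomir_rows(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
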