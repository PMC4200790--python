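"""Synthetic references and small-RNA libraries with known ground truth.

The generator emulates the statistical structure a cell-vs-exosome small
RNA-seq experiment presents to the analysis: a toy genome carrying hairpin
precursors with arm-annotated matures, contaminant reference sets (rRNA,
tRNA, snRNA, mRNA, repeats), and two 36-cycle single-end FASTQ libraries
whose reads are class-mixed fragments with the 3' adapter read through.
miRNA reads carry isomiR end heterogeneity (+/-4 nt) and rare single
substitutions; per-miRNA abundances span several orders of magnitude; the
two libraries share a configurable fraction of their miRNA repertoires.
Every read's origin is recorded so downstream stages can be tested for
exact recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .quantify import MatureRegion, PrecursorRecord
from .util import DNA_ALPHABET, revcomp

CLASS_NAMES = ("miRNA", "rRNA", "tRNA", "snRNA", "mRNA", "repeat", "unannotated")

# Total-read class proportions patterned on a cellular small-RNA library:
# miRNA-rich, heavy structured-ncRNA contamination, a large unannotated bin.
DEFAULT_MIXTURE = {
    "miRNA": 0.33,
    "rRNA": 0.148,
    "tRNA": 0.09,
    "snRNA": 0.031,
    "mRNA": 0.01,
    "repeat": 0.011,
    "unannotated": 0.38,
}

# Cleavage-offset heterogeneity: most reads match the annotated ends, with
# geometrically rarer 1-4 nt shifts on either side.
DEFAULT_OFFSETS = {
    -4: 0.002, -3: 0.008, -2: 0.04, -1: 0.15,
    0: 0.6,
    1: 0.15, 2: 0.04, 3: 0.008, 4: 0.002,
}

# Classic single-end small-RNA 3' adapter.
DEFAULT_ADAPTER = "TCGTATGCCGTCTTCTGCTTG"

# Extra precursor sequence flanking the hairpin so every +/-4 nt end shift
# stays within the precursor.
_PAD = 4


@dataclass
class SimulationConfig:
    """All knobs of the simulator; one integer seed drives every draw."""

    seed: int = 0
    reads_per_library: int = 50_000
    class_mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    expression_magnitude_range: float = 5.0  # orders of magnitude across miRNAs
    isomir_offset_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    mismatch_rate: float = 0.02
    adapter: str = DEFAULT_ADAPTER
    shared_fraction: float = 0.14  # fraction of mature arms expressed in both libraries
    n_precursors: int = 24
    n_chromosomes: int = 2
    chromosome_length: int = 12_000
    read_length: int = 36
    mature_length_range: tuple[int, int] = (17, 26)
    loop_length_range: tuple[int, int] = (8, 15)
    library_names: tuple[str, str] = ("cells", "exosomes")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_precursors < 1:
            raise ValueError("at least one precursor is required")
        if self.reads_per_library < 1:
            raise ValueError("reads_per_library must be >= 1")
        unknown = set(self.class_mixture) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown classes in mixture: {sorted(unknown)}")
        for name, dist in (
            ("class_mixture", self.class_mixture),
            ("isomir_offset_distribution", self.isomir_offset_distribution),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probabilities")
        if any(abs(o) > 4 for o in self.isomir_offset_distribution):
            raise ValueError("isomiR offsets must lie in [-4, 4]")
        for rate in (self.mismatch_rate, self.shared_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.mature_length_range
        if not 15 <= lo <= hi <= 32:
            raise ValueError("mature lengths must stay within 15-32 nt")
        if self.loop_length_range[0] < 3:
            raise ValueError("hairpin loop must be at least 3 nt")
        if len(self.adapter) < 6:
            raise ValueError("adapter must be at least 6 nt")


@dataclass(frozen=True)
class ReferenceSet:
    """Toy genome, precursor annotations and contaminant class references."""

    genome: Mapping[str, str]
    precursors: tuple[PrecursorRecord, ...]
    class_refs: Mapping[str, Sequence[tuple[str, str]]]


@dataclass(frozen=True)
class ReadOrigin:
    """Ground truth for one simulated read."""

    read_id: str
    class_name: str
    parent_id: str  # "<precursor>/<arm>" for miRNA, reference id otherwise
    offset5: int
    offset3: int
    mismatch_pos: int  # position within the insert, -1 for none
    insert: str


@dataclass
class SimulationTruth:
    """Per-read origins plus the aggregates recovery tests compare against."""

    library_name: str
    reads: list[ReadOrigin]
    class_counts: dict[str, int]
    mirna_counts: dict[tuple[str, str], int]

    def check_conservation(self, reads_per_library: int) -> None:
        if sum(self.class_counts.values()) != reads_per_library:
            raise AssertionError("truth class counts do not sum to library size")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


def build_reference(config: SimulationConfig) -> ReferenceSet:
    """Deterministically generate the toy genome and reference sets.

    Each precursor is a perfect inverted repeat (5' arm, >=3 nt loop,
    reverse-complement 3' arm) with 4 nt of flanking pad, planted at a
    non-overlapping genomic position on a random strand.  Mature regions of
    17-26 nt are annotated on one or both arms.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mature_length_range
    llo, lhi = config.loop_length_range

    drafts: list[tuple[str, str, tuple[MatureRegion, ...]]] = []
    for i in range(config.n_precursors):
        m5len = int(rng.integers(lo, hi + 1))
        m3len = int(rng.integers(lo, min(hi, m5len) + 1))
        loop_len = int(rng.integers(llo, lhi + 1))
        arm5 = _random_seq(rng, m5len)
        loop = _random_seq(rng, loop_len)
        pad5 = _random_seq(rng, _PAD)
        pad3 = _random_seq(rng, _PAD)
        seq = pad5 + arm5 + loop + revcomp(arm5) + pad3
        arm3_start = _PAD + m5len + loop_len
        matures = [
            MatureRegion("5p", _PAD, _PAD + m5len),
            MatureRegion("3p", arm3_start, arm3_start + m3len),
        ]
        which = rng.random()
        if which < 0.15:
            matures = [matures[0]]
        elif which < 0.30:
            matures = [matures[1]]
        drafts.append((f"pre{i:03d}", seq, tuple(matures)))

    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    genome = {
        name: list(_random_seq(rng, config.chromosome_length)) for name in chrom_names
    }
    cursors = {name: 1 for name in chrom_names}
    precursors: list[PrecursorRecord] = []
    for idx, (pid, seq, matures) in enumerate(drafts):
        chrom = chrom_names[idx % len(chrom_names)]
        gap = int(rng.integers(20, 60))
        start = cursors[chrom] + gap
        end = start + len(seq) - 1
        if end > config.chromosome_length:
            raise ValueError(
                "genome too short to place all precursors without overlap; "
                "increase chromosome_length or n_chromosomes"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        insert = seq if strand == "+" else revcomp(seq)
        genome[chrom][start - 1 : end] = list(insert)
        cursors[chrom] = end + 1
        precursors.append(
            PrecursorRecord(pid, chrom, start, end, strand, seq, matures)
        )

    class_sizes = {"rRNA": (3, 300), "tRNA": (5, 75), "snRNA": (4, 150), "mRNA": (4, 600), "repeat": (3, 400)}
    class_refs = {
        cls: [(f"{cls}_{k}", _random_seq(rng, length)) for k in range(n)]
        for cls, (n, length) in class_sizes.items()
    }
    return ReferenceSet(
        genome={name: "".join(chars) for name, chars in genome.items()},
        precursors=tuple(precursors),
        class_refs=class_refs,
    )


def _library_bucket(config: SimulationConfig, library_name: str) -> int:
    if library_name in config.library_names:
        return config.library_names.index(library_name)
    return zlib.crc32(library_name.encode()) % 2


def _expression_plan(
    config: SimulationConfig, refs: ReferenceSet
) -> dict[int, tuple[list[tuple[str, str]], np.ndarray]]:
    """Per-library miRNA repertoires and abundance weights.

    Drawn from the master seed alone so both libraries see a coordinated
    split: a shared core plus disjoint library-specific arms, each with a
    log-uniform abundance over ``expression_magnitude_range`` decades.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    arms = [
        (p.id, m.arm) for p in refs.precursors for m in p.matures
    ]
    order = rng.permutation(len(arms))
    n_shared = int(round(config.shared_fraction * len(arms)))
    shared = [arms[i] for i in order[:n_shared]]
    rest = [arms[i] for i in order[n_shared:]]
    specific = {0: rest[0::2], 1: rest[1::2]}
    plan = {}
    for bucket in (0, 1):
        expressed = shared + specific[bucket]
        if not expressed:
            expressed = shared or arms
        weights = 10.0 ** rng.uniform(0, config.expression_magnitude_range, len(expressed))
        plan[bucket] = (expressed, weights / weights.sum())
    return plan


def simulate_reads(
    refs: ReferenceSet, config: SimulationConfig, library_name: str
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Simulate one library in memory.

    Returns ``[(read_id, read_sequence), ...]`` (fixed-length reads with the
    adapter read through) and the ground truth.  Deterministic for a fixed
    (config, seed, library name).
    """
    bucket = _library_bucket(config, library_name)
    plan = _expression_plan(config, refs)
    expressed, weights = plan[bucket]
    precursors = {p.id: p for p in refs.precursors}

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2, zlib.crc32(library_name.encode())])
    )
    n = config.reads_per_library
    class_names = sorted(config.class_mixture)
    probs = np.array([config.class_mixture[c] for c in class_names])
    class_draw = rng.choice(len(class_names), size=n, p=probs / probs.sum())

    offsets = sorted(config.isomir_offset_distribution)
    offset_probs = np.array([config.isomir_offset_distribution[o] for o in offsets])
    offset_probs = offset_probs / offset_probs.sum()

    reads: list[tuple[str, str]] = []
    origins: list[ReadOrigin] = []
    class_counts: dict[str, int] = {c: 0 for c in CLASS_NAMES}
    mirna_counts: dict[tuple[str, str], int] = {}

    for i in range(n):
        cls = class_names[class_draw[i]]
        class_counts[cls] += 1
        parent = ""
        o5 = o3 = 0
        mismatch_pos = -1
        if cls == "miRNA":
            k = int(rng.choice(len(expressed), p=weights))
            pid, arm = expressed[k]
            prec = precursors[pid]
            m = prec.mature(arm)
            o5 = int(offsets[int(rng.choice(len(offsets), p=offset_probs))])
            o3 = int(offsets[int(rng.choice(len(offsets), p=offset_probs))])
            a = max(0, m.start + o5)
            b = min(len(prec.sequence), m.end + o3)
            o5, o3 = a - m.start, b - m.end  # realized offsets after clipping
            insert = prec.sequence[a:b]
            if config.mismatch_rate > 0 and rng.random() < config.mismatch_rate:
                mismatch_pos = int(rng.integers(0, len(insert)))
                old = insert[mismatch_pos]
                new = DNA_ALPHABET[
                    (DNA_ALPHABET.index(old) + 1 + int(rng.integers(0, 3))) % 4
                ]
                insert = insert[:mismatch_pos] + new + insert[mismatch_pos + 1 :]
            parent = f"{pid}/{arm}"
            mirna_counts[(pid, arm)] = mirna_counts.get((pid, arm), 0) + 1
        elif cls == "unannotated":
            insert = _random_seq(rng, int(rng.integers(15, 33)))
            parent = "random"
        else:
            ref_list = refs.class_refs[cls]
            ref_id, ref_seq = ref_list[int(rng.integers(0, len(ref_list)))]
            frag_len = int(rng.integers(15, min(32, len(ref_seq)) + 1))
            start = int(rng.integers(0, len(ref_seq) - frag_len + 1))
            insert = ref_seq[start : start + frag_len]
            parent = ref_id

        read = insert + config.adapter
        if len(read) < config.read_length:
            read += _random_seq(rng, config.read_length - len(read))
        read = read[: config.read_length]
        read_id = f"{library_name}_{i:06d}"
        reads.append((read_id, read))
        origins.append(ReadOrigin(read_id, cls, parent, o5, o3, mismatch_pos, insert))

    truth = SimulationTruth(library_name, origins, class_counts, mirna_counts)
    truth.check_conservation(n)
    return reads, truth


def simulate_library(
    refs: ReferenceSet,
    config: SimulationConfig,
    library_name: str,
    fastq_path,
) -> SimulationTruth:
    """Simulate a library and write it as Phred+33 FASTQ (constant quality)."""
    reads, truth = simulate_reads(refs, config, library_name)
    qual = "I" * config.read_length
    with open(fastq_path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
    return truth
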