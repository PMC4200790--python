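"""Novel miRNA candidate prediction from unannotated tags.

The classifier follows the three classical structural criteria: (i) the
input tags are already the unannotated bin, so known miRNAs and other
ncRNA classes are excluded by construction; (ii) singleton tags (a single
read in a library) are not accepted as supporting evidence in that
library; (iii) each mapped locus must fold into a hairpin with the read
entirely inside one arm and without large internal loops or bulges.

Secondary structure comes from Nussinov-style base-pair maximization
(Watson-Crick plus G.T wobble, the DNA-alphabet image of G.U) with a
minimum hairpin loop of 3 nt — a self-contained, exactly testable stand-in
for thermodynamic folding; an optional hook reports free energy through an
external folder when one is installed.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .preprocess import ReadTag
from .util import revcomp, validate_dna

_PAIRS = frozenset({"AT", "TA", "GC", "CG", "GT", "TG"})
MIN_LOOP = 3


@dataclass(frozen=True)
class FoldResult:
    """A nested secondary structure in dot-bracket notation."""

    sequence: str
    structure: str
    pairs: tuple[tuple[int, int], ...]  # 0-based (i, j) with i < j

    @property
    def pair_count(self) -> int:
        return len(self.pairs)

    @property
    def paired_positions(self) -> frozenset[int]:
        return frozenset(i for p in self.pairs for i in p)


@dataclass(frozen=True)
class Locus:
    """1-based inclusive genomic interval with strand."""

    chromosome: str
    start: int
    end: int
    strand: str

    @property
    def coordinate(self) -> str:
        return f"{self.chromosome}:{self.start}..{self.end}: {self.strand}"


@dataclass(frozen=True)
class Window:
    """An excised candidate-precursor window with the read placed inside it.

    ``read_start``/``read_end`` are 0-based half-open offsets of the
    supporting read within ``sequence`` (already on the read's strand).
    """

    sequence: str
    chromosome: str
    start: int
    end: int
    strand: str
    read_start: int
    read_end: int
    label: str  # which arm the window was excised for ("5p" or "3p")

    @property
    def coordinate(self) -> str:
        return f"{self.chromosome}:{self.start}..{self.end}: {self.strand}"


@dataclass(frozen=True)
class HairpinParams:
    """Quantified structural thresholds for "a clean hairpin".

    min_stem_paired
        Paired *positions* (2 per base pair) in the dominant stem-loop.
    min_read_paired_frac
        Fraction of read bases that must be paired.
    max_bulge
        Largest internal loop/bulge tolerated within the read-spanning stem.
    min_read_helix
        Shortest acceptable run of consecutive stacked base pairs touching
        the read.  Base-pair maximization folds random sequence into long
        but defect-riddled "stems"; a genuine miRNA duplex is a clean
        helix, and requiring one touching the read is what separates real
        hairpins from folded noise.
    """

    min_stem_paired: int = 18
    min_read_paired_frac: float = 0.6
    max_bulge: int = 6
    min_read_helix: int = 12
    min_loop: int = MIN_LOOP


@dataclass(frozen=True)
class NovelParams:
    hairpin: HairpinParams = field(default_factory=HairpinParams)
    flank: int = 70
    min_support: int = 2


@dataclass(frozen=True)
class NovelCandidate:
    """A hairpin locus supported by unannotated reads.

    One candidate row is emitted per locus; a consensus mature sequence
    mapping to several loci yields one row per locus carrying identical
    per-library counts (the supporting reads cannot be attributed to either
    copy).  ``loci`` lists every locus of the consensus sequence.
    """

    candidate_id: str
    locus: Locus
    loci: tuple[Locus, ...]
    precursor_sequence: str
    fold: FoldResult
    arm: str
    consensus_mature_sequence: str
    counts: Mapping[str, int]
    most_abundant_isomir_sequence: str
    reference_is_most_abundant: bool

    @property
    def coordinate(self) -> str:
        return self.locus.coordinate


def fold_nussinov(sequence: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Maximum base-pairing nested structure by dynamic programming.

    Pairs are Watson-Crick plus G.T wobble; hairpin loops keep at least
    ``min_loop`` unpaired nucleotides.  The traceback is deterministic:
    at each interval the leftmost pairing partner achieving the optimum is
    taken before leaving the right end unpaired.
    """
    validate_dna(sequence)
    n = len(sequence)
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if sequence[k] + sequence[j] in _PAIRS:
                    left = dp[i][k - 1] if k > i else 0
                    cand = left + 1 + dp[k + 1][j - 1]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        target = dp[i][j]
        chosen = False
        for k in range(i, j - min_loop):
            if sequence[k] + sequence[j] in _PAIRS:
                left = dp[i][k - 1] if k > i else 0
                if left + 1 + dp[k + 1][j - 1] == target:
                    pairs.append((k, j))
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    chosen = True
                    break
        if not chosen:
            stack.append((i, j - 1))
    pairs.sort()
    structure = ["."] * n
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return FoldResult(sequence, "".join(structure), tuple(pairs))


def map_to_genome(sequence: str, genome: Mapping[str, str]) -> list[Locus]:
    """All exact occurrences of the tag on both genome strands.

    Minus-strand hits report the genomic (plus-strand) window carrying the
    reverse complement of the tag.
    """
    loci: list[Locus] = []
    L = len(sequence)
    for chrom in sorted(genome):
        s = genome[chrom]
        for strand, query in (("+", sequence), ("-", revcomp(sequence))):
            pos = s.find(query)
            while pos != -1:
                loci.append(Locus(chrom, pos + 1, pos + L, strand))
                pos = s.find(query, pos + 1)
    loci.sort(key=lambda l: (l.chromosome, l.start, l.strand))
    return loci


def excise_window(locus: Locus, genome: Mapping[str, str], flank: int = 70) -> list[Window]:
    """Two candidate-precursor windows around a mapped read.

    The read may sit in either hairpin arm, so one window extends mostly
    downstream (read near the 5' arm) and one mostly upstream (read near
    the 3' arm), each with a 10 nt margin on the short side; both are
    clipped to the chromosome and reverse-complemented for minus-strand
    loci.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    chrom_seq = genome[locus.chromosome]
    n = len(chrom_seq)
    windows: list[Window] = []
    genomic = [
        ("5p" if locus.strand == "+" else "3p", locus.start - 10, locus.start + flank),
        ("3p" if locus.strand == "+" else "5p", locus.end - flank, locus.end + 10),
    ]
    for label, a, b in genomic:
        a = max(1, a)
        b = min(n, b)
        seq = chrom_seq[a - 1 : b]
        if locus.strand == "+":
            rs, re_ = locus.start - a, locus.end - a + 1
        else:
            seq = revcomp(seq)
            rs, re_ = b - locus.end, b - locus.start + 1
        windows.append(
            Window(seq, locus.chromosome, a, b, locus.strand, rs, re_, label)
        )
    return windows


def hairpin_check(
    fold: FoldResult,
    read_start: int,
    read_end: int,
    params: HairpinParams = HairpinParams(),
) -> tuple[bool, dict]:
    """Test whether a fold is a clean hairpin with the read inside one arm.

    Checks, in order: (a) a dominant stem-loop with at least
    ``min_stem_paired`` paired positions; (b) the read entirely 5' or 3' of
    that stem's terminal loop; (c) at least ``min_read_paired_frac`` of read
    bases paired; (d) no internal loop or bulge larger than ``max_bulge``
    within the read-spanning part of the stem; (e) an uninterrupted helix
    of at least ``min_read_helix`` stacked pairs touching the read.
    Returns the verdict plus a diagnostics dict (including the inferred arm
    when (b) holds).
    """
    diag: dict = {"stem_paired": 0, "read_paired_frac": 0.0, "arm": None}
    pairs = fold.pairs
    if not pairs:
        diag["reason"] = "no base pairs"
        return False, diag

    innermost = [
        p
        for p in pairs
        if not any(p[0] < q[0] and q[1] < p[1] for q in pairs)
    ]
    chains = {
        p: [q for q in pairs if q[0] <= p[0] and p[1] <= q[1]] for p in innermost
    }
    loop_pair = max(innermost, key=lambda p: (len(chains[p]), -p[0]))
    chain = sorted(chains[loop_pair])
    diag["stem_paired"] = 2 * len(chain)
    if 2 * len(chain) < params.min_stem_paired:
        diag["reason"] = "dominant stem too short"
        return False, diag

    loop_lo, loop_hi = loop_pair[0] + 1, loop_pair[1]  # unpaired loop interval
    diag["loop"] = (loop_lo, loop_hi)
    if read_end <= loop_lo:
        diag["arm"] = "5p"
    elif read_start >= loop_hi:
        diag["arm"] = "3p"
    else:
        diag["reason"] = "read overlaps the terminal loop"
        return False, diag

    paired = fold.paired_positions
    span = max(1, read_end - read_start)
    frac = sum(1 for i in range(read_start, read_end) if i in paired) / span
    diag["read_paired_frac"] = frac
    if frac < params.min_read_paired_frac:
        diag["reason"] = "read insufficiently paired"
        return False, diag

    # Bulges are charged against the read's core: its outer 4 nt are where
    # cleavage wobble lives (the isomiR end window), so breathing defects
    # clipping only a read end are tolerated.
    core_start, core_end = read_start + 4, read_end - 4
    for (a1, b1), (a2, b2) in zip(chain, chain[1:]):
        gap5, gap3 = a2 - a1 - 1, b1 - b2 - 1
        # charge the read only for internal loops/bulges whose unpaired
        # segment actually overlaps its core (on either strand of the stem)
        overlaps5 = gap5 > 0 and core_start < a2 and core_end > a1 + 1
        overlaps3 = gap3 > 0 and core_start < b1 and core_end > b2 + 1
        if (overlaps5 or overlaps3) and max(gap5, gap3) > params.max_bulge:
            diag["reason"] = f"bulge of {max(gap5, gap3)} nt in read stem"
            return False, diag

    best = cur = 0
    prev: tuple[int, int] | None = None
    for a, b in chain:
        cur = cur + 1 if prev is not None and (a, b) == (prev[0] + 1, prev[1] - 1) else 1
        if read_start <= a < read_end or read_start <= b < read_end:
            best = max(best, cur)
        prev = (a, b)
    diag["read_helix"] = best
    if best < params.min_read_helix:
        diag["reason"] = "no clean helix through the read"
        return False, diag

    diag["reason"] = "ok"
    return True, diag


def call_novel(
    tags_by_library: Mapping[str, Sequence[ReadTag]],
    genome: Mapping[str, str],
    params: NovelParams = NovelParams(),
) -> list[NovelCandidate]:
    """Predict novel miRNA candidates from per-library unannotated tags.

    Tags seen fewer than ``min_support`` times in a library contribute no
    evidence (and no counts) in that library.  Surviving tags are mapped
    exactly to both genome strands; each locus is excised, folded and kept
    when the hairpin test passes.  Tags whose loci overlap an accepted
    candidate are folded into it as isomiR-style variant support; distinct
    loci sharing one consensus sequence yield one candidate row per locus
    with identical counts.
    """
    libraries = sorted(tags_by_library)
    support: dict[str, dict[str, int]] = {}
    for lib in libraries:
        for tag in tags_by_library[lib]:
            if tag.count >= params.min_support:
                support.setdefault(tag.sequence, {})[lib] = tag.count
    ordered = sorted(
        support, key=lambda s: (-sum(support[s].values()), s)
    )

    accepted: list[dict] = []
    for seq in ordered:
        loci = map_to_genome(seq, genome)
        passing: list[tuple[Locus, Window, FoldResult, str]] = []
        for locus in loci:
            for window in excise_window(locus, genome, params.flank):
                fold = fold_nussinov(window.sequence, params.hairpin.min_loop)
                ok, diag = hairpin_check(
                    fold, window.read_start, window.read_end, params.hairpin
                )
                if ok:
                    passing.append((locus, window, fold, diag["arm"]))
                    break
        if not passing:
            continue
        # A perfect inverted repeat also maps the read on the opposite
        # strand of its own mirror arm; collapse hits landing within one
        # window span of each other into a single locus.
        deduped: list[tuple[Locus, Window, FoldResult, str]] = []
        for item in passing:
            locus = item[0]
            if any(
                locus.chromosome == kept[0].chromosome
                and locus.start <= kept[0].end + params.flank
                and kept[0].start <= locus.end + params.flank
                for kept in deduped
            ):
                continue
            deduped.append(item)
        passing = deduped
        counts = dict(support[seq])
        host = None
        for cand in accepted:
            if any(
                l.chromosome == pl.chromosome
                and l.strand == pl.strand
                and l.start <= pl.end
                and pl.start <= l.end
                for l in cand["loci"]
                for pl, *_ in passing
            ):
                host = cand
                break
        if host is not None:
            for lib, c in counts.items():
                host["counts"][lib] = host["counts"].get(lib, 0) + c
            total = sum(counts.values())
            if total > host["top_count"]:
                host["top_count"] = total
                host["top_seq"] = seq
            continue
        accepted.append(
            {
                "consensus": seq,
                "loci": [p[0] for p in passing],
                "windows": passing,
                "counts": counts,
                "top_seq": seq,
                "top_count": sum(counts.values()),
            }
        )

    candidates: list[NovelCandidate] = []
    serial = 0
    for cand in accepted:
        all_loci = tuple(cand["loci"])
        for locus, window, fold, arm in cand["windows"]:
            serial += 1
            counts = {lib: cand["counts"].get(lib, 0) for lib in libraries}
            candidates.append(
                NovelCandidate(
                    candidate_id=f"{locus.chromosome}_{serial}",
                    locus=Locus(window.chromosome, window.start, window.end, window.strand),
                    loci=all_loci,
                    precursor_sequence=window.sequence,
                    fold=fold,
                    arm=arm,
                    consensus_mature_sequence=cand["consensus"],
                    counts=counts,
                    most_abundant_isomir_sequence=cand["top_seq"],
                    reference_is_most_abundant=cand["top_seq"] == cand["consensus"],
                )
            )
    return candidates


def rnafold_energy(sequence: str) -> float | None:
    """Minimum free energy from an external ``RNAfold`` binary, if present.

    Purely an optional cross-check hook; returns ``None`` when no folder is
    installed.  The pipeline itself never depends on it.
    """
    exe = shutil.which("RNAfold")
    if exe is None:
        return None
    out = subprocess.run(
        [exe, "--noPS"], input=sequence + "\n", capture_output=True, text=True, check=True
    ).stdout
    last = out.strip().splitlines()[-1]
    return float(last.rsplit("(", 1)[1].rstrip(")").strip())
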