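# Methods

This note documents the models and procedures implemented in `exomir`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not
demonstrate about real data.

## Read model and preprocessing

Libraries are single-end 36-cycle reads of short RNA inserts. Inserts
shorter than the read length are sequenced through into the 3' adapter,
so the usable insert is the prefix before the leftmost adapter
occurrence; because the adapter itself can be truncated at the read end,
a match of its first *k* bases (*k* = min(adapter length, bases
remaining)) counts as an occurrence. Reads with no detectable adapter are
discarded: without the adapter boundary the 3' end of the insert cannot
be confirmed. Adapter matching is exact; the stage is deterministic and
the simulator does not generate sequencing errors inside the adapter.

Inserts are kept when 15 ≤ length ≤ 32 nt, collapsed into unique
sequence tags with counts (sorted by descending count, then sequence),
and tags below `min_count` (default 2) are dropped as likely artifacts.
The count-filter threshold is a config knob; all recovery tests that
compare against simulation ground truth run with `min_count = 1` so that
every simulated read is accounted for.

## Class annotation

Each tag receives exactly one class by walking a priority list, default
rRNA > tRNA > snRNA > miRNA > repeat > mRNA, falling through to
*unannotated*. The ordering reflects the usual contamination-removal
sequence (structured ncRNA first, genome-derived classes last) and is
configurable. Contaminant classes match by exact sense-strand substring
containment in their reference sequences — small-RNA protocols are
stranded, so antisense matching is deliberately not performed. The miRNA
class uses the isomiR matcher below, so end-shifted and single-mismatch
variants are still annotated as miRNA. Composition tables report
unique-tag and total-read counts per class with percentages against the
library's unique-tag and trimmed-read totals, rounded half-up to two
decimals (the convention used when such tables are printed).

## IsomiR model and known-miRNA quantification

A tag is an isomiR of an annotated mature region when it lies entirely
within the region extended by ±4 nt on both sides and its Hamming
distance to the precursor there is ≤ 1. End offsets are recorded relative
to the annotated mature ends; the ±4 window models Drosha/Dicer cleavage
wobble and the single substitution covers both biological variants and
residual sequencing error. Tags matching several precursors are assigned
to one by: fewest mismatches, then smallest |5' offset| + |3' offset|,
then lexicographically smallest precursor id, then 5p before 3p — an
arbitrary but deterministic tie-break.

Per (precursor, arm) the isomiRs form a profile: the representative is
the most abundant variant (count ties broken lexicographically), because
the most abundant isomiR is a more robust expression proxy across samples
than the catalogued reference sequence; the profile records whether the
reference is itself the most abundant. A miRNA counts as *identified* in
a library only when at least one perfectly matching (0-mismatch) isomiR
supports it; tolerant reads contribute counts but cannot identify a
miRNA on their own. The seed is positions 2–7 (1-based) of the reference
mature. Expression is RPM = count / library total × 10⁶, where the
library total is the adapter-trimmed read total by default (the pre-trim
clean-read total is available as a config option; the bundled dataset's
regulation split is identical under both). Profiles with fewer than 2
raw supporting reads are removed before differential analysis — the
threshold is applied to raw counts, not RPM, so the rule is scale-free
across library sizes.

## Secondary structure and novel-miRNA prediction

Folding uses Nussinov-style base-pair maximization over Watson–Crick
pairs plus G·U wobble (G·T in DNA alphabet), minimum hairpin loop 3 nt,
with a deterministic traceback (leftmost pairing partner first). Maximum
pairing was chosen over thermodynamic free energy because it is
self-contained and exactly verifiable — the test suite checks it against
exhaustive enumeration of all nested pairings for sequences ≤ 15 nt. An
optional hook (`rnafold_energy`) reports minimum free energy through an
external `RNAfold` binary when one is installed; nothing depends on it.

Novel candidates are called from the unannotated tag bin in three steps
mirroring the classical criteria: known-class matches are excluded by
construction; tags observed only once in a library contribute no evidence
(and no counts) in that library; and each exactly-mapped genomic locus
must pass a hairpin test. Around each locus two windows are excised (read
near the 5' arm: 10 nt upstream to `flank` = 70 nt downstream; read near
the 3' arm: mirrored), reverse-complemented for minus-strand hits.

The hairpin test quantifies "a clean hairpin with the read inside one
arm" as five checks: (a) the dominant stem-loop — the terminal loop with
the deepest enclosing pair chain — carries ≥ 18 paired positions;
(b) the read lies entirely 5' or entirely 3' of that terminal loop (this
also assigns the 5p/3p arm); (c) ≥ 60% of read bases are paired; (d) no
internal loop or bulge larger than 6 nt overlaps the read's *core* (the
read minus 4 nt at each end — the same end-wobble window as the isomiR
model, so breathing defects that only clip a read end are tolerated);
and (e) an uninterrupted helix of ≥ 12 stacked pairs touches the read.

Criterion (e) deserves explanation: base-pair maximization folds even
random sequence into long nested "stems", but those stems are riddled
with 1–3 nt defects. Measured on random 81-nt windows, the longest clean
helix touching a centrally placed 22-nt read never exceeded 10 pairs
(400 draws), while perfect planted hairpins with 22-nt matures never
fell below 16; the default of 12 sits between the two distributions.
With these defaults, planted-hairpin recall at ≥ 2 supporting reads and
precision against random-sequence decoys were both 100% across 60
independent simulation seeds. All five thresholds are parameters of
`HairpinParams`.

Tags whose loci overlap an accepted candidate are folded into it as
variant (isomiR-style) support; the best-supported sequence is the
consensus. Because a read also maps to the minus strand of its own
hairpin's mirror arm when the stem is near-perfect, hits landing within
one window span of an accepted locus are collapsed. A consensus mapping
to several distant loci is reported once per locus with identical counts
— multi-mapped support cannot be attributed to either copy, and
candidate identifiers (`<chromosome>_<serial>`) are per-locus.

## Two-library comparison

Repertoire overlap is exact set arithmetic over identified miRNA keys.
Fold change is the RPM ratio of library B over A; a feature is *up* when
the ratio exceeds the threshold (default 2), *down* below the
reciprocal, *unchanged* between, *absent* when missing from both, and
infinite when present only in B. The common-novel tally counts candidate
loci with nonzero counts in both libraries, one per locus (so a
two-locus consensus contributes two tallies, matching per-locus candidate
identifiers); it is invariant to row order. qRT-PCR arithmetic is
2^−ΔCt with ΔCt = Ct(target) − Ct(endogenous control).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies
on, not sequencing physics. It emulates: a class mixture patterned on a
cellular small-RNA library (33% miRNA, ~27% structured ncRNA, 38%
unannotated by reads); per-miRNA abundances log-uniform over 5 decades;
isomiR end offsets drawn per end from a symmetric distribution
concentrated at 0 (60% at 0, 15% at ±1, tapering to 0.2% at ±4); a 2%
single-substitution rate; two libraries sharing 14% of their mature-arm
repertoires with the remainder split between them (the shared fraction
follows the bundled dataset's 48-of-342 known-miRNA overlap); perfect
inverted-repeat precursors with 17–26 nt matures, ≥ 8 nt loops and 4 nt
pads so every ±4 offset stays inside the precursor; and 36-nt reads
assembled as insert + adapter + random fill. Quality strings are
constant: base-calling quality filtering is upstream of this package's
scope. Precursor placement, strand, and contaminant reference sequences
are all drawn from one integer seed; identical configurations produce
byte-identical FASTQ and truth tables.

Not modeled: position-dependent error profiles, PCR duplication bias,
adapter ligation bias, imperfect (bulged) precursor stems, overlapping
or clustered genomic features, and non-templated additions. Passing the
recovery tests therefore shows the pipeline's logic is exact under its
own assumptions — correct class partitioning, isomiR offset recovery
within binomial error, 100% planted-hairpin recall — not that those
assumptions hold for any particular instrument or protocol.

Problem sizes used by the test suite and the acceptance script — 20–24
precursors, 50,000 reads per library for recovery checks, 60 folding
oracle sequences, 8 planted hairpins plus 8 decoys — were chosen so each
check has enough statistics to be meaningful (e.g. ≥ 3 binomial SE
resolution on every offset class) while the whole suite stays
desk-runnable.

## Numerical and degenerate-input choices

Percentages use decimal half-up rounding, not float banker's rounding.
An empty library yields an all-zero composition table rather than a
division error. `collapse_tags` sorting, the assignment tie-break, the
representative tie-break and the folding traceback are all fully
deterministic so reruns are byte-identical. Known edge cases: an insert
longer than 32 nt (a maximally 3'-extended 26-nt mature) is discarded by
the length filter, so extreme-offset isomiRs of long matures are
slightly censored — the offset-recovery experiment uses 20–24 nt matures
so that every ±4 variant stays within the 15–32 nt retention window.

## Known limitations

The bundled published tables are summary-level: raw reads for that
experiment were never deposited, so desk checks against it are limited
to arithmetic the printed numbers support (composition percentages,
overlap counts, the 8-up/4-down regulation split, seed positions). One
bundled novel candidate (hsa-miR-chrY_24624) publishes only a 5'-shifted
most-abundant isomiR and no reference mature, so its seed cannot be
recomputed from printed data; the seed checks cover the other 47 rows.
The novel-candidate caller matches exactly during genome mapping
(variants are gathered only after a locus is accepted), does not score
star-arm read support, and reports pairing counts rather than folding
free energies.
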