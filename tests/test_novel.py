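"""Folding, genome mapping, hairpin criteria and novel-candidate calling."""

import numpy as np
import pytest

import exomir as ex
from exomir.novel import HairpinParams, NovelParams
from exomir.util import revcomp
from tests.conftest import random_seq

_PAIRS = {"AT", "TA", "GC", "CG", "GT", "TG"}


def enumerate_max_pairs(seq, min_loop=3):
    """Exhaustive enumeration of all nested pairings; returns the max size."""

    def gen(i, j):
        if j - i <= min_loop:
            yield 0
            return
        for size in gen(i + 1, j):
            yield size
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in _PAIRS:
                for s1 in gen(i + 1, k - 1):
                    for s2 in gen(k + 1, j):
                        yield 1 + s1 + s2

    return max(gen(0, len(seq) - 1)) if seq else 0


def make_hairpin(rng, mature_len=22, stem_extra=8, loop_len=8):
    mature = random_seq(rng, mature_len)
    stem5 = mature + random_seq(rng, stem_extra)
    return mature, stem5 + random_seq(rng, loop_len) + revcomp(stem5)


class TestFold:
    def test_no_complementary_bases_no_pairs(self):
        fold = ex.fold_nussinov("AAAAAAAA")
        assert fold.pair_count == 0 and fold.structure == "." * 8

    def test_simple_stem_loop(self):
        fold = ex.fold_nussinov("GGGAAACCC")
        assert fold.structure == "(((...)))"
        assert fold.pair_count == 3

    def test_min_loop_enforced(self):
        # GC at distance 3 cannot pair: would leave only a 2-nt loop
        fold = ex.fold_nussinov("GAAC")
        assert fold.pair_count == 0

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            ex.fold_nussinov("ACGUN")

    def test_structure_is_well_formed(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            seq = random_seq(rng, 60)
            fold = ex.fold_nussinov(seq)
            assert len(fold.structure) == len(seq)
            depth = 0
            for ch in fold.structure:
                depth += {"(": 1, ")": -1}.get(ch, 0)
                assert depth >= 0
            assert depth == 0
            for i, j in fold.pairs:
                assert seq[i] + seq[j] in _PAIRS
                assert j - i > 3

    @pytest.mark.parametrize("length", [8, 10, 12, 15])
    def test_pair_count_matches_exhaustive_enumeration(self, length):
        rng = np.random.default_rng(length)
        for _ in range(15):
            seq = random_seq(rng, length)
            assert ex.fold_nussinov(seq).pair_count == enumerate_max_pairs(seq)


class TestMapToGenome:
    def test_planted_site_found(self):
        rng = np.random.default_rng(9)
        tag = random_seq(rng, 20)
        genome = {"chr1": random_seq(rng, 200) + tag + random_seq(rng, 200)}
        loci = ex.map_to_genome(tag, genome)
        assert [(" ".join([l.chromosome, str(l.start), str(l.end), l.strand]))
                for l in loci] == ["chr1 201 220 +"]

    def test_reverse_complement_site_reports_minus_strand(self):
        rng = np.random.default_rng(10)
        tag = random_seq(rng, 20)
        genome = {"chr2": random_seq(rng, 50) + revcomp(tag) + random_seq(rng, 50)}
        loci = ex.map_to_genome(tag, genome)
        assert len(loci) == 1 and loci[0].strand == "-"
        assert (loci[0].start, loci[0].end) == (51, 70)

    def test_matches_naive_scan_oracle(self):
        rng = np.random.default_rng(11)
        genome = {"chr1": random_seq(rng, 400), "chr2": random_seq(rng, 300)}
        for L in (6, 8):  # short tags so chance hits occur
            for _ in range(30):
                tag = random_seq(rng, L)
                expected = set()
                for chrom, s in genome.items():
                    for i in range(len(s) - L + 1):
                        if s[i : i + L] == tag:
                            expected.add((chrom, i + 1, i + L, "+"))
                        if s[i : i + L] == revcomp(tag):
                            expected.add((chrom, i + 1, i + L, "-"))
                got = {(l.chromosome, l.start, l.end, l.strand) for l in ex.map_to_genome(tag, genome)}
                assert got == expected


class TestExciseWindow:
    def test_windows_match_substring_oracle(self):
        rng = np.random.default_rng(12)
        chrom = random_seq(rng, 500)
        locus = ex.Locus("chr1", 201, 222, "+")
        w5, w3 = ex.excise_window(locus, {"chr1": chrom}, flank=70)
        assert w5.sequence == chrom[190 : 271]
        assert w3.sequence == chrom[151 : 232]
        assert w5.sequence[w5.read_start : w5.read_end] == chrom[200:222]
        assert w3.sequence[w3.read_start : w3.read_end] == chrom[200:222]

    def test_minus_strand_windows_are_reverse_complemented(self):
        rng = np.random.default_rng(13)
        chrom = random_seq(rng, 500)
        tag = revcomp(chrom[200:222])
        locus = ex.map_to_genome(tag, {"chr1": chrom})[0]
        for w in ex.excise_window(locus, {"chr1": chrom}, flank=70):
            assert w.sequence[w.read_start : w.read_end] == tag

    def test_chromosome_edge_is_clipped(self):
        chrom = "ACGT" * 20
        locus = ex.Locus("chr1", 3, 24, "+")
        for w in ex.excise_window(locus, {"chr1": chrom}, flank=70):
            assert 1 <= w.start <= w.end <= len(chrom)


class TestHairpinCheck:
    def test_ideal_hairpin_with_read_in_5p_arm(self):
        rng = np.random.default_rng(14)
        mature, hairpin = make_hairpin(rng)
        fold = ex.fold_nussinov(hairpin)
        ok, diag = ex.hairpin_check(fold, 0, len(mature))
        assert ok and diag["arm"] == "5p"

    def test_read_across_terminal_loop_fails(self):
        rng = np.random.default_rng(15)
        _, hairpin = make_hairpin(rng)
        fold = ex.fold_nussinov(hairpin)
        mid = len(hairpin) // 2
        ok, diag = ex.hairpin_check(fold, mid - 10, mid + 10)
        assert not ok and "loop" in diag["reason"]

    def test_unstructured_sequence_fails(self):
        fold = ex.fold_nussinov("A" * 60)
        ok, diag = ex.hairpin_check(fold, 0, 20)
        assert not ok and diag["reason"] == "no base pairs"

    def test_read_in_3p_arm(self):
        rng = np.random.default_rng(16)
        mature, hairpin = make_hairpin(rng)
        ok, diag = ex.hairpin_check(
            ex.fold_nussinov(hairpin), len(hairpin) - len(mature), len(hairpin)
        )
        assert ok and diag["arm"] == "3p"


class TestCallNovel:
    def _genome_with(self, rng, *blocks, spacing=150):
        parts = [random_seq(rng, 200)]
        for b in blocks:
            parts += [b, random_seq(rng, spacing)]
        return {"chr1": "".join(parts)}

    def test_planted_hairpin_called_with_counts(self):
        rng = np.random.default_rng(21)
        mature, hairpin = make_hairpin(rng)
        genome = self._genome_with(rng, hairpin)
        cands = ex.call_novel({"cells": [ex.ReadTag(mature, 3)]}, genome)
        assert len(cands) == 1
        c = cands[0]
        assert c.consensus_mature_sequence == mature
        assert c.counts == {"cells": 3}
        assert c.arm in ("5p", "3p")
        assert c.candidate_id.startswith("chr1_")

    def test_singleton_support_is_excluded(self):
        rng = np.random.default_rng(22)
        mature, hairpin = make_hairpin(rng)
        genome = self._genome_with(rng, hairpin)
        assert ex.call_novel({"cells": [ex.ReadTag(mature, 1)]}, genome) == []
        # ... and a singleton in one library contributes no counts there
        cands = ex.call_novel(
            {"cells": [ex.ReadTag(mature, 1)], "exosomes": [ex.ReadTag(mature, 5)]},
            genome,
        )
        assert cands and cands[0].counts == {"cells": 0, "exosomes": 5}

    def test_non_hairpin_decoy_rejected(self):
        rng = np.random.default_rng(24)
        decoy = random_seq(rng, 22)
        genome = self._genome_with(rng, decoy)
        assert ex.call_novel({"cells": [ex.ReadTag(decoy, 10)]}, genome) == []

    def test_multi_locus_consensus_reported_once_per_locus(self):
        rng = np.random.default_rng(25)
        mature, hairpin = make_hairpin(rng)
        genome = self._genome_with(rng, hairpin, hairpin, spacing=300)
        cands = ex.call_novel(
            {"cells": [ex.ReadTag(mature, 30)], "exosomes": [ex.ReadTag(mature, 306)]},
            genome,
        )
        assert len(cands) == 2
        assert all(c.counts == {"cells": 30, "exosomes": 306} for c in cands)
        assert all(len(c.loci) == 2 for c in cands)
        assert cands[0].loci == cands[1].loci

    def test_variant_reads_group_into_one_candidate(self):
        rng = np.random.default_rng(26)
        mature, hairpin = make_hairpin(rng)
        genome = self._genome_with(rng, hairpin)
        idx = genome["chr1"].find(hairpin)
        shifted = genome["chr1"][idx + 1 : idx + 1 + len(mature)]
        cands = ex.call_novel(
            {"cells": [ex.ReadTag(mature, 4), ex.ReadTag(shifted, 9)]}, genome
        )
        assert len(cands) == 1
        c = cands[0]
        assert c.counts == {"cells": 13}
        # the best-supported variant is taken as the consensus
        assert c.consensus_mature_sequence == shifted
        assert c.most_abundant_isomir_sequence == shifted
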