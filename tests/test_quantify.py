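"""IsomiR alignment, profiling, seeds and RPM normalization."""

import numpy as np
import pytest

import exomir as ex
from exomir.util import hamming
from tests.conftest import make_precursor, random_seq

MIR21 = "TAGCTTATCAGACTGATGTTGA"


class TestSeed:
    @pytest.mark.parametrize(
        "mature,seed",
        [
            ("TAGCTTATCAGACTGATGTTGA", "AGCTTA"),
            ("AAAAGCTGGGTTGAGAGGGCGA", "AAAGCT"),
            ("TGAGGTAGTAGATTGTATAGTT", "GAGGTA"),
        ],
    )
    def test_positions_2_to_7(self, mature, seed):
        assert ex.extract_seed(mature) == seed

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            ex.extract_seed("ACGTAC")


class TestRpm:
    def test_limits(self):
        assert ex.normalize_rpm(0, 100) == 0.0
        assert ex.normalize_rpm(100, 100) == 1_000_000.0

    def test_hand_computed_value(self):
        assert ex.normalize_rpm(382_634, 9_595_761) == pytest.approx(39_875.3, abs=0.1)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            ex.normalize_rpm(1, 0)


def brute_force_placements(tag_seq, precursor, max_shift=4, max_mismatches=1):
    """Independent oracle: try every placement of the tag on the precursor."""
    hits = set()
    prec = precursor.sequence
    for m in precursor.matures:
        lo, hi = max(0, m.start - max_shift), min(len(prec), m.end + max_shift)
        for p in range(len(prec) - len(tag_seq) + 1):
            if p < lo or p + len(tag_seq) > hi:
                continue
            d = sum(a != b for a, b in zip(tag_seq, prec[p : p + len(tag_seq)]))
            if d <= max_mismatches:
                hits.add((m.arm, p - m.start, (p + len(tag_seq)) - m.end, d))
    return hits


class TestAlign:
    def test_exact_mature_single_candidate(self):
        prec = make_precursor(MIR21)
        cands = ex.align_to_precursor(ex.ReadTag(MIR21, 3), prec)
        exact = [c for c in cands if c.arm == "5p"]
        assert len(exact) == 1
        c = exact[0]
        assert (c.offset5, c.offset3, c.mismatches) == (0, 0, 0)
        assert c.is_reference and c.count == 3

    def test_shift_past_window_is_rejected(self):
        prec = make_precursor(MIR21)
        m = prec.mature("5p")
        shifted = prec.sequence[m.start - 4 : m.end - 5]  # 5' end 5 nt upstream...
        tag = prec.sequence[m.start - 4 : m.end]
        # valid at -4, but a tag reaching 5 nt upstream leaves the window
        assert any(c.offset5 == -4 for c in ex.align_to_precursor(ex.ReadTag(tag, 1), prec))
        prec2 = make_precursor(MIR21, pad="AACCG")
        too_far = prec2.sequence[prec2.mature("5p").start - 5 : prec2.mature("5p").end]
        assert not any(
            c.offset5 == -5 for c in ex.align_to_precursor(ex.ReadTag(too_far, 1), prec2)
        )

    def test_two_mismatches_rejected(self):
        prec = make_precursor(MIR21)
        doubled = "CC" + MIR21[2:]
        assert hamming(doubled, MIR21) == 2
        assert not ex.align_to_precursor(ex.ReadTag(doubled, 1), prec)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            prec = make_precursor(random_seq(rng, int(rng.integers(18, 25))))
            # probe with mature fragments, shifted/mutated variants and noise
            m = prec.mature("5p")
            base = prec.sequence[m.start : m.end]
            probes = [
                base,
                prec.sequence[m.start - 2 : m.end + 1],
                base[:-1] + ("A" if base[-1] != "A" else "C"),
                random_seq(rng, 20),
            ]
            for seq in probes:
                got = {
                    (c.arm, c.offset5, c.offset3, c.mismatches)
                    for c in ex.align_to_precursor(ex.ReadTag(seq, 1), prec)
                }
                assert got == brute_force_placements(seq, prec)


class TestAssign:
    def test_fewest_mismatches_wins(self):
        rng = np.random.default_rng(3)
        mature = random_seq(rng, 22)
        perfect = make_precursor(mature, pid="a-perfect")
        mutated_mature = "A" + mature[1:] if mature[0] != "A" else "C" + mature[1:]
        with_mismatch = make_precursor(mutated_mature, pid="b-mismatch")
        rec = ex.assign_isomirs([ex.ReadTag(mature, 4)], [with_mismatch, perfect])
        assert rec[0].mirna_id == "a-perfect"
        assert rec[0].mismatches == 0

    def test_unplaceable_tag_raises(self):
        prec = make_precursor(MIR21)
        with pytest.raises(ValueError, match="no precursor placement"):
            ex.assign_isomirs([ex.ReadTag("ATATATCGCGCGCGATATAT", 1)], [prec])

    def test_noiseless_assignments_match_truth(self, noiseless):
        refs, reads, truth = noiseless
        truth_parent = {
            o.insert: o.parent_id for o in truth.reads if o.class_name == "miRNA"
        }
        tags, _ = ex.preprocess_reads((s for _, s in reads), ex.SimulationConfig().adapter)
        mirna_tags = [t for t in tags if t.sequence in truth_parent]
        records = ex.assign_isomirs(mirna_tags, refs.precursors)
        for tag, rec in zip(mirna_tags, records):
            assert f"{rec.mirna_id}/{rec.arm}" == truth_parent[tag.sequence]


class TestProfiles:
    def _profiles(self, isomir_counts, library_total=1000):
        prec = make_precursor(MIR21, pid="mir-21")
        tags = [ex.ReadTag(seq, c) for seq, c in isomir_counts]
        recs = ex.assign_isomirs(tags, [prec])
        return ex.profile_mirna(recs, [prec], library_total), prec

    def test_most_abundant_isomir_becomes_representative(self):
        shifted = "C" + MIR21[:-1]  # one-base 5' extension variant...
        prec = make_precursor(MIR21, pid="mir-21")
        shifted = prec.sequence[prec.mature("5p").start - 1 : prec.mature("5p").end - 1]
        profiles, _ = self._profiles([(MIR21, 10), (shifted, 90)])
        p5 = [p for p in profiles if p.arm == "5p"][0]
        assert p5.representative_sequence == shifted
        assert not p5.reference_is_most_abundant
        assert p5.total_count == 100
        assert sum(r.is_most_abundant for r in p5.isomirs) == 1

    def test_single_isomir_is_representative(self):
        profiles, _ = self._profiles([(MIR21, 7)])
        p5 = [p for p in profiles if p.arm == "5p"][0]
        assert p5.representative_sequence == MIR21
        assert p5.reference_is_most_abundant and p5.identified

    def test_identification_requires_a_perfect_read(self):
        mutated = MIR21[:5] + ("A" if MIR21[5] != "A" else "C") + MIR21[6:]
        profiles, _ = self._profiles([(mutated, 50)])
        p5 = [p for p in profiles if p.arm == "5p"][0]
        assert p5.total_count == 50 and not p5.identified

    def test_totals_match_group_by_oracle(self, simulated, refs, small_config):
        reads, _ = simulated
        res = ex.run_library(
            "cells", (s for _, s in reads), refs.precursors, refs.class_refs,
            ex.PipelineConfig(min_count=1),
        )
        mirna_read_total = sum(
            t.count for t in res.tags if res.classes[t.sequence] == "miRNA"
        )
        assert sum(p.total_count for p in res.all_profiles) == mirna_read_total
        total = res.summary.trimmed_read_count
        assert sum(p.normalized_expression for p in res.all_profiles) == pytest.approx(
            1e6 * mirna_read_total / total
        )
        for p in res.all_profiles:
            assert all(r.count <= max(x.count for x in p.isomirs) for r in p.isomirs)
            assert p.representative_sequence in {r.sequence for r in p.isomirs}

    def test_seed_comes_from_reference_mature(self):
        profiles, prec = self._profiles([(MIR21, 3)])
        p5 = [p for p in profiles if p.arm == "5p"][0]
        assert p5.seed == ex.extract_seed(prec.mature_sequence("5p")) == "AGCTTA"


class TestLowExpressionFilter:
    def test_threshold_and_idempotence(self):
        prec = make_precursor(MIR21, pid="mir-21")
        recs = ex.assign_isomirs([ex.ReadTag(MIR21, 1)], [prec])
        profiles = ex.profile_mirna(recs, [prec], 100)
        assert ex.filter_low_expression(profiles) == []
        recs = ex.assign_isomirs([ex.ReadTag(MIR21, 2)], [prec])
        profiles = ex.profile_mirna(recs, [prec], 100)
        kept = ex.filter_low_expression(profiles)
        assert [p.total_count for p in kept if p.arm == "5p"] == [2]
        assert ex.filter_low_expression(kept) == kept


class TestIsomirReport:
    def test_arm_totals_and_roundtrip(self, tmp_path):
        from exomir import io as eio

        prec = make_precursor(MIR21, pid="mir-21", loop="ACGTACGTA")
        shifted = prec.sequence[prec.mature("5p").start + 1 : prec.mature("5p").end + 1]
        tags = [ex.ReadTag(MIR21, 10), ex.ReadTag(shifted, 4)]
        recs = ex.assign_isomirs(tags, [prec])
        profile = [
            p for p in ex.profile_mirna(recs, [prec], 100) if p.arm == "5p"
        ][0]
        report = ex.isomir_report(profile, prec)
        assert report["arm_totals"]["5p"] == 14
        assert report["most_abundant"]["count"] == 10
        assert len(report["structure"]) == len(prec.sequence)
        path = tmp_path / "report.tsv"
        eio.write_isomir_report(report, path)
        back = eio.read_isomir_rows(path)
        assert len(back) == len(report["isomirs"])
        assert list(back["count"]) == [r["count"] for r in report["isomirs"]]
        assert list(back["sequence"]) == [r["sequence"] for r in report["isomirs"]]
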