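"""Gap inventory, closure classification, repeat intersection, telomeres."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from triobin import gaps, simulate
from triobin.gaps import (
    CLOSED,
    OPEN,
    TRANS_SCAFFOLD,
    UNPLACED,
    GapRecord,
    classify_gap_closure,
    compare_closures,
    extract_gap_flanks,
    find_assembly_gaps,
    find_telomeres,
    intersect_repeats,
    telomere_null_pvalue,
)


class TestFindAssemblyGaps:
    def test_no_n_no_gaps(self):
        assert find_assembly_gaps({"c": "ACGT" * 100}) == []

    def test_single_run_interval(self):
        (g,) = find_assembly_gaps({"c": "AC" + "N" * 50 + "GT"})
        assert (g.start, g.end) == (2, 52)

    def test_runs_separated_by_one_base_stay_separate(self):
        found = find_assembly_gaps({"c": "N" * 10 + "A" + "N" * 12})
        assert [(g.start, g.end) for g in found] == [(0, 10), (11, 23)]

    def test_short_runs_ignored(self):
        assert find_assembly_gaps({"c": "AC" + "N" * 9 + "GT"}) == []
        assert find_assembly_gaps({"c": "ac" + "n" * 10 + "gt"}) != []


class TestExtractGapFlanks:
    REF = {"c": "A" * 1000 + "N" * 100 + "G" * 1000}

    def test_flank_arithmetic(self):
        g = GapRecord("c", 1000, 1100, "gap1")
        (pair,), seqs = extract_gap_flanks(self.REF, [g])
        assert pair.five_prime == ("c", 500, 1000)
        assert pair.three_prime == ("c", 1100, 1600)
        assert seqs["gap1_5p"] == "A" * 500
        assert seqs["gap1_3p"] == "G" * 500

    def test_truncated_flank_flagged(self):
        ref = {"c": "A" * 100 + "N" * 50 + "G" * 1000}
        g = GapRecord("c", 100, 150, "gap1")
        (pair,), seqs = extract_gap_flanks(ref, [g])
        assert pair.truncated_5p and not pair.truncated_3p
        assert len(seqs["gap1_5p"]) == 100

    def test_adjacent_gap_overlap_flagged(self):
        ref = {"c": "A" * 300 + "N" * 20 + "C" * 200 + "N" * 20 + "G" * 300}
        found = find_assembly_gaps(ref)
        pairs, _ = extract_gap_flanks(ref, found)
        assert pairs[0].overlaps_adjacent_gap and pairs[1].overlaps_adjacent_gap


def _aln(name, scaf, start, length=500, reverse=False, refs=None):
    refs = refs or {"s1": 500_000, "s2": 500_000}
    header = pysam.AlignmentHeader.from_references(list(refs), list(refs.values()))
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.query_sequence = "A" * length
    rec.flag = 0x10 if reverse else 0
    rec.reference_id = list(refs).index(scaf)
    rec.reference_start = start
    rec.mapping_quality = 60
    rec.cigartuples = [(0, length)]
    rec.set_tag("AS", length)
    return rec


class TestClassifyGapClosure:
    def test_closed_within_distance(self):
        alns = [_aln("g1_5p", "s1", 0), _aln("g1_3p", "s1", 2_500)]
        (call,) = classify_gap_closure(alns, [], gap_ids=["g1"])
        assert call.status == CLOSED and call.separation == 2_000

    def test_exact_100kb_boundary(self):
        alns = [_aln("g1_5p", "s1", 0), _aln("g1_3p", "s1", 100_500)]
        (call,) = classify_gap_closure(alns, [], gap_ids=["g1"])
        assert call.status == CLOSED and call.separation == 100_000
        alns = [_aln("g1_5p", "s1", 0), _aln("g1_3p", "s1", 100_501)]
        (call,) = classify_gap_closure(alns, [], gap_ids=["g1"])
        assert call.status == OPEN

    def test_trans_scaffold(self):
        alns = [_aln("g1_5p", "s1", 0), _aln("g1_3p", "s2", 0)]
        (call,) = classify_gap_closure(alns, [], gap_ids=["g1"])
        assert call.status == TRANS_SCAFFOLD

    def test_intervening_target_gap_blocks_closure(self):
        alns = [_aln("g1_5p", "s1", 0), _aln("g1_3p", "s1", 2_500)]
        target_gaps = [GapRecord("s1", 1_000, 1_050, "t1")]
        (call,) = classify_gap_closure(alns, target_gaps, gap_ids=["g1"])
        assert call.status == OPEN

    def test_unplaced_when_flank_missing(self):
        alns = [_aln("g1_5p", "s1", 0)]
        (call,) = classify_gap_closure(alns, [], gap_ids=["g1"])
        assert call.status == UNPLACED

    def test_discordant_orientation_not_closed(self):
        alns = [_aln("g1_5p", "s1", 0), _aln("g1_3p", "s1", 2_500, reverse=True)]
        (call,) = classify_gap_closure(alns, [], gap_ids=["g1"])
        assert call.status == OPEN and not call.orientation_ok

    def test_multiple_primaries_rejected(self):
        alns = [_aln("g1_5p", "s1", 0), _aln("g1_5p", "s1", 100)]
        with pytest.raises(ValueError, match="primary"):
            classify_gap_closure(alns, [], gap_ids=["g1"])

    def test_fixture_truth_recovered(self, tiny_config):
        fx = simulate.make_gap_fixture(tiny_config)
        for label, asm in fx.targets.items():
            calls = classify_gap_closure(
                fx.flank_sams[label], find_assembly_gaps(asm)
            )
            got = {c.gap_id: c.status for c in calls}
            want = (
                fx.truth.gaps.query("target == @label")
                .set_index("gap_id")["status"]
                .to_dict()
            )
            assert got == want


class TestCompareClosures:
    def _calls(self, statuses):
        return [
            gaps.ClosureCall(f"g{i}", s, (), None) for i, s in enumerate(statuses)
        ]

    def test_identical_lists_diagonal(self):
        calls = self._calls([CLOSED, OPEN, TRANS_SCAFFOLD])
        table = compare_closures(calls, calls)
        assert table.values.sum() == 3
        assert table.loc[CLOSED, CLOSED] == 1
        assert table.attrs["discordant_closed"] == []

    def test_constructed_cells(self):
        a = self._calls([CLOSED] * 5)
        b = self._calls([CLOSED] * 3 + [OPEN] * 2)
        table = compare_closures(a, b)
        assert table.loc[CLOSED, CLOSED] == 3
        assert table.loc[CLOSED, OPEN] == 2
        assert table.attrs["discordant_closed"] == ["g3", "g4"]

    def test_empty_inventory(self):
        table = compare_closures([], [])
        assert table.values.sum() == 0

    def test_inventory_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_closures(self._calls([CLOSED]), self._calls([CLOSED, OPEN]))


def brute_force_overlaps(interval, repeats):
    """Per-base oracle: a repeat overlaps iff any base index is shared."""
    chrom, start, end = interval[:3]
    hits = {}
    for rc, rs, re, name in repeats:
        if rc == chrom and set(range(rs, re)) & set(range(start, end)):
            hits[name] = hits.get(name, 0) + 1
    return hits


class TestIntersectRepeats:
    def test_no_repeats_zero(self):
        df = intersect_repeats([("c", 0, 100, "f1")], [])
        assert df["count"].sum() == 0

    def test_abutting_repeat_not_counted(self):
        df = intersect_repeats([("c", 100, 200, "f1")], [("c", 200, 300, "L1")])
        assert df["count"].sum() == 0
        df = intersect_repeats([("c", 100, 200, "f1")], [("c", 199, 300, "L1")])
        assert df["count"].sum() == 1

    def test_planted_overlaps(self, tiny_config):
        fx = simulate.make_gap_fixture(tiny_config)
        ref_gaps = find_assembly_gaps(fx.reference)
        pairs, _ = extract_gap_flanks(fx.reference, ref_gaps)
        intervals = [(*p.five_prime, f"{p.gap_id}_5p") for p in pairs]
        df = intersect_repeats(intervals, fx.repeats)
        assert int(df["count"].sum()) == 4

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(8)
        repeats = [
            ("c", int(s), int(s) + int(l), ["L1", "BovB"][int(i) % 2])
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 5_000, 40), rng.integers(1, 400, 40))
            )
        ]
        intervals = [
            ("c", int(s), int(s) + 300, f"iv{j}")
            for j, s in enumerate(rng.integers(0, 5_000, 15))
        ]
        df = intersect_repeats(intervals, repeats)
        for iv in intervals:
            want = brute_force_overlaps(iv, repeats)
            got = {
                r.repeat_class: r.count
                for r in df[df["interval"] == iv[3]].itertuples()
                if r.count > 0
            }
            assert got == want


class TestTelomeres:
    def test_threshold_boundary(self, tiny_config):
        seqs = simulate.make_telomere_fixture(tiny_config, repeat_counts=(8, 5, 4, 0))
        calls = {c.seq_id: c for c in find_telomeres(seqs)}
        assert calls["seq1_n8"].is_telomeric and calls["seq1_n8"].count >= 8
        assert calls["seq2_n5"].is_telomeric
        assert not calls["seq3_n4"].is_telomeric
        assert calls["seq4_n0"].count == 0

    def test_poly_a_zero(self):
        (c,) = find_telomeres({"s": "A" * 2000})
        assert c.count == 0 and not c.is_telomeric

    def test_short_sequence_flagged(self):
        (c,) = find_telomeres({"s": "TTAGGG" * 10})
        assert c.truncated_window and c.is_telomeric

    def test_motif_only_in_terminal_window(self):
        seq = "TTAGGG" * 10 + "A" * 2000
        (c,) = find_telomeres({"s": seq})
        assert c.count == 0


class TestTelomereNull:
    def test_zero_count_certain(self):
        assert telomere_null_pvalue(0) == 1.0

    def test_monotone_nonincreasing(self):
        values = [telomere_null_pvalue(c) for c in range(8)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_quick_montecarlo_agreement_at_count_one(self):
        """Cheap cross-check of the Poisson tail against direct simulation in
        a regime where few replicates suffice (count 1 has p ~ 0.22)."""
        rng = np.random.default_rng(12)
        mc = gaps.telomere_null_montecarlo(1, 100_000, rng, batch=20_000)
        expected = telomere_null_pvalue(1)
        assert abs(mc - expected) / expected <= 0.05
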