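"""Paired-end scaffolding: links, bundles, het masking, building, rectification."""

import math

import pytest

from dbgasm.graph import Unitig
from dbgasm.io_config import Library, Read
from dbgasm.kmer import revcomp
from dbgasm.multik import ReadPlacement, map_reads_to_contigs
from dbgasm.scaffold import (LinkBundle, Scaffold, ScaffoldPart,
                             build_scaffolds, bundle_links, collect_pe_links,
                             detect_het_pairs, recover_weak_links,
                             rectify_chimeras, scaffold_pipeline)
from dbgasm.sim import make_diploid_region, simulate_genome, \
    simulate_pe_library

from conftest import make_truth_layout


LIB = Library(name="pe500", avg_ins=500, ins_sd=20, rank=1)


def _pair(rid, seq1="A" * 100, seq2="A" * 100):
    r1 = Read(f"{rid}/1", seq1, mate_id=f"{rid}/2", library=LIB)
    r2 = Read(f"{rid}/2", seq2, mate_id=f"{rid}/1", library=LIB)
    return r1, r2


class TestCollectLinks:
    def test_gap_formula(self):
        # d_a = 150 (read at offset 850 on a 1000 bp contig), d_b = 150
        r1, r2 = _pair("p")
        placements = [
            ReadPlacement("p/1", 0, 850, "+", 0),
            ReadPlacement("p/2", 1, 50, "-", 0),
        ]
        out = collect_pe_links(placements, [r1, r2], {0: 1_000, 1: 2_000})
        (link,) = out.links
        assert link.gap_obs == 500 - 150 - 150 == 200
        assert (link.end_a, link.end_b) == ("R", "L")

    def test_same_contig_pair_feeds_insert_reestimation(self):
        r1, r2 = _pair("p")
        placements = [
            ReadPlacement("p/1", 0, 100, "+", 0),
            ReadPlacement("p/2", 0, 520, "-", 0),
        ]
        out = collect_pe_links(placements, [r1, r2], {0: 1_000})
        assert out.links == []
        assert out.insert_samples["pe500"] == [520]

    def test_unplaced_mate_yields_nothing(self):
        r1, r2 = _pair("p")
        out = collect_pe_links([ReadPlacement("p/1", 0, 100, "+", 0)],
                               [r1, r2], {0: 1_000})
        assert out.links == [] and out.insert_samples == {}

    def test_orientation_violation_counted(self):
        r1, r2 = _pair("p")
        placements = [
            ReadPlacement("p/1", 0, 100, "+", 0),
            ReadPlacement("p/2", 0, 520, "+", 0),  # same strand: discordant
        ]
        out = collect_pe_links(placements, [r1, r2], {0: 1_000})
        assert out.orientation_violations == 1


class TestBundleLinks:
    def _links(self, gaps, rid0=0, orient=("R", "L")):
        from dbgasm.scaffold import PELink
        return [PELink(0, 1, orient[0], orient[1], g, LIB, f"p{rid0 + i}")
                for i, g in enumerate(gaps)]

    def test_support_and_trimmed_mean(self):
        res = bundle_links(self._links([190, 200, 210, 205, 195]), 3)
        (b,) = res.accepted
        assert b.support == 5
        assert b.gap_mean == pytest.approx(200)
        assert b.gap_sd == pytest.approx(LIB.ins_sd / math.sqrt(5))

    def test_outlier_beyond_3sd_trimmed(self):
        res = bundle_links(self._links([200, 200, 200, 200, 500]), 3)
        (b,) = res.accepted
        assert b.gap_mean == pytest.approx(200)
        assert b.support == 5  # support counts pairs, trimming only the mean

    def test_low_support_goes_to_weak(self):
        res = bundle_links(self._links([200, 210]), 3)
        assert res.accepted == []
        assert len(res.weak) == 1 and res.weak[0].status == "weak"

    def test_conflicting_orientations_majority_wins(self):
        links = self._links([200, 205, 210, 195]) + \
                self._links([400], rid0=10, orient=("R", "R"))
        res = bundle_links(links, 3)
        (b,) = res.accepted
        assert b.support == 4 and (b.end_a, b.end_b) == ("R", "L")
        (c,) = res.conflicts
        assert c.status == "conflict" and c.support == 1


def _bundle(a, b, ea, eb, support=10, gap=100.0, rank=1, sd=5.0):
    return LinkBundle(contig_a=a, contig_b=b, end_a=ea, end_b=eb,
                      support=support, gap_mean=gap, gap_sd=sd, rank=rank)


class TestDetectHetPairs:
    def _contigs(self):
        # 0 and 4: 2 kb flanks at full depth; 1,2: allelic pair at half depth
        return [Unitig(0, "A" * 2_000, 0), Unitig(1, "C" * 1_500, 0),
                Unitig(2, "G" * 1_400, 0), Unitig(4, "T" * 2_000, 0)]

    def _bundles(self):
        return [_bundle(0, 1, "R", "L"), _bundle(0, 2, "R", "L"),
                _bundle(1, 4, "R", "L"), _bundle(2, 4, "R", "L")]

    def test_allelic_pair_detected_higher_depth_kept(self):
        depth = {0: 40.0, 1: 21.0, 2: 18.0, 4: 40.0}
        pairs = detect_het_pairs(self._contigs(), self._bundles(), depth)
        assert pairs == [(1, 2)]

    def test_full_depth_contig_not_flagged(self):
        depth = {0: 40.0, 1: 39.0, 2: 18.0, 4: 40.0}
        assert detect_het_pairs(self._contigs(), self._bundles(), depth) == []

    def test_equal_depth_tie_keeps_smaller_id(self):
        depth = {0: 40.0, 1: 20.0, 2: 20.0, 4: 40.0}
        assert detect_het_pairs(self._contigs(), self._bundles(), depth) == \
            [(1, 2)]

    def test_length_ratio_guard(self):
        contigs = self._contigs()
        contigs[2] = Unitig(2, "G" * 400, 0)  # < half the partner length
        depth = {0: 40.0, 1: 20.0, 2: 19.0, 4: 40.0}
        assert detect_het_pairs(contigs, self._bundles(), depth) == []


class TestBuildScaffolds:
    def test_single_contig_no_bundles(self):
        contigs = [Unitig(0, "ACGT" * 100, 0)]
        (s,) = build_scaffolds(contigs, [])
        assert s.contig_ids() == [0]
        assert s.sequence({0: contigs[0].seq}) == contigs[0].seq

    def test_negative_gap_rendered_with_min_wildcard(self):
        contigs = [Unitig(0, "A" * 500, 0), Unitig(1, "C" * 500, 0)]
        bundles = [_bundle(0, 1, "R", "L", gap=-10.0)]
        scaffolds = build_scaffolds(contigs, bundles)
        (s,) = scaffolds
        part = next(p for p in s.parts if p.gap_after is not None)
        assert part.gap_after == -10  # signed estimate retained
        seq = s.sequence({0: "A" * 500, 1: "C" * 500})
        assert seq == "A" * 500 + "N" + "C" * 500

    def test_ambiguous_branching_left_unjoined(self):
        contigs = [Unitig(i, "ACGT" * 250, 0) for i in range(3)]
        bundles = [_bundle(0, 1, "R", "L", gap=100),
                   _bundle(0, 2, "R", "L", gap=105)]  # two rivals for 0:R
        scaffolds = build_scaffolds(contigs, bundles)
        assert sorted(len(s.parts) for s in scaffolds) == [1, 1, 1]

    def test_transitive_edge_removed_and_chain_built(self):
        contigs = [Unitig(i, "ACGT" * 250, 0) for i in range(3)]
        # 0-1 (gap 100), 1-2 (gap 50), redundant 0-2 (gap 100+1000+50)
        bundles = [_bundle(0, 1, "R", "L", gap=100),
                   _bundle(1, 2, "R", "L", gap=50),
                   _bundle(0, 2, "R", "L", gap=1_150, support=4)]
        (s,) = build_scaffolds(contigs, bundles)
        assert [p.contig_id for p in s.parts] == [0, 1, 2]

    def test_masked_contigs_excluded(self):
        contigs = [Unitig(i, "ACGT" * 250, 0) for i in range(2)]
        bundles = [_bundle(0, 1, "R", "L", gap=100)]
        scaffolds = build_scaffolds(contigs, bundles, masked={1})
        assert [s.contig_ids() for s in scaffolds] == [[0]]


class TestEndToEndLayout:
    def test_truth_layout_recovered(self):
        gt, contigs, true_gaps = make_truth_layout(3)
        lib1 = Library(name="pe500", avg_ins=500, ins_sd=20, rank=1)
        lib2 = Library(name="mp5k", avg_ins=5_000, ins_sd=300, rank=2)
        r1a, r2a, _ = simulate_pe_library(gt, lib1, 100, coverage=30, seed=8)
        r1b, r2b, _ = simulate_pe_library(gt, lib2, 100, coverage=15, seed=9)
        res = scaffold_pipeline(contigs, r1a + r2a + r1b + r2b,
                                detect_het=False)
        big = max(res.scaffolds, key=lambda s: len(s.parts))
        layout = [(p.contig_id, p.orient) for p in big.parts]
        assert layout == [(i, "+") for i in range(10)] or \
            layout == [(9 - i, "-") for i in range(10)]
        # conservation: every contig in exactly one scaffold
        seen = [c for s in res.scaffolds for c in s.contig_ids()]
        assert sorted(seen) == list(range(10))

    def test_contig_length_conserved_in_scaffold(self):
        gt, contigs, _ = make_truth_layout(4)
        lib = Library(name="pe500", avg_ins=500, ins_sd=20, rank=1)
        r1, r2, _ = simulate_pe_library(gt, lib, 100, coverage=30, seed=10)
        res = scaffold_pipeline(contigs, r1 + r2, detect_het=False)
        lengths = {c.id: len(c.seq) for c in contigs}
        for s in res.scaffolds:
            seq = s.sequence({c.id: c.seq for c in contigs})
            assert len(seq) - seq.count("N") == \
                sum(lengths[c] for c in s.contig_ids())


class TestRectifyChimeras:
    def test_no_higher_rank_is_noop(self):
        s = Scaffold(0, [ScaffoldPart(0, "+", 50), ScaffoldPart(1, "+", None)])
        out, n = rectify_chimeras([s], [], {0: 1_000, 1: 1_000})
        assert n == 0 and out[0].parts == s.parts

    def test_false_join_cut_true_join_kept(self):
        # scaffold 0-1 true (spanned), scaffold with false junction 2|5
        lengths = {i: 1_000 for i in range(6)}
        chimera = Scaffold(0, [ScaffoldPart(2, "+", 50),
                               ScaffoldPart(5, "+", None)])
        true_s = Scaffold(1, [ScaffoldPart(0, "+", 50),
                              ScaffoldPart(1, "+", None)])
        hi = [
            _bundle(0, 1, "R", "L", support=8, gap=50, rank=2, sd=30),  # spans
            _bundle(2, 3, "R", "L", support=5, gap=60, rank=2, sd=30),  # 2 elsewhere
        ]
        out, n = rectify_chimeras([chimera, true_s], hi, lengths)
        assert n == 1
        assert sorted(tuple(s.contig_ids()) for s in out) == \
            [(0, 1), (2,), (5,)]


class TestRecoverWeakLinks:
    def test_weak_link_accepted_via_corroborating_path(self):
        # truth: A(0) - C(1) - B(2); C is not scaffoldable (masked), so A and
        # B are singletons; accepted bundles A-C and C-B imply A-B layout
        lengths = {0: 1_000, 1: 500, 2: 1_000}
        scaffolds = [Scaffold(0, [ScaffoldPart(0, "+", None)]),
                     Scaffold(2, [ScaffoldPart(2, "+", None)])]
        accepted = [_bundle(0, 1, "R", "L", gap=50),
                    _bundle(1, 2, "R", "L", gap=40)]
        weak = [_bundle(0, 2, "R", "L", support=2, gap=590, sd=15)]
        out, recovered = recover_weak_links(scaffolds, accepted, weak, lengths)
        assert len(recovered) == 1 and recovered[0].status == "recovered"
        (s,) = out
        assert [p.contig_id for p in s.parts] == [0, 2]

    def test_unique_dead_end_candidate_accepted(self):
        lengths = {0: 1_000, 2: 1_000}
        scaffolds = [Scaffold(0, [ScaffoldPart(0, "+", None)]),
                     Scaffold(2, [ScaffoldPart(2, "+", None)])]
        weak = [_bundle(0, 2, "R", "L", support=2, gap=100)]
        out, recovered = recover_weak_links(scaffolds, [], weak, lengths)
        assert len(recovered) == 1 and len(out) == 1

    def test_conflicting_candidates_between_hubs_rejected(self):
        lengths = {i: 1_000 for i in range(4)}
        scaffolds = [Scaffold(i, [ScaffoldPart(i, "+", None)])
                     for i in range(4)]
        # 0:R is a hub with accepted links elsewhere; weak 0-3 conflicts
        accepted = [_bundle(0, 1, "R", "L", gap=50),
                    _bundle(0, 2, "R", "L", gap=55)]
        weak = [_bundle(0, 3, "R", "L", support=2, gap=60)]
        out, recovered = recover_weak_links(scaffolds, accepted, weak, lengths)
        assert recovered == [] and len(out) == 4

    def test_duplicate_of_existing_join_ignored(self):
        lengths = {0: 1_000, 1: 1_000}
        joined = Scaffold(5, [ScaffoldPart(0, "+", 50),
                              ScaffoldPart(1, "+", None)])
        weak = [_bundle(0, 1, "R", "L", support=2, gap=50)]
        out, recovered = recover_weak_links([joined], [], weak, lengths)
        assert recovered == [] and out == [joined]


class TestHetPipeline:
    def test_diploid_allelic_contig_masked_and_scaffold_built(self):
        gt = simulate_genome(24_000, seed=21)
        dip = make_diploid_region(gt, 0.02, 10_000, 13_000, seed=22)
        g0, g1 = dip.haplotypes
        # truth contigs: flanks (full depth) + the two alleles of the middle
        contigs = [
            Unitig(0, g0[:9_800], 0),
            Unitig(1, g0[10_000:13_000], 0),   # allele 0
            Unitig(2, g1[10_000:13_000], 0),   # allele 1
            Unitig(3, g0[13_200:], 0),
        ]
        lib = Library(name="pe500", avg_ins=500, ins_sd=20, rank=1)
        r1, r2, _ = simulate_pe_library(dip, lib, 100, coverage=40, seed=23)
        res = scaffold_pipeline(contigs, r1 + r2)
        assert len(res.het_pairs) == 1
        kept, dropped = res.het_pairs[0]
        assert {kept, dropped} == {1, 2}
        assert res.depth[kept] >= res.depth[dropped]
        # dropped allele in no scaffold; kept allele scaffolded with flanks
        for s in res.scaffolds:
            assert dropped not in s.contig_ids()
        big = max(res.scaffolds, key=lambda s: len(s.parts))
        assert set(big.contig_ids()) == {0, kept, 3}
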