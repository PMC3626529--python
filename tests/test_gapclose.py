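"""Gap closing: recruitment, cumulative consensus, closure and safety rails."""

import numpy as np
import pytest

from dbgasm.gapclose import (AssignedRead, GapTask, assign_reads_to_gaps,
                             close_gaps, extend_cycle, find_gap_tasks,
                             resolve_conflict)
from dbgasm.graph import Unitig
from dbgasm.io_config import Library, Read
from dbgasm.kmer import revcomp
from dbgasm.multik import ReadPlacement
from dbgasm.scaffold import Scaffold, ScaffoldPart
from dbgasm.sim import simulate_genome, simulate_pe_library

from conftest import make_truth_layout


class TestResolveConflict:
    def test_clear_majority(self):
        assert resolve_conflict({"A": 6.0, "G": 1.0}) == "A"

    def test_close_race_is_ambiguous(self):
        assert resolve_conflict({"A": 5.0, "G": 4.5}) is None

    def test_single_vote(self):
        assert resolve_conflict({"C": 1.0}) == "C"

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            resolve_conflict({})


class TestAssignReads:
    def _setup(self):
        lib = Library(name="l", avg_ins=500, ins_sd=20, rank=1)
        scaf = Scaffold(0, [ScaffoldPart(0, "+", 150),
                            ScaffoldPart(1, "+", None)])
        contig_lengths = {0: 2_000, 1: 2_000}
        tasks = [GapTask(0, 0, "A" * 140, "C" * 140, 150)]
        return lib, scaf, contig_lengths, tasks

    def test_mate_near_gap_recruits_read(self):
        lib, scaf, lens, tasks = self._setup()
        # mate 300 bp left of the gap end of contig 0, pointing right
        r = Read("p/1", "G" * 100, mate_id="p/2", library=lib)
        m = Read("p/2", "T" * 100, mate_id="p/1", library=lib)
        placements = [ReadPlacement("p/2", 0, 1_600, "+", 0)]
        assign_reads_to_gaps(tasks, [scaf], placements, [r, m], lens)
        assert tasks[0].has_read("p/1")
        (a,) = tasks[0].assigned_reads
        assert a.seq == revcomp("G" * 100)  # oriented to scaffold plus strand

    def test_mate_far_from_gap_not_recruited(self):
        lib, scaf, lens, tasks = self._setup()
        r = Read("p/1", "G" * 100, mate_id="p/2", library=lib)
        m = Read("p/2", "T" * 100, mate_id="p/1", library=lib)
        placements = [ReadPlacement("p/2", 0, 100, "+", 0)]  # ~1.9 kb away
        assign_reads_to_gaps(tasks, [scaf], placements, [r, m], lens)
        assert tasks[0].assigned_reads == []

    def test_well_placed_read_not_recruited(self):
        lib, scaf, lens, tasks = self._setup()
        r = Read("p/1", "G" * 100, mate_id="p/2", library=lib)
        m = Read("p/2", "T" * 100, mate_id="p/1", library=lib)
        placements = [ReadPlacement("p/2", 0, 1_600, "+", 0),
                      ReadPlacement("p/1", 1, 300, "-", 0)]
        assign_reads_to_gaps(tasks, [scaf], placements, [r, m], lens)
        assert tasks[0].assigned_reads == []


def _mk_read(seq, rid, cycle, side="L"):
    return AssignedRead(seq=seq, read_id=rid, cycle_first_seen=cycle,
                        side=side)


class TestCumulativeVsLegacy:
    def _conflict_task(self):
        """Column where cycle-1 readers vote G (5 reads) and cycle-2 readers
        vote A (2 reads)."""
        rng = np.random.default_rng(77)
        flank = "".join(rng.choice(list("ACGT"), size=60))
        true_next = "G"
        wrong_next = "A"
        early = [_mk_read(flank[-30:] + true_next + "CATG", f"e{i}", 1)
                 for i in range(5)]
        late = [_mk_read(flank[-30:] + wrong_next + "CATG", f"l{i}", 2)
                for i in range(2)]
        task = GapTask(0, 0, flank, "T" * 60, 10)
        task.assigned_reads = early + late
        return task, true_next, wrong_next

    def test_cumulative_rule_keeps_early_majority(self):
        task, true_next, _ = self._conflict_task()
        extend_cycle(task, cycle=2, k_fill=25)
        assert task.ext_left[0] == true_next

    def test_legacy_rule_follows_current_cycle_only(self):
        task, _, wrong_next = self._conflict_task()
        extend_cycle(task, cycle=2, k_fill=25, legacy_cycle_local=True)
        assert task.ext_left[0] == wrong_next

    def test_zero_assigned_reads_no_extension(self):
        task = GapTask(0, 0, "A" * 60, "C" * 60, 100)
        extend_cycle(task, cycle=1)
        assert task.ext_left == "" and task.ext_right == ""


@pytest.fixture(scope="module")
def gap_fixture():
    """Truth layout with 10 gaps plus 40x reads over the full genome."""
    gt, contigs, true_gaps = make_truth_layout(9, n_contigs=11,
                                               gap_len=(100, 400))
    g = gt.haplotypes[0]
    parts, pos, fills = [], 0, []
    for i, c in enumerate(contigs):
        pos += len(c.seq)
        if i < len(contigs) - 1:
            fills.append(g[pos : pos + true_gaps[i]])
            parts.append(ScaffoldPart(i, "+", true_gaps[i]))
            pos += true_gaps[i]
        else:
            parts.append(ScaffoldPart(i, "+", None))
    scaf = Scaffold(100, parts)
    lib = Library(name="pe500", avg_ins=500, ins_sd=20, rank=1)
    r1, r2, _ = simulate_pe_library(gt, lib, 100, coverage=40, seed=10)
    return gt, contigs, scaf, fills, r1 + r2


class TestCloseGaps:
    def test_unique_gaps_closed_exactly(self, gap_fixture):
        gt, contigs, scaf, fills, reads = gap_fixture
        rendered, results, ntrace = close_gaps([scaf], reads, contigs)
        closed = [r for r in results if r.status == "closed"]
        assert len(closed) >= 9
        for r in closed:
            assert r.fill_seq == fills[r.gap_index]

    def test_flanks_byte_stable(self, gap_fixture):
        gt, contigs, scaf, fills, reads = gap_fixture
        rendered, results, _ = close_gaps([scaf], reads, contigs)
        ((_, seq),) = rendered
        # contig sequence outside gaps is untouched
        assert seq.startswith(contigs[0].seq)
        assert seq.endswith(contigs[-1].seq)
        for c in contigs:
            assert c.seq in seq

    def test_n_count_never_increases(self, gap_fixture):
        gt, contigs, scaf, fills, reads = gap_fixture
        _, _, ntrace = close_gaps([scaf], reads, contigs)
        assert all(b <= a for a, b in zip(ntrace, ntrace[1:]))

    def test_closed_assembly_matches_genome(self, gap_fixture):
        gt, contigs, scaf, fills, reads = gap_fixture
        rendered, results, _ = close_gaps([scaf], reads, contigs)
        if all(r.status == "closed" for r in results):
            # the truth layout may not use the genome's trailing bases
            assert gt.haplotypes[0].startswith(rendered[0][1])

    def test_no_gaps_is_byte_identical_noop(self, small_genome):
        contigs = [Unitig(0, small_genome.haplotypes[0][:4_000], 0)]
        scaf = Scaffold(0, [ScaffoldPart(0, "+", None)])
        rendered, results, ntrace = close_gaps([scaf], [], contigs)
        assert rendered == [(0, contigs[0].seq)]
        assert results == [] and ntrace == [0]

    def test_negative_gap_closed_by_flank_overlap(self):
        gt = simulate_genome(4_000, seed=61)
        g = gt.haplotypes[0]
        # contigs overlap by 40 bp: signed gap -40
        contigs = [Unitig(0, g[:2_020], 0), Unitig(1, g[1_980:], 0)]
        scaf = Scaffold(0, [ScaffoldPart(0, "+", -40),
                            ScaffoldPart(1, "+", None)])
        rendered, results, _ = close_gaps([scaf], [], contigs)
        (r,) = results
        assert r.status == "closed"
        assert rendered[0][1] == g

    def test_repeat_gap_never_misjoined(self):
        # the gap lies inside one copy of a diverged 2-copy repeat longer
        # than the read length: closing must not paste the wrong copy
        rng = np.random.default_rng(5)
        unit = "".join(rng.choice(list("ACGT"), size=300))
        unit2 = list(unit)
        for p in range(10, 300, 35):  # ~3% divergence between copies
            unit2[p] = "A" if unit2[p] != "A" else "C"
        unit2 = "".join(unit2)
        left = "".join(rng.choice(list("ACGT"), size=2_000))
        mid = "".join(rng.choice(list("ACGT"), size=2_000))
        right = "".join(rng.choice(list("ACGT"), size=2_000))
        genome = left + unit + mid + unit2 + right
        from dbgasm.sim import GenomeTruth
        gt = GenomeTruth(haplotypes=[genome])
        # gap covers the middle of unit2
        cut0 = len(left) + len(unit) + len(mid) + 100
        cut1 = cut0 + 150
        contigs = [Unitig(0, genome[:cut0], 0), Unitig(1, genome[cut1:], 0)]
        scaf = Scaffold(0, [ScaffoldPart(0, "+", 150),
                            ScaffoldPart(1, "+", None)])
        lib = Library(name="l", avg_ins=500, ins_sd=20, rank=1)
        r1, r2, _ = simulate_pe_library(gt, lib, 100, coverage=40, seed=6)
        rendered, results, _ = close_gaps([scaf], r1 + r2, contigs)
        (r,) = results
        truth_fill = genome[cut0:cut1]
        if r.status == "closed":
            assert r.fill_seq == truth_fill
        else:
            assert r.status in ("partial", "open")


def test_find_gap_tasks_orients_flanks(small_genome):
    g = small_genome.haplotypes[0]
    contigs = {0: g[:2_000], 1: g[2_100:4_000]}
    scaf = Scaffold(0, [ScaffoldPart(0, "-", 100), ScaffoldPart(1, "+", None)])
    (task,) = find_gap_tasks([scaf], contigs, flank_len=200)
    assert task.left_flank == revcomp(contigs[0])[-200:]
    assert task.right_flank == contigs[1][:200]
    assert task.est_gap == 100
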