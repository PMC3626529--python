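"""Gap closing by iterative local assembly.

Scaffold gaps (N runs with a signed length estimate) are filled by growing
a consensus inward from both flanks, one base at a time, using reads whose
mates anchor near the gap.  The defining rule: reads recruited in *earlier*
cycles keep voting in later cycles (evidence accumulates), which resolves
conflicting columns that any single cycle's reads cannot.  The previous
behaviour — only the current cycle's reads vote — is kept behind
``legacy_cycle_local=True`` for comparison.

A gap closes when the two inward extensions overlap by at least ``k_fill``
bases with at most one mismatch; negative gap estimates (overlapping
contig ends) are checked for a direct flank overlap first.  Fills are
capped at ``est_gap + 3*sd + 2*read_len``; beyond that the gap is reported
``partial``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_config import Library, Read
from .kmer import revcomp
from .multik import map_reads_to_contigs
from .scaffold import Scaffold

log = logging.getLogger(__name__)


@dataclass
class AssignedRead:
    seq: str                # oriented to the scaffold plus strand
    read_id: str
    cycle_first_seen: int
    side: str               # 'L': anchored left of the gap, 'R': right


@dataclass
class GapTask:
    scaffold_id: int
    gap_index: int
    left_flank: str
    right_flank: str
    est_gap: int
    assigned_reads: list[AssignedRead] = field(default_factory=list)
    ext_left: str = ""      # grown rightward from the left flank
    ext_right: str = ""     # grown leftward from the right flank
    status: str = "open"
    fill_seq: str = ""
    final_gap: int = 0      # signed; negative = contigs overlap by that much
    cycles_used: int = 0

    def has_read(self, read_id: str) -> bool:
        return any(a.read_id == read_id for a in self.assigned_reads)


@dataclass
class GapResult:
    scaffold_id: int
    gap_index: int
    status: str             # closed | partial | open
    fill_seq: str
    final_gap: int
    cycles_used: int


def resolve_conflict(column_votes: dict[str, float],
                     ambiguity_ratio: float = 0.8) -> str | None:
    """Pick the base with the highest cumulative weight.

    Returns None (ambiguity) when the runner-up is within ``ambiguity_ratio``
    of the winner; extension stops at such a column.  Empty votes are a
    contract violation.
    """
    if not column_votes:
        raise ValueError("resolve_conflict requires at least one vote")
    ranked = sorted(column_votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[1][1] >= ambiguity_ratio * ranked[0][1]:
        return None
    return ranked[0][0]


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _extend_consensus(cur: str, pool: list[AssignedRead], k_fill: int,
                      max_len: int, ambiguity_ratio: float = 0.8,
                      max_read_mismatch: int = 2) -> str:
    """Grow ``cur`` rightward by cumulative-majority consensus.

    Reads anchor by an exact ``k_fill``-mer match to the current tail; a read
    whose anchored overlap with the consensus carries mismatches votes at
    half weight (dropped entirely beyond ``max_read_mismatch``).
    """
    ext = []
    while len(ext) < max_len:
        tail = (cur + "".join(ext))[-k_fill:]
        if len(tail) < k_fill:
            break
        s = cur + "".join(ext)
        votes: dict[str, float] = {}
        for ar in pool:
            j = ar.seq.find(tail)
            while j != -1:
                nxt_idx = j + k_fill
                if nxt_idx < len(ar.seq):
                    # overlap of the read's prefix with the consensus
                    start_in_s = len(s) - k_fill - j
                    if start_in_s >= 0:
                        mm = _mismatches(ar.seq[:j], s[start_in_s : len(s) - k_fill])
                    else:
                        mm = _mismatches(ar.seq[-start_in_s : j], s[: len(s) - k_fill])
                    if mm <= max_read_mismatch:
                        w = 1.0 if mm == 0 else 0.5
                        b = ar.seq[nxt_idx]
                        votes[b] = votes.get(b, 0.0) + w
                j = ar.seq.find(tail, j + 1)
        if not votes:
            break
        base = resolve_conflict(votes, ambiguity_ratio)
        if base is None:
            break
        ext.append(base)
    return "".join(ext)


def _try_close(task: GapTask, k_fill: int, max_fill: int) -> bool:
    """Look for a >= k_fill overlap (<= 1 mismatch) between the extensions."""
    left = task.left_flank + task.ext_left
    right = task.ext_right + task.right_flank
    best = None
    max_ov = min(len(left), len(right))
    for ov in range(max_ov, k_fill - 1, -1):
        if _mismatches(left[-ov:], right[:ov]) <= 1:
            best = ov
            break
    if best is None:
        return False
    merged = left + right[best:]
    fill_len = len(merged) - len(task.left_flank) - len(task.right_flank)
    if fill_len > max_fill:
        return False
    task.status = "closed"
    task.final_gap = fill_len
    task.fill_seq = (merged[len(task.left_flank):
                            len(merged) - len(task.right_flank)]
                     if fill_len > 0 else "")
    return True


def find_gap_tasks(scaffolds: list[Scaffold], contig_seqs: dict[int, str],
                   flank_len: int) -> list[GapTask]:
    """One task per internal scaffold gap, with N-free flanks from the
    adjacent oriented contigs."""
    tasks = []
    for s in scaffolds:
        for i, part in enumerate(s.parts[:-1]):
            left_seq = contig_seqs[part.contig_id]
            if part.orient == "-":
                left_seq = revcomp(left_seq)
            nxt = s.parts[i + 1]
            right_seq = contig_seqs[nxt.contig_id]
            if nxt.orient == "-":
                right_seq = revcomp(right_seq)
            tasks.append(GapTask(
                scaffold_id=s.id, gap_index=i,
                left_flank=left_seq[-flank_len:],
                right_flank=right_seq[:flank_len],
                est_gap=part.gap_after if part.gap_after is not None else 0))
    return tasks


def assign_reads_to_gaps(tasks: list[GapTask], scaffolds: list[Scaffold],
                         placements, reads: list[Read],
                         contig_lengths: dict[int, int], cycle: int = 1,
                         min_wildcard: int = 1) -> None:
    """Initial recruitment: a read joins a gap when its placed mate implies
    the read falls inside the gap interval (mate position +/- insert +/- 3 sd),
    and the read itself is unplaced or placed only with mismatches.
    """
    by_id = {p.read_id: p for p in placements}
    rmeta = {r.id: r for r in reads}
    # contig -> (scaffold, start, orient); gap intervals in scaffold coords
    scaf_pos: dict[int, tuple[int, int, str]] = {}
    gap_interval: dict[tuple[int, int], tuple[int, int]] = {}
    for s in scaffolds:
        pos = s.positions(contig_lengths, min_wildcard)
        for cid, (start, orient) in pos.items():
            scaf_pos[cid] = (s.id, start, orient)
        cur = 0
        for i, part in enumerate(s.parts):
            cur += contig_lengths[part.contig_id]
            if part.gap_after is not None:
                glen = max(part.gap_after, min_wildcard)
                gap_interval[(s.id, i)] = (cur, cur + glen)
                cur += glen
    task_by_key = {(t.scaffold_id, t.gap_index): t for t in tasks}
    for r in reads:
        if r.mate_id is None:
            continue
        mate_p = by_id.get(r.mate_id)
        if mate_p is None:
            continue
        own_p = by_id.get(r.id)
        if own_p is not None and own_p.mismatches == 0:
            continue  # confidently placed: belongs to a contig, not a gap
        lib = r.library or rmeta[r.mate_id].library
        if lib is None:
            continue
        rl = len(r.seq)
        mate_len = len(rmeta[r.mate_id].seq)
        sid, cstart, corient = scaf_pos[mate_p.contig_id]
        clen = contig_lengths[mate_p.contig_id]
        if corient == "+":
            mstart = cstart + mate_p.offset
            mstrand = mate_p.strand
        else:
            mstart = cstart + (clen - mate_p.offset - mate_len)
            mstrand = "+" if mate_p.strand == "-" else "-"
        if lib.orientation == "RF":
            mstrand = "+" if mstrand == "-" else "-"
        sd3 = 3 * lib.ins_sd
        if mstrand == "+":
            lo = mstart + lib.avg_ins - rl - sd3
            hi = mstart + lib.avg_ins + sd3
            oriented = revcomp(r.seq)
            side = "L"
        else:
            lo = mstart + mate_len - lib.avg_ins - sd3
            hi = mstart + mate_len - lib.avg_ins + rl + sd3
            oriented = r.seq
            side = "R"
        for (gs, gi), (g0, g1) in gap_interval.items():
            if gs != sid:
                continue
            if hi < g0 - rl or lo > g1 + rl:
                continue
            task = task_by_key[(gs, gi)]
            if not task.has_read(r.id):
                task.assigned_reads.append(
                    AssignedRead(seq=oriented, read_id=r.id,
                                 cycle_first_seen=cycle, side=side))


def _recruit_from_extensions(task: GapTask, unplaced_pairs, cycle: int,
                             reach: int) -> int:
    """Cycle >1 recruitment: pairs with both mates off-contig whose one mate
    now matches the grown extension pull their partner into the pool."""
    n = 0
    left = (task.left_flank + task.ext_left)[-reach:]
    right = (task.ext_right + task.right_flank)[:reach]
    for r, mate in unplaced_pairs:
        if task.has_read(r.id):
            continue
        mseq = mate.seq
        found = None
        if left.find(mseq) != -1:
            found = ("L", revcomp(r.seq))
        elif left.find(revcomp(mseq)) != -1 or right.find(mseq) != -1 \
                or right.find(revcomp(mseq)) != -1:
            found = ("R", r.seq)
        if found:
            task.assigned_reads.append(
                AssignedRead(seq=found[1], read_id=r.id,
                             cycle_first_seen=cycle, side=found[0]))
            # both orientations may be needed; add the mirror too
            task.assigned_reads.append(
                AssignedRead(seq=revcomp(found[1]), read_id=r.id + "~rc",
                             cycle_first_seen=cycle, side=found[0]))
            n += 1
    return n


def extend_cycle(task: GapTask, cycle: int, k_fill: int = 25,
                 max_fill: int | None = None,
                 legacy_cycle_local: bool = False) -> GapTask:
    """One extension cycle: grow both flanks inward by consensus.

    Cumulative mode (default) lets every read assigned in cycles <= cycle
    vote; the legacy rule restricts voting to reads first seen in this
    cycle.
    """
    if legacy_cycle_local:
        pool = [a for a in task.assigned_reads if a.cycle_first_seen == cycle]
    else:
        pool = [a for a in task.assigned_reads if a.cycle_first_seen <= cycle]
    if not pool:
        return task
    if max_fill is None:
        max_fill = max(task.est_gap, 0) + 1000
    room = max(max_fill - len(task.ext_left) - len(task.ext_right), 0)
    task.ext_left += _extend_consensus(
        task.left_flank + task.ext_left, pool, k_fill, room)
    room = max(max_fill - len(task.ext_left) - len(task.ext_right), 0)
    # grow the right flank leftward: work in reverse-complement space
    rc_pool = [AssignedRead(seq=revcomp(a.seq), read_id=a.read_id,
                            cycle_first_seen=a.cycle_first_seen, side=a.side)
               for a in pool]
    grown = _extend_consensus(
        revcomp(task.ext_right + task.right_flank), rc_pool, k_fill, room)
    task.ext_right = revcomp(grown) + task.ext_right
    task.cycles_used = cycle
    return task


def close_gaps(scaffolds: list[Scaffold], reads: list[Read],
               contigs, max_cycles: int = 10, k_fill: int = 25,
               flank_len: int | None = None, max_mismatch: int = 2,
               legacy_cycle_local: bool = False,
               min_wildcard: int = 1,
               ) -> tuple[list[tuple[int, str]], list[GapResult], list[int]]:
    """Close scaffold gaps; returns (rendered scaffolds, per-gap results,
    per-cycle total N counts).

    ``contigs`` is the contig list the scaffolds refer to.  The N-count
    trace starts with the pre-closure assembly and never increases.
    """
    contig_seqs = {c.id: c.seq for c in contigs}
    lengths = {c.id: len(c.seq) for c in contigs}
    libs = {r.library.ins_sd for r in reads if r.library}
    max_sd = max(libs) if libs else 50
    read_len = max((len(r.seq) for r in reads), default=100)
    if flank_len is None:
        flank_len = 2 * max_sd + read_len
    tasks = find_gap_tasks(scaffolds, contig_seqs, flank_len)
    if not tasks:
        rendered = [(s.id, s.sequence(contig_seqs, min_wildcard))
                    for s in scaffolds]
        return rendered, [], [0]
    placements = map_reads_to_contigs(reads, list(contigs), max_mismatch)
    assign_reads_to_gaps(tasks, scaffolds, placements, reads, lengths,
                         cycle=1, min_wildcard=min_wildcard)
    placed_ids = {p.read_id for p in placements}
    rmeta = {r.id: r for r in reads}
    unplaced_pairs = [(r, rmeta[r.mate_id]) for r in reads
                      if r.mate_id and r.id not in placed_ids
                      and r.mate_id not in placed_ids and r.mate_id in rmeta]

    def render(all_tasks) -> tuple[list[tuple[int, str]], int]:
        out = []
        n_count = 0
        tmap = {(t.scaffold_id, t.gap_index): t for t in all_tasks}
        for s in scaffolds:
            chunks = []
            trim = 0  # overlap bases to drop from the next contig
            for i, part in enumerate(s.parts):
                cs = contig_seqs[part.contig_id]
                oriented = cs if part.orient == "+" else revcomp(cs)
                chunks.append(oriented[trim:])
                trim = 0
                if part.gap_after is not None:
                    t = tmap[(s.id, i)]
                    if t.status == "closed":
                        if t.final_gap >= 0:
                            chunks.append(t.fill_seq)
                        else:
                            trim = -t.final_gap
                    else:
                        glen = max(part.gap_after, min_wildcard)
                        remaining = max(glen - len(t.ext_left) - len(t.ext_right),
                                        min_wildcard)
                        chunks.append(t.ext_left + "N" * remaining + t.ext_right)
                        n_count += remaining
            out.append((s.id, "".join(chunks)))
        return out, n_count

    n_trace = [render(tasks)[1]]
    pooled_sd3 = 3 * max_sd
    for cycle in range(1, max_cycles + 1):
        progress = False
        for t in tasks:
            if t.status == "closed":
                continue
            max_fill = max(t.est_gap, 0) + pooled_sd3 + 2 * read_len
            if t.est_gap < 0 and cycle == 1 and _try_close(t, k_fill, max_fill):
                progress = True
                continue
            before = (len(t.ext_left), len(t.ext_right))
            extend_cycle(t, cycle, k_fill, max_fill, legacy_cycle_local)
            if _try_close(t, k_fill, max_fill):
                progress = True
            elif (len(t.ext_left), len(t.ext_right)) != before:
                progress = True
            if t.status != "closed":
                n = _recruit_from_extensions(
                    t, unplaced_pairs, cycle + 1,
                    reach=read_len + 6 * max_sd + max((r.library.avg_ins
                          for r in reads if r.library), default=500))
                progress = progress or n > 0
        n_trace.append(render(tasks)[1])
        if all(t.status == "closed" for t in tasks) or not progress:
            break
    rendered, _ = render(tasks)
    results = []
    for t in tasks:
        status = t.status
        if status != "closed" and (t.ext_left or t.ext_right):
            status = "partial"
        results.append(GapResult(
            scaffold_id=t.scaffold_id, gap_index=t.gap_index, status=status,
            fill_seq=t.fill_seq,
            final_gap=(t.final_gap if t.status == "closed"
                       else max(t.est_gap, min_wildcard)
                       - len(t.ext_left) - len(t.ext_right)),
            cycles_used=t.cycles_used))
    return rendered, results, n_trace
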