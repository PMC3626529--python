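"""Iterative multi-k contig assembly and read-to-contig mapping.

Small k assembles through low coverage and lets cleaning remove sequencing
errors; large k resolves repeats longer than k-1.  The multi-k strategy
takes both: assemble at k_min, then rebuild at successively larger k from
(a) reads threaded consistently against the previous contigs and (b) the
previous contigs themselves injected as protected pseudo-reads, so no
assembled sequence can be lost when per-k' coverage drops below the
cleaning thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .graph import DBGraph, Unitig, build_dbg, clip_tips, extract_unitigs, \
    pop_bubbles, remove_low_coverage
from .kmer import _canonical_windows, revcomp

log = logging.getLogger(__name__)


@dataclass
class MultikPlan:
    """k schedule: odd k from k_min to k_max in even steps."""

    k_min: int
    k_max: int
    step: int = 8

    def __post_init__(self) -> None:
        if self.k_min % 2 == 0 or self.k_max % 2 == 0:
            raise ValueError("k_min and k_max must be odd")
        if self.step % 2 != 0 or self.step <= 0:
            raise ValueError("step must be even and positive")
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")

    def ks(self) -> list[int]:
        out = list(range(self.k_min, self.k_max + 1, self.step))
        if out[-1] != self.k_max:
            out.append(self.k_max)
        return out


@dataclass
class ReadPlacement:
    read_id: str
    contig_id: int
    offset: int
    strand: str  # '+'/'-'
    mismatches: int


def _count_mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


class ContigIndex:
    """Seed index over contig sequences for full-length ungapped placement."""

    def __init__(self, contigs: list[Unitig], seed_len: int = 31):
        self.contigs = contigs
        self.seed_len = seed_len
        self.index: dict[str, list[tuple[int, int]]] = {}
        for c in contigs:
            seq = c.seq
            for pos in range(0, len(seq) - seed_len + 1):
                self.index.setdefault(seq[pos : pos + seed_len], []).append((c.id, pos))
        self.by_id = {c.id: c for c in contigs}

    def place(self, seq: str, max_mismatch: int) -> ReadPlacement | None:
        """Best full-length ungapped placement on either strand, or None.

        Ties break by (mismatches, contig id, offset, '+' before '-'):
        deterministic.
        """
        s = self.seed_len
        if len(seq) < s:
            return None
        best: tuple | None = None
        for strand, rseq in (("+", seq), ("-", revcomp(seq))):
            # enough disjoint seeds that <= max_mismatch errors leave one clean
            offs = list(range(0, len(rseq) - s + 1, s))
            if offs[-1] != len(rseq) - s:
                offs.append(len(rseq) - s)
            tried: set[tuple[int, int]] = set()
            for soff in offs:
                for cid, cpos in self.index.get(rseq[soff : soff + s], ()):
                    off = cpos - soff
                    if off < 0 or (cid, off) in tried:
                        continue
                    tried.add((cid, off))
                    contig = self.by_id[cid].seq
                    if off + len(rseq) > len(contig):
                        continue
                    mm = _count_mismatches(rseq, contig[off : off + len(rseq)],
                                           max_mismatch)
                    if mm > max_mismatch:
                        continue
                    key = (mm, cid, off, 0 if strand == "+" else 1)
                    if best is None or key < best[0]:
                        best = (key, ReadPlacement(read_id="", contig_id=cid,
                                                   offset=off, strand=strand,
                                                   mismatches=mm))
        return best[1] if best else None


def map_reads_to_contigs(reads, contigs: list[Unitig], max_mismatch: int = 2,
                         seed_len: int | None = None) -> list[ReadPlacement]:
    """Best full-length ungapped placement of each read on the contig set.

    Reads with no placement within ``max_mismatch`` are omitted.
    """
    if not contigs:
        return []
    if seed_len is None:
        seed_len = min(31, min(len(c.seq) for c in contigs))
    idx = ContigIndex(contigs, seed_len)
    out: list[ReadPlacement] = []
    for read in reads:
        p = idx.place(read.seq, max_mismatch)
        if p is not None:
            p.read_id = read.id
            out.append(p)
    return out


def contig_read_depth(contigs: list[Unitig], placements: list[ReadPlacement],
                      read_len_of: dict[str, int]) -> dict[int, float]:
    """Mean read depth of each contig from its full-length placements.

    A read of length r can only start at the first len-r+1 positions, so the
    placed-base mass is normalized by that effective length; dividing by the
    raw length would understate the depth of contigs shorter than a few read
    lengths (exactly the short repeat copies whose depth matters most).
    """
    bases: dict[int, int] = {c.id: 0 for c in contigs}
    rl_sum: dict[int, int] = {c.id: 0 for c in contigs}
    n_pl: dict[int, int] = {c.id: 0 for c in contigs}
    for p in placements:
        rl = read_len_of[p.read_id]
        bases[p.contig_id] += rl
        rl_sum[p.contig_id] += rl
        n_pl[p.contig_id] += 1
    out = {}
    for c in contigs:
        if not len(c.seq) or not n_pl[c.id]:
            out[c.id] = 0.0
            continue
        mean_rl = rl_sum[c.id] / n_pl[c.id]
        eff = max(len(c.seq) - mean_rl + 1, 1.0)
        out[c.id] = bases[c.id] / eff
    return out


def _single_k_round(reads, k: int, tip_len: int | None, bubble_div: float,
                    cov_cutoff: int, protected: set[str] | None = None) -> list[Unitig]:
    g = build_dbg(reads, k)
    remove_low_coverage(g, cov_cutoff, protected_edges=protected)
    clip_tips(g, tip_len if tip_len is not None else 2 * k, protected_edges=protected)
    pop_bubbles(g, bubble_div, protected_edges=protected)
    return extract_unitigs(g)


def assemble_multik(reads, plan: MultikPlan, max_mismatch: int = 2,
                    tip_len: int | None = None, bubble_div: float = 0.03,
                    cov_cutoff: int = 1) -> list[Unitig]:
    """Run the multi-k schedule and return the final round's unitigs with
    per-contig mean read depth recomputed by mapping the reads back.

    Each later round's graph is built from reads that place on the previous
    unitigs (within ``max_mismatch``) plus unplaced reads, together with the
    previous unitigs as pseudo-reads whose edges are protected from cleaning.
    Edges supported only by unplaced reads face the low-coverage filter as
    usual.
    """
    reads = list(reads)
    if reads and plan.k_max >= min(len(r.seq) for r in reads):
        raise ValueError("k_max must be smaller than the read length")
    ks = plan.ks()
    unitigs = _single_k_round(reads, ks[0], tip_len, bubble_div, cov_cutoff)
    for k in ks[1:]:
        placements = map_reads_to_contigs(reads, unitigs, max_mismatch)
        placed_ids = {p.read_id for p in placements}
        g = DBGraph(k)
        for r in reads:
            g.add_sequence(r.seq)
        protected: set[str] = set()
        for u in unitigs:
            g.add_sequence(u.seq)
            protected.update(_canonical_windows(u.seq, k + 1))
        n_unplaced = len(reads) - len(placed_ids)
        if n_unplaced:
            log.info("k=%d: %d reads without placement on previous unitigs",
                     k, n_unplaced)
        remove_low_coverage(g, cov_cutoff, protected_edges=protected)
        clip_tips(g, tip_len if tip_len is not None else 2 * k,
                  protected_edges=protected)
        pop_bubbles(g, bubble_div, protected_edges=protected)
        unitigs = extract_unitigs(g)
    # recompute depth from read placements
    placements = map_reads_to_contigs(reads, unitigs, max_mismatch)
    rl = {r.id: len(r.seq) for r in reads}
    depth = contig_read_depth(unitigs, placements, rl)
    for u in unitigs:
        u.mean_coverage = depth[u.id]
    return unitigs
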