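"""Hierarchical paired-end scaffolding.

Contigs are ordered and oriented into scaffolds using paired-end links,
processing libraries from small to large insert size (by rank).  The stages
within each rank:

1. mate pairs whose reads place on two different contigs become links, with
   a per-pair gap observation ``gap = insert - d_a - d_b`` (d = distance
   from the read's outermost base to the linked contig end);
2. links are bundled per contig pair and orientation; bundles below
   ``min_support`` are kept aside as weak candidates;
3. heterozygous contig pairs (half depth, shared flanking neighbors,
   comparable length) are masked, keeping the higher-depth allele;
4. bundles are lifted onto the current super-contigs, transitively
   redundant edges are removed, and unambiguous chains are linearized;
5. junctions built by earlier (smaller-insert) ranks are re-examined with
   the current rank's links: a junction no pair spans, while one side links
   elsewhere with enough support, is a chimera and is cut;
6. after all ranks, weak candidates are re-admitted where the accepted
   bundle topology independently implies the same layout, or where they are
   the unique link between two otherwise dead ends.

Gaps keep their signed estimates internally; rendered sequence shows
``max(gap, 1)`` N's.  Negative gaps (overlapping ends) are resolved later
by gap closing, not here.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

from .io_config import Library, Read
from .graph import Unitig
from .kmer import revcomp
from .multik import ReadPlacement, map_reads_to_contigs, contig_read_depth

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# link collection


@dataclass
class PELink:
    """One mate pair's evidence joining two contigs.

    ``end_a``/``end_b`` name the contig end facing the gap ('L' or 'R', in
    each contig's own plus-strand frame).  Normalized so contig_a < contig_b.
    """

    contig_a: int
    contig_b: int
    end_a: str
    end_b: str
    gap_obs: int
    library: Library
    read_pair_id: str
    read_span: int = 200  # summed mate read lengths (selection-bias correction)


@dataclass
class LinkCollection:
    links: list[PELink] = field(default_factory=list)
    insert_samples: dict[str, list[int]] = field(default_factory=dict)
    orientation_violations: int = 0

    def reestimate_inserts(self) -> dict[str, tuple[float, float]]:
        """Per-library (mean, sd) of observed same-contig insert sizes."""
        out = {}
        for name, xs in self.insert_samples.items():
            if len(xs) >= 2:
                m = sum(xs) / len(xs)
                v = sum((x - m) ** 2 for x in xs) / (len(xs) - 1)
                out[name] = (m, math.sqrt(v))
        return out


def _link_end(p: ReadPlacement, read_len: int, contig_len: int,
              rf: bool) -> tuple[str, int]:
    """(linked end, distance from the read's outermost base to that end)."""
    strand = p.strand
    if rf:  # mate-pair sense: reads point outward; flip to innie frame
        strand = "+" if strand == "-" else "-"
    if strand == "+":
        return "R", contig_len - p.offset
    return "L", p.offset + read_len


def collect_pe_links(placements: list[ReadPlacement], reads: list[Read],
                     contig_lengths: dict[int, int]) -> LinkCollection:
    """Turn mate-pair placements into contig-contig links.

    Pairs on one contig feed insert re-estimation (or count as orientation
    violations when discordant); pairs with an unplaced mate yield nothing.
    """
    by_id = {p.read_id: p for p in placements}
    rmeta = {r.id: r for r in reads}
    out = LinkCollection()
    seen_pairs: set[str] = set()
    for r in reads:
        if r.mate_id is None or r.id not in by_id or r.mate_id not in by_id:
            continue
        pair_id = min(r.id, r.mate_id).rsplit("/", 1)[0]
        if pair_id in seen_pairs:
            continue
        seen_pairs.add(pair_id)
        p1, p2 = by_id[r.id], by_id[r.mate_id]
        lib = r.library or rmeta[r.mate_id].library
        if lib is None:
            continue
        rf = lib.orientation == "RF"
        len1 = len(rmeta[r.id].seq)
        len2 = len(rmeta[r.mate_id].seq)
        if p1.contig_id == p2.contig_id:
            s1, s2 = p1.strand, p2.strand
            if rf:
                s1 = "+" if s1 == "-" else "-"
                s2 = "+" if s2 == "-" else "-"
            if s1 == s2:
                out.orientation_violations += 1
                continue
            plus, minus = (p1, p2) if s1 == "+" else (p2, p1)
            plus_len = len1 if plus is p1 else len2
            minus_len = len2 if minus is p2 else len1
            ins = (minus.offset + minus_len) - plus.offset
            if ins <= 0 or plus.offset > minus.offset + minus_len:
                out.orientation_violations += 1
                continue
            out.insert_samples.setdefault(lib.name, []).append(ins)
            continue
        e1, d1 = _link_end(p1, len1, contig_lengths[p1.contig_id], rf)
        e2, d2 = _link_end(p2, len2, contig_lengths[p2.contig_id], rf)
        gap = lib.avg_ins - d1 - d2
        a, ea, b, eb = p1.contig_id, e1, p2.contig_id, e2
        if a > b:
            a, ea, b, eb = b, eb, a, ea
        out.links.append(PELink(a, b, ea, eb, gap, lib, pair_id,
                                read_span=len1 + len2))
    return out


# ---------------------------------------------------------------------------
# bundling


@dataclass
class LinkBundle:
    contig_a: int
    contig_b: int
    end_a: str
    end_b: str
    support: int
    gap_mean: float
    gap_sd: float
    rank: int
    status: str = "accepted"  # accepted | weak | conflict | recovered


@dataclass
class BundleResult:
    accepted: list[LinkBundle] = field(default_factory=list)
    weak: list[LinkBundle] = field(default_factory=list)
    conflicts: list[LinkBundle] = field(default_factory=list)

    def all(self) -> list[LinkBundle]:
        return self.accepted + self.weak + self.conflicts


def _median(xs: list[int]) -> float:
    s = sorted(xs)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def bundle_links(links: list[PELink], min_support: int = 3,
                 correct_length_bias: bool = False) -> BundleResult:
    """Aggregate links per (contig pair, orientation).

    Gap observations farther than 3 library sd from the bundle median are
    trimmed before averaging.  Where one pair shows conflicting orientations,
    the majority orientation forms the bundle and the minority is recorded
    as conflict evidence.  Bundles below ``min_support`` are returned as weak
    candidates, not discarded.  ``gap_sd`` is the standard error of the gap
    estimate, library sd / sqrt(support).

    ``correct_length_bias`` additionally undoes the selection shift of
    spanning pairs (a pair can only span when its insert exceeds
    gap + both read lengths, so observed gaps run high by about
    sd^2 / (insert - gap - read span)); the scaffolding pipeline enables it.
    """
    by_pair: dict[tuple[int, int], dict[tuple[str, str], list[PELink]]] = {}
    for ln in links:
        by_pair.setdefault((ln.contig_a, ln.contig_b), {}) \
               .setdefault((ln.end_a, ln.end_b), []).append(ln)
    res = BundleResult()
    for (a, b), orients in sorted(by_pair.items()):
        groups = sorted(orients.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        for gi, ((ea, eb), grp) in enumerate(groups):
            sd_lib = max(ln.library.ins_sd for ln in grp)
            med = _median([ln.gap_obs for ln in grp])
            kept = [ln.gap_obs for ln in grp
                    if abs(ln.gap_obs - med) <= 3 * sd_lib]
            if not kept:
                kept = [int(med)]
            support = len({ln.read_pair_id for ln in grp})
            gap_mean = sum(kept) / len(kept)
            # pairs spanning a gap are length-biased: the insert must exceed
            # gap + both read lengths, so E[obs] = g - sd^2/(mu - g - span).
            # Undo that shift (one fixed-point step; skipped when the
            # denominator is within one sd of zero).
            if correct_length_bias:
                mu = max(ln.library.avg_ins for ln in grp)
                span = sum(ln.read_span for ln in grp) / len(grp)
                denom = mu - gap_mean - span
                if denom > sd_lib:
                    gap_mean += sd_lib ** 2 / denom
            bundle = LinkBundle(
                contig_a=a, contig_b=b, end_a=ea, end_b=eb, support=support,
                gap_mean=gap_mean,
                gap_sd=sd_lib / math.sqrt(max(len(kept), 1)),
                rank=min(ln.library.rank for ln in grp))
            if gi > 0:
                bundle.status = "conflict"
                res.conflicts.append(bundle)
            elif support < min_support:
                bundle.status = "weak"
                res.weak.append(bundle)
            else:
                res.accepted.append(bundle)
    return res


# ---------------------------------------------------------------------------
# heterozygous contig pairs


def modal_depth(contigs: list[Unitig], depth: dict[int, float],
                min_len: int = 1000) -> float:
    """Length-weighted mode of rounded depths over contigs >= min_len.

    Weighting by length makes the mode the depth of most assembled *bases*,
    which is robust when few contigs exist.  Falls back to all contigs when
    none reach ``min_len``; ties break toward the smaller depth.
    """
    big = [c for c in contigs if len(c.seq) >= min_len] or list(contigs)
    counts: Counter = Counter()
    for c in big:
        counts[int(round(depth[c.id]))] += len(c.seq)
    top = max(counts.values())
    return float(min(d for d, n in counts.items() if n == top))


def _neighbor_map(bundles: list[LinkBundle]) -> dict[tuple[int, str], set]:
    nb: dict[tuple[int, str], set] = defaultdict(set)
    for b in bundles:
        nb[(b.contig_a, b.end_a)].add((b.contig_b, b.end_b))
        nb[(b.contig_b, b.end_b)].add((b.contig_a, b.end_a))
    return nb


def detect_het_pairs(contigs: list[Unitig], bundles: list[LinkBundle],
                     depth: dict[int, float],
                     depth_window: tuple[float, float] = (0.3, 0.7),
                     max_len_ratio: float = 2.0) -> list[tuple[int, int]]:
    """Allelic contig pairs: both at roughly half the modal depth, with
    lengths within ``max_len_ratio`` of each other, and locally equivalent in
    the link graph: they share flanking neighbors on both sides, or share one
    side while being directly cross-linked to each other (mate pairs split
    across the two alleles of one locus — reads without a distinguishing
    variant map to one allele, so the weaker allele can lose one flank).

    Returns (kept_id, dropped_id) pairs — the higher-depth member is kept;
    equal depth keeps the smaller id.  Pass *all* bundles (including weak and
    conflict evidence); support thresholds do not apply to topology here.
    """
    mode = modal_depth(contigs, depth)
    lo, hi = depth_window[0] * mode, depth_window[1] * mode
    cand = [c for c in contigs if lo < depth[c.id] < hi]
    nb = _neighbor_map(bundles)
    out: list[tuple[int, int]] = []
    taken: set[int] = set()
    for i, x in enumerate(cand):
        for y in cand[i + 1:]:
            if x.id in taken or y.id in taken:
                continue
            lx, ly = len(x.seq), len(y.seq)
            if max(lx, ly) > max_len_ratio * min(lx, ly):
                continue
            # neighbor sets with links between the pair itself removed
            def side(c, e, other):
                return {n for n in nb[(c.id, e)] if n[0] != other.id}
            xl, xr = side(x, "L", y), side(x, "R", y)
            yl, yr = side(y, "L", x), side(y, "R", x)
            cross = any(n[0] == y.id for e in ("L", "R") for n in nb[(x.id, e)])
            fwd = bool(xl & yl) + bool(xr & yr)
            rev = bool(xl & yr) + bool(xr & yl)
            both_sides = max(fwd, rev) >= 2
            one_side_plus_cross = max(fwd, rev) >= 1 and cross
            if not (both_sides or one_side_plus_cross):
                continue
            dx, dy = depth[x.id], depth[y.id]
            if dx > dy or (dx == dy and x.id < y.id):
                out.append((x.id, y.id))
            else:
                out.append((y.id, x.id))
            taken.update((x.id, y.id))
    return out


# ---------------------------------------------------------------------------
# scaffolds


@dataclass
class ScaffoldPart:
    contig_id: int
    orient: str  # '+'/'-'
    gap_after: int | None  # signed estimate; None after the last part


@dataclass
class Scaffold:
    id: int
    parts: list[ScaffoldPart]

    def contig_ids(self) -> list[int]:
        return [p.contig_id for p in self.parts]

    def length(self, lengths: dict[int, int], min_wildcard: int = 1) -> int:
        total = 0
        for p in self.parts:
            total += lengths[p.contig_id]
            if p.gap_after is not None:
                total += max(p.gap_after, min_wildcard)
        return total

    def positions(self, lengths: dict[int, int],
                  min_wildcard: int = 1) -> dict[int, tuple[int, str]]:
        """contig id -> (start position in rendered scaffold, orientation)."""
        pos = {}
        cur = 0
        for p in self.parts:
            pos[p.contig_id] = (cur, p.orient)
            cur += lengths[p.contig_id]
            if p.gap_after is not None:
                cur += max(p.gap_after, min_wildcard)
        return pos

    def sequence(self, contig_seqs: dict[int, str], min_wildcard: int = 1) -> str:
        chunks = []
        for p in self.parts:
            s = contig_seqs[p.contig_id]
            chunks.append(s if p.orient == "+" else revcomp(s))
            if p.gap_after is not None:
                chunks.append("N" * max(p.gap_after, min_wildcard))
        return "".join(chunks)

    def reversed_(self) -> "Scaffold":
        parts = []
        gaps = [p.gap_after for p in self.parts]
        for i in range(len(self.parts) - 1, -1, -1):
            p = self.parts[i]
            gap = gaps[i - 1] if i > 0 else None
            parts.append(ScaffoldPart(p.contig_id,
                                      "+" if p.orient == "-" else "-", gap))
        return Scaffold(self.id, parts)


@dataclass
class _SuperBundle:
    a: int          # scaffold id
    ea: str         # 'L'/'R' scaffold end
    b: int
    eb: str
    gap: float
    sd: float
    support: int
    source: LinkBundle | None = None


def _facing(orient: str, end: str) -> str:
    """Which scaffold direction a contig end faces: 'R' or 'L'."""
    return "R" if (orient == "+") == (end == "R") else "L"


def _lift_bundle_side(scaf_of: dict[int, tuple[Scaffold, int]], cid: int,
                      end: str, lengths: dict[int, int],
                      min_wildcard: int) -> tuple[int, str, int] | None:
    """Map a contig end to (scaffold id, scaffold end, extra distance)."""
    if cid not in scaf_of:
        return None
    scaf, _ = scaf_of[cid]
    pos = scaf.positions(lengths, min_wildcard)
    start, orient = pos[cid]
    total = scaf.length(lengths, min_wildcard)
    if _facing(orient, end) == "R":
        return scaf.id, "R", total - (start + lengths[cid])
    return scaf.id, "L", start


def _lift_bundles(bundles: list[LinkBundle], scaffolds: list[Scaffold],
                  lengths: dict[int, int], min_wildcard: int = 1,
                  max_extra: float | None = None) -> list[_SuperBundle]:
    """Aggregate contig-level bundles into scaffold-end-level super bundles."""
    scaf_of: dict[int, tuple[Scaffold, int]] = {}
    for s in scaffolds:
        for i, p in enumerate(s.parts):
            scaf_of[p.contig_id] = (s, i)
    agg: dict[tuple, list[tuple[float, float, int, LinkBundle]]] = defaultdict(list)
    for b in bundles:
        sa = _lift_bundle_side(scaf_of, b.contig_a, b.end_a, lengths, min_wildcard)
        sb = _lift_bundle_side(scaf_of, b.contig_b, b.end_b, lengths, min_wildcard)
        if sa is None or sb is None or sa[0] == sb[0]:
            continue
        gap = b.gap_mean - sa[2] - sb[2]
        if max_extra is not None and (sa[2] > max_extra or sb[2] > max_extra):
            continue
        key = (sa[0], sa[1], sb[0], sb[1])
        if key[0] > key[2]:
            key = (sb[0], sb[1], sa[0], sa[1])
        agg[key].append((gap, b.gap_sd, b.support, b))
    out = []
    for (a, ea, b_, eb), obs in sorted(agg.items()):
        support = sum(o[2] for o in obs)
        gap = sum(o[0] * o[2] for o in obs) / support
        sd = min(o[1] for o in obs)
        src = max(obs, key=lambda o: o[2])[3]
        out.append(_SuperBundle(a, ea, b_, eb, gap, sd, support, src))
    return out


def _transitive_reduce(sbs: list[_SuperBundle],
                       scaf_len: dict[int, int]) -> list[_SuperBundle]:
    """Drop A-C edges explainable as A-B-C within 3 pooled sd."""
    alive = set(range(len(sbs)))
    adj: dict[tuple[int, str], set[int]] = defaultdict(set)
    for i, sb in enumerate(sbs):
        adj[(sb.a, sb.ea)].add(i)
        adj[(sb.b, sb.eb)].add(i)

    def other(i, node):
        sb = sbs[i]
        return (sb.b, sb.eb) if (sb.a, sb.ea) == node else (sb.a, sb.ea)

    changed = True
    while changed:
        changed = False
        for node, idxs in list(adj.items()):
            live = [i for i in idxs if i in alive]
            if len(live) < 2:
                continue
            for i in live:
                for j in live:
                    if i == j or j not in alive or i not in alive:
                        continue
                    mid = other(i, node)       # node -> mid (via i)
                    tgt = other(j, node)       # node -> tgt (via j): candidate
                    far = (mid[0], "L" if mid[1] == "R" else "R")
                    for t in adj.get(far, ()):
                        if t not in alive or t == i or t == j:
                            continue
                        if other(t, far) != tgt:
                            continue
                        implied = sbs[i].gap + scaf_len[mid[0]] + sbs[t].gap
                        tol = 3 * math.sqrt(sbs[i].sd ** 2 + sbs[t].sd ** 2)
                        if abs(sbs[j].gap - implied) <= max(tol, 3):
                            alive.discard(j)
                            changed = True
                            break
    return [sbs[i] for i in sorted(alive)]


def _merge_pair(s1: Scaffold, e1: str, s2: Scaffold, e2: str,
                gap: int, next_id: int) -> Scaffold:
    left = s1 if e1 == "R" else s1.reversed_()
    right = s2 if e2 == "L" else s2.reversed_()
    parts = [replace(p) for p in left.parts]
    parts[-1].gap_after = gap
    parts.extend(replace(p) for p in right.parts)
    return Scaffold(next_id, parts)


def _linearize(scaffolds: list[Scaffold], sbs: list[_SuperBundle],
               lengths: dict[int, int], next_id: int,
               min_wildcard: int = 1) -> tuple[list[Scaffold], int]:
    """Join scaffold ends that carry exactly one surviving bundle each."""
    by_end: dict[tuple[int, str], list[_SuperBundle]] = defaultdict(list)
    for sb in sbs:
        by_end[(sb.a, sb.ea)].append(sb)
        by_end[(sb.b, sb.eb)].append(sb)
    joins = [sb for sb in sbs
             if len(by_end[(sb.a, sb.ea)]) == 1 and len(by_end[(sb.b, sb.eb)]) == 1]
    # build chains over scaffold ids
    join_at: dict[tuple[int, str], _SuperBundle] = {}
    for sb in joins:
        join_at[(sb.a, sb.ea)] = sb
        join_at[(sb.b, sb.eb)] = sb
    by_id = {s.id: s for s in scaffolds}
    used: set[int] = set()
    merged: list[Scaffold] = []

    def free_end(sid: int) -> str | None:
        for e in ("L", "R"):
            if (sid, e) not in join_at:
                return e
        return None

    order = sorted(by_id)
    for sid in order:
        if sid in used:
            continue
        fe = free_end(sid)
        if fe is None:
            continue
        used.add(sid)
        work = by_id[sid] if fe == "L" else by_id[sid].reversed_()
        # the end of `work` currently facing right is the original end:
        right_end = "R" if fe == "L" else "L"
        cur_sid = sid
        while (cur_sid, right_end) in join_at:
            sb = join_at[(cur_sid, right_end)]
            if (sb.a, sb.ea) == (cur_sid, right_end):
                nsid, nend = sb.b, sb.eb
            else:
                nsid, nend = sb.a, sb.ea
            if nsid in used:
                break  # safety (shouldn't happen on a chain)
            nxt = by_id[nsid] if nend == "L" else by_id[nsid].reversed_()
            work = _merge_pair(work, "R", nxt, "L", int(round(sb.gap)), next_id)
            used.add(nsid)
            cur_sid = nsid
            right_end = "R" if nend == "L" else "L"
        work.id = next_id
        next_id += 1
        merged.append(work)
    # cycles: every end joined; break at the weakest join and re-walk
    cycle_ids = [sid for sid in order if sid not in used]
    while cycle_ids:
        comp_joins = [sb for sb in joins
                      if sb.a in cycle_ids or sb.b in cycle_ids]
        weakest = min(comp_joins, key=lambda sb: sb.support)
        log.warning("cycle in scaffold graph; breaking at support-%d join",
                    weakest.support)
        for key in ((weakest.a, weakest.ea), (weakest.b, weakest.eb)):
            join_at.pop(key, None)
        joins.remove(weakest)
        start = weakest.a
        fe = free_end(start)
        used.add(start)
        work = by_id[start] if fe == "L" else by_id[start].reversed_()
        right_end = "R" if fe == "L" else "L"
        cur_sid = start
        while (cur_sid, right_end) in join_at:
            sb = join_at[(cur_sid, right_end)]
            if (sb.a, sb.ea) == (cur_sid, right_end):
                nsid, nend = sb.b, sb.eb
            else:
                nsid, nend = sb.a, sb.ea
            if nsid in used:
                break
            nxt = by_id[nsid] if nend == "L" else by_id[nsid].reversed_()
            work = _merge_pair(work, "R", nxt, "L", int(round(sb.gap)), next_id)
            used.add(nsid)
            cur_sid = nsid
            right_end = "R" if nend == "L" else "L"
        work.id = next_id
        next_id += 1
        merged.append(work)
        cycle_ids = [sid for sid in order if sid not in used]
    return merged, next_id


def build_scaffolds(contigs: list[Unitig], bundles: list[LinkBundle],
                    weak_candidates: list[LinkBundle] | None = None,
                    libraries: list[Library] | None = None,
                    masked: set[int] | None = None, min_support: int = 3,
                    min_wildcard: int = 1) -> list[Scaffold]:
    """Order and orient contigs into scaffolds, one library rank at a time.

    Ranks are processed in ascending order; each later rank treats the
    current scaffolds as super-contigs.  Ambiguous branchings (an end with
    more than one non-redundant candidate) are left unjoined.  Masked
    (heterozygous) contigs are excluded entirely.
    """
    masked = masked or set()
    lengths = {c.id: len(c.seq) for c in contigs}
    scaffolds = [Scaffold(c.id, [ScaffoldPart(c.id, "+", None)])
                 for c in contigs if c.id not in masked]
    next_id = (max((c.id for c in contigs), default=-1)) + 1
    usable = [b for b in bundles
              if b.support >= min_support
              and b.contig_a not in masked and b.contig_b not in masked]
    for rank in sorted({b.rank for b in usable}):
        rb = [b for b in usable if b.rank == rank]
        sbs = _lift_bundles(rb, scaffolds, lengths, min_wildcard)
        scaf_len = {s.id: s.length(lengths, min_wildcard) for s in scaffolds}
        sbs = _transitive_reduce(sbs, scaf_len)
        scaffolds, next_id = _linearize(scaffolds, sbs, lengths, next_id,
                                        min_wildcard)
    return scaffolds


# ---------------------------------------------------------------------------
# chimera rectification


def rectify_chimeras(scaffolds: list[Scaffold],
                     higher_rank_bundles: list[LinkBundle],
                     contig_lengths: dict[int, int], min_support: int = 3,
                     min_wildcard: int = 1,
                     gap_slack: float = 100.0) -> tuple[list[Scaffold], int]:
    """Cut scaffold junctions that larger-insert evidence contradicts.

    A junction is cut when **no** higher-rank pair spans it consistently with
    the layout AND contigs on at least one side have >= min_support
    higher-rank links to contigs outside the scaffold.  Junctions spanned by
    any consistent pair are never touched.  Returns (scaffolds, n_cuts).
    """
    if not higher_rank_bundles:
        return scaffolds, 0
    in_scaffold: dict[int, int] = {}
    for s in scaffolds:
        for p in s.parts:
            in_scaffold[p.contig_id] = s.id
    out: list[Scaffold] = []
    next_id = max((s.id for s in scaffolds), default=-1) + 1
    n_cuts = 0
    for scaf in scaffolds:
        segments = [scaf.parts]
        if len(scaf.parts) > 1:
            pos = scaf.positions(contig_lengths, min_wildcard)
            cut_after: list[int] = []
            for i in range(len(scaf.parts) - 1):
                left_ids = {p.contig_id for p in scaf.parts[: i + 1]}
                right_ids = {p.contig_id for p in scaf.parts[i + 1:]}
                spanning = 0
                elsewhere_l = 0
                elsewhere_r = 0
                for b in higher_rank_bundles:
                    a_in_l = b.contig_a in left_ids
                    a_in_r = b.contig_a in right_ids
                    b_in_l = b.contig_b in left_ids
                    b_in_r = b.contig_b in right_ids
                    if (a_in_l and b_in_r) or (a_in_r and b_in_l):
                        u, eu, v, ev = ((b.contig_a, b.end_a, b.contig_b, b.end_b)
                                        if a_in_l else
                                        (b.contig_b, b.end_b, b.contig_a, b.end_a))
                        pu, ou = pos[u]
                        pv, ov = pos[v]
                        if _facing(ou, eu) != "R" or _facing(ov, ev) != "L":
                            continue
                        expected = pv - (pu + contig_lengths[u])
                        if abs(b.gap_mean - expected) <= 3 * b.gap_sd + gap_slack:
                            spanning += b.support
                    elif (a_in_l or a_in_r) != (b_in_l or b_in_r):
                        # exactly one side inside this scaffold
                        inside_left = a_in_l or b_in_l
                        other_cid = b.contig_b if (a_in_l or a_in_r) else b.contig_a
                        if in_scaffold.get(other_cid) == scaf.id:
                            continue
                        if inside_left:
                            elsewhere_l += b.support
                        else:
                            elsewhere_r += b.support
                if spanning == 0 and max(elsewhere_l, elsewhere_r) >= min_support:
                    cut_after.append(i)
            if cut_after:
                segments = []
                prev = 0
                for i in cut_after:
                    segments.append(scaf.parts[prev : i + 1])
                    prev = i + 1
                segments.append(scaf.parts[prev:])
                n_cuts += len(cut_after)
        for seg in segments:
            seg = [replace(p) for p in seg]
            seg[-1].gap_after = None
            if len(segments) == 1:
                out.append(Scaffold(scaf.id, seg))
            else:
                out.append(Scaffold(next_id, seg))
                next_id += 1
    return out, n_cuts


# ---------------------------------------------------------------------------
# weak-link recovery


def recover_weak_links(scaffolds: list[Scaffold], accepted: list[LinkBundle],
                       weak_candidates: list[LinkBundle],
                       contig_lengths: dict[int, int],
                       min_wildcard: int = 1) -> tuple[list[Scaffold], list[LinkBundle]]:
    """Re-admit under-supported links that independent topology corroborates.

    A weak candidate joining two free scaffold ends is accepted when (a) a
    path of accepted bundles through a third contig implies the same layout
    within 3 pooled sd, or (b) both ends are dead ends (no accepted bundle)
    and it is the unique, unconflicted candidate between them.  Accepted
    joins are tagged ``recovered``.  A weak link internal to an existing
    scaffold is ignored (idempotence).
    """
    scaffolds = list(scaffolds)
    recovered: list[LinkBundle] = []
    next_id = max((s.id for s in scaffolds), default=-1) + 1
    acc_at: dict[tuple[int, str], list[LinkBundle]] = defaultdict(list)
    for b in accepted:
        acc_at[(b.contig_a, b.end_a)].append(b)
        acc_at[(b.contig_b, b.end_b)].append(b)
    weak_at: dict[tuple[int, str], list[LinkBundle]] = defaultdict(list)
    for w in weak_candidates:
        weak_at[(w.contig_a, w.end_a)].append(w)
        weak_at[(w.contig_b, w.end_b)].append(w)

    for w in sorted(weak_candidates, key=lambda b: -b.support):
        scaf_of = {}
        for s in scaffolds:
            for p in s.parts:
                scaf_of[p.contig_id] = (s, 0)
        sa = _lift_bundle_side(scaf_of, w.contig_a, w.end_a, contig_lengths,
                               min_wildcard)
        sb = _lift_bundle_side(scaf_of, w.contig_b, w.end_b, contig_lengths,
                               min_wildcard)
        if sa is None or sb is None:
            continue
        if sa[0] == sb[0]:
            continue  # duplicates an existing join: idempotent
        if sa[2] != 0 or sb[2] != 0:
            continue  # not at free scaffold ends
        na = (w.contig_a, w.end_a)
        nb_ = (w.contig_b, w.end_b)
        ok = False
        # (a) corroborating two-hop path through accepted bundles
        for b1 in acc_at[na]:
            mid = ((b1.contig_b, b1.end_b) if (b1.contig_a, b1.end_a) == na
                   else (b1.contig_a, b1.end_a))
            far = (mid[0], "L" if mid[1] == "R" else "R")
            for b2 in acc_at[far]:
                tgt = ((b2.contig_b, b2.end_b) if (b2.contig_a, b2.end_a) == far
                       else (b2.contig_a, b2.end_a))
                if tgt != nb_:
                    continue
                implied = b1.gap_mean + contig_lengths[mid[0]] + b2.gap_mean
                tol = 3 * math.sqrt(b1.gap_sd ** 2 + b2.gap_sd ** 2)
                if abs(w.gap_mean - implied) <= max(tol, 3):
                    ok = True
                    break
            if ok:
                break
        # (b) unique candidate between two dead ends
        if not ok and not acc_at[na] and not acc_at[nb_]:
            if len(weak_at[na]) == 1 and len(weak_at[nb_]) == 1:
                ok = True
        if not ok:
            continue
        s1 = next(s for s in scaffolds if s.id == sa[0])
        s2 = next(s for s in scaffolds if s.id == sb[0])
        joined = _merge_pair(s1, sa[1], s2, sb[1], int(round(w.gap_mean)),
                             next_id)
        next_id += 1
        scaffolds = [s for s in scaffolds if s.id not in (s1.id, s2.id)]
        scaffolds.append(joined)
        w2 = replace(w, status="recovered")
        recovered.append(w2)
    return scaffolds, recovered


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class ScaffoldingResult:
    scaffolds: list[Scaffold]
    het_pairs: list[tuple[int, int]]
    bundles: BundleResult
    recovered: list[LinkBundle]
    n_chimera_cuts: int
    depth: dict[int, float]


def scaffold_pipeline(contigs: list[Unitig], reads: list[Read],
                      min_support: int = 3, max_mismatch: int = 2,
                      min_wildcard: int = 1, detect_het: bool = True,
                      rectify: bool = True, recover_weak: bool = True,
                      repeat_depth_factor: float = 1.5) -> ScaffoldingResult:
    """Full scaffolding pass: map, link, bundle, mask het pairs, build by
    rank with chimera rectification after each later rank, then recover
    weak links."""
    lengths = {c.id: len(c.seq) for c in contigs}
    placements = map_reads_to_contigs(reads, contigs, max_mismatch)
    rl = {r.id: len(r.seq) for r in reads}
    depth = contig_read_depth(contigs, placements, rl)
    coll = collect_pe_links(placements, reads, lengths)
    # bundle per library rank: gap estimates for a junction come from the
    # rank that builds it (mixing insert sizes would length-bias the gaps)
    by_rank: dict[int, list[PELink]] = defaultdict(list)
    for ln in coll.links:
        by_rank[ln.library.rank].append(ln)
    bres = BundleResult()
    for r in sorted(by_rank):
        sub = bundle_links(by_rank[r], min_support, correct_length_bias=True)
        bres.accepted.extend(sub.accepted)
        bres.weak.extend(sub.weak)
        bres.conflicts.extend(sub.conflicts)
    het = (detect_het_pairs(contigs, bres.all(), depth)
           if detect_het else [])
    masked = {dropped for _, dropped in het}
    # contigs at well over modal depth are repeat copies: their links point
    # to several loci at once, so they are kept out of linearization (they
    # stay in the output as singletons; gap closing can restore their
    # sequence inside the joined gaps)
    mode = modal_depth(contigs, depth)
    repeatish = {c.id for c in contigs if depth[c.id] > repeat_depth_factor * mode}
    usable = [b for b in bres.accepted
              if b.contig_a not in masked and b.contig_b not in masked
              and b.contig_a not in repeatish and b.contig_b not in repeatish]
    ranks = sorted({b.rank for b in usable}) or [1]
    scaffolds = [Scaffold(c.id, [ScaffoldPart(c.id, "+", None)])
                 for c in contigs if c.id not in masked]
    next_id = (max((c.id for c in contigs), default=-1)) + 1
    n_cuts = 0
    for ri, rank in enumerate(ranks):
        rb = [b for b in usable if b.rank == rank]
        sbs = _lift_bundles(rb, scaffolds, lengths, min_wildcard)
        scaf_len = {s.id: s.length(lengths, min_wildcard) for s in scaffolds}
        sbs = _transitive_reduce(sbs, scaf_len)
        scaffolds, next_id = _linearize(scaffolds, sbs, lengths, next_id,
                                        min_wildcard)
        if rectify and ri > 0:
            scaffolds, c = rectify_chimeras(scaffolds, rb, lengths,
                                            min_support, min_wildcard)
            n_cuts += c
    recovered: list[LinkBundle] = []
    if recover_weak:
        scaffolds, recovered = recover_weak_links(scaffolds, usable,
                                                  bres.weak, lengths,
                                                  min_wildcard)
    return ScaffoldingResult(scaffolds=scaffolds, het_pairs=het, bundles=bres,
                             recovered=recovered, n_chimera_cuts=n_cuts,
                             depth=depth)
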