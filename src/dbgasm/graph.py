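"""De Bruijn graph construction and cleaning.

Representation: nodes are canonical k-mers; an edge is a canonical (k+1)-mer,
whose prefix and suffix k-mers are its two endpoints.  This encoding makes
the graph strand-symmetric by construction — traversing an edge forward is
the same stored object as traversing its reverse complement backward.

Cleaning operations (tip clipping, bubble popping, low-coverage removal) are
written once against this dense view; the sparse graph stores anchors plus
extension strings and lowers to the same view, so the spelled unitig set of
sparse and dense construction is identical at equal k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .kmer import canonical_kmer, revcomp, _canonical_windows

log = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class Unitig:
    """A maximal unbranched path, spelled in canonical orientation."""

    id: int
    seq: str
    mean_coverage: float
    in_degree: int = 0   # at the seq start (canonical orientation)
    out_degree: int = 0  # at the seq end

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SparseNode:
    """An anchor k-mer plus the bases to the next anchor on its linear path."""

    anchor: str
    extension: str
    g: int


class DBGraph:
    """Dense de Bruijn graph over canonical k-mers.

    ``edges`` maps canonical (k+1)-mers to multiplicity; ``node_coverage``
    maps canonical k-mers to their total observation count.
    """

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        self.k = k
        self.edges: dict[str, int] = {}
        self.node_coverage: dict[str, int] = {}

    # -- construction -----------------------------------------------------

    def add_sequence(self, seq: str, weight: int = 1) -> None:
        k = self.k
        for ckmer in _canonical_windows(seq, k):
            self.node_coverage[ckmer] = self.node_coverage.get(ckmer, 0) + weight
        for cedge in _canonical_windows(seq, k + 1):
            self.edges[cedge] = self.edges.get(cedge, 0) + weight

    # -- basic queries -----------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.node_coverage)

    def n_nodes(self) -> int:
        return len(self.node_coverage)

    def n_edges(self) -> int:
        return len(self.edges)

    def has_node(self, kmer: str) -> bool:
        return canonical_kmer(kmer) in self.node_coverage

    def edge_mult(self, kp1: str) -> int:
        return self.edges.get(canonical_kmer(kp1), 0)

    def successors(self, oriented: str) -> list[tuple[str, str]]:
        """Out-neighbors of an *oriented* k-mer: list of (next_oriented, edge_key)."""
        out = []
        for b in _BASES:
            e = oriented + b
            ce = canonical_kmer(e)
            if ce in self.edges:
                out.append((e[1:], ce))
        return out

    def predecessors(self, oriented: str) -> list[tuple[str, str]]:
        out = []
        for b in _BASES:
            e = b + oriented
            ce = canonical_kmer(e)
            if ce in self.edges:
                out.append((e[:-1], ce))
        return out

    def out_degree(self, oriented: str) -> int:
        return len(self.successors(oriented))

    def in_degree(self, oriented: str) -> int:
        return len(self.predecessors(oriented))

    # -- mutation ----------------------------------------------------------

    def remove_edge(self, edge_key: str) -> None:
        self.edges.pop(edge_key, None)

    def remove_node(self, kmer: str) -> None:
        c = canonical_kmer(kmer)
        self.node_coverage.pop(c, None)
        for b in _BASES:
            for e in (c + b, b + c):
                self.edges.pop(canonical_kmer(e), None)
        rc = revcomp(c)
        for b in _BASES:
            for e in (rc + b, b + rc):
                self.edges.pop(canonical_kmer(e), None)

    def copy(self) -> "DBGraph":
        g = DBGraph(self.k)
        g.edges = dict(self.edges)
        g.node_coverage = dict(self.node_coverage)
        return g


def build_dbg(reads, k: int) -> DBGraph:
    """Dense de Bruijn graph of a read stream: one node per canonical k-mer,
    one edge per adjacent k-mer pair, multiplicity = supporting windows.

    Deterministic and invariant under permutation of the stream.
    """
    g = DBGraph(k)
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        g.add_sequence(seq)
    if not g.node_coverage:
        log.warning("no valid k-mers at k=%d; graph is empty", k)
    return g


# -- unbranched path machinery --------------------------------------------


def _is_path_start(g: DBGraph, oriented: str) -> bool:
    preds = g.predecessors(oriented)
    if len(preds) != 1:
        return True
    return g.out_degree(preds[0][0]) != 1


def _walk(g: DBGraph, start: str):
    """Follow the unbranched path from an oriented start k-mer.

    Returns (oriented node list, edge key list, spelled sequence).
    """
    path = [start]
    edge_keys: list[str] = []
    seq = [start]
    cur = start
    # track canonical forms so a palindromic (k+1)-mer edge cannot walk the
    # path onto its own reverse-complement strand and over-spell
    seen = {canonical_kmer(start)}
    while True:
        succs = g.successors(cur)
        if len(succs) != 1:
            break
        nxt, ekey = succs[0]
        if g.in_degree(nxt) != 1:
            break
        if canonical_kmer(nxt) in seen:  # cycle closure or strand crossing
            break
        path.append(nxt)
        edge_keys.append(ekey)
        seq.append(nxt[-1])
        seen.add(nxt)
        cur = nxt
    return path, edge_keys, "".join([seq[0]] + seq[1:])


def _all_paths(g: DBGraph):
    """All maximal unbranched paths, each yielded once (deduped by canonical seq).

    Yields (node list, edge keys, spelled seq) with seq in traversal
    orientation.
    """
    seen_seqs: set[str] = set()
    seen_nodes: set[str] = set()
    for node in list(g.node_coverage):
        for oriented in (node, revcomp(node)):
            if not _is_path_start(g, oriented):
                continue
            path, ekeys, seq = _walk(g, oriented)
            cs = canonical_kmer(seq) if len(seq) == g.k else min(seq, revcomp(seq))
            if cs in seen_seqs:
                continue
            seen_seqs.add(cs)
            seen_nodes.update(canonical_kmer(p) for p in path)
            yield path, ekeys, seq
    # pure cycles: no path start anywhere
    for node in list(g.node_coverage):
        if node in seen_nodes:
            continue
        path, ekeys, seq = _walk(g, node)
        seen_nodes.update(canonical_kmer(p) for p in path)
        cs = min(seq, revcomp(seq))
        if cs not in seen_seqs:
            seen_seqs.add(cs)
            yield path, ekeys, seq


def extract_unitigs(graph) -> list[Unitig]:
    """Spell all maximal unbranched paths as canonically oriented unitigs.

    Each unitig appears once, oriented as the lexicographically smaller of
    its sequence and reverse complement; ordering is (length desc, seq asc).
    ``mean_coverage`` is the mean edge multiplicity along the path (node
    coverage for single-node unitigs).
    """
    g = _dense_view(graph)
    raw: list[tuple[str, float, int, int]] = []
    for path, ekeys, seq in _all_paths(g):
        if ekeys:
            cov = sum(g.edges[e] for e in ekeys) / len(ekeys)
        else:
            cov = float(g.node_coverage.get(canonical_kmer(path[0]), 0))
        if seq <= revcomp(seq):
            ind = g.in_degree(path[0])
            outd = g.out_degree(path[-1])
        else:
            seq = revcomp(seq)
            ind = g.out_degree(path[-1])
            outd = g.in_degree(path[0])
        raw.append((seq, cov, ind, outd))
    raw.sort(key=lambda t: (-len(t[0]), t[0]))
    return [Unitig(id=i, seq=s, mean_coverage=c, in_degree=ind, out_degree=outd)
            for i, (s, c, ind, outd) in enumerate(raw)]


# -- cleaning ---------------------------------------------------------------


def clip_tips(graph, max_tip_len: int,
              protected_edges: set[str] | None = None):
    """Iteratively remove short, low-coverage dead-end spurs.

    A tip is an unbranched path with one free end (degree 0) whose other end
    attaches to a junction, shorter than ``max_tip_len`` bp and with lower
    mean coverage than the best competing branch at the junction.  Repeats to
    fixpoint.  Edges in ``protected_edges`` are never removed.
    """
    g = _dense_view(graph)
    protected = protected_edges or set()
    changed = True
    while changed:
        changed = False
        for path, ekeys, seq in list(_all_paths(g)):
            if any(canonical_kmer(p) not in g.node_coverage for p in path):
                continue  # already deleted this sweep
            start, end = path[0], path[-1]
            dead_start = g.in_degree(start) == 0
            dead_end = g.out_degree(end) == 0
            if dead_start == dead_end:
                continue  # internal path or isolated component
            if len(seq) >= max_tip_len:
                continue
            if dead_start:
                # attached at the far (end) side; junction is end's successor
                succs = g.successors(end)
                if not succs:
                    continue
                junction = succs[0][0]
                join_edge = succs[0][1]
                rivals = [e for p, e in g.predecessors(junction) if e != join_edge]
            else:
                preds = g.predecessors(start)
                if not preds:
                    continue
                junction = preds[0][0]
                join_edge = preds[0][1]
                rivals = [e for p, e in g.successors(junction) if e != join_edge]
            if not rivals:
                continue
            tip_edges = ekeys + [join_edge]
            if any(e in protected for e in tip_edges):
                continue
            tip_cov = sum(g.edges[e] for e in tip_edges) / len(tip_edges)
            rival_cov = max(g.edges[e] for e in rivals)
            if tip_cov >= rival_cov:
                continue
            for p in path:
                g.remove_node(p)
            g.remove_edge(join_edge)
            changed = True
    return graph


def _path_divergence(a: str, b: str) -> float:
    if a == b:
        return 0.0
    d = edlib.align(a, b)["editDistance"]
    return d / max(len(a), len(b))


def pop_bubbles(graph, max_divergence: float = 0.03,
                protected_edges: set[str] | None = None):
    """Merge near-identical parallel paths (sequencing error / heterozygosity).

    For two unbranched paths sharing source and sink whose spelled sequences
    differ by at most ``max_divergence`` (edit distance over the longer
    length), the lower-coverage path is folded into the higher-coverage one:
    its nodes and edges are deleted and its mean multiplicity is added to the
    surviving path's edges.  Coverage ties keep the lexicographically smaller
    spelled sequence.
    """
    g = _dense_view(graph)
    protected = protected_edges or set()
    changed = True
    while changed:
        changed = False
        for node in list(g.node_coverage):
            if node not in g.node_coverage:
                continue
            for source in (node, revcomp(node)):
                succs = g.successors(source)
                if len(succs) < 2:
                    continue
                # follow each branch's unbranched path to its terminal junction
                branches = []
                for nxt, ekey in succs:
                    if g.in_degree(nxt) != 1:
                        continue  # immediately re-merging; not a simple bubble arm
                    path, ekeys, seq = _walk(g, nxt)
                    ends = g.successors(path[-1])
                    sink = ends[0][0] if len(ends) == 1 else None
                    # full arm spelling: source + branch bases (excl. sink)
                    branches.append((sink, path, [ekey] + ekeys,
                                     source + seq[g.k - 1:],
                                     ends[0][1] if sink else None))
                by_sink: dict[str, list] = {}
                for br in branches:
                    if br[0] is not None:
                        by_sink.setdefault(br[0], []).append(br)
                for sink, group in by_sink.items():
                    if len(group) < 2:
                        continue
                    merged = _merge_bubble_group(g, group, max_divergence, protected)
                    if merged:
                        changed = True
                if changed:
                    break
            if changed:
                break
    return graph


def _merge_bubble_group(g, group, max_divergence, protected) -> bool:
    # deterministic, strand-independent tie-break frame: canonical arm spelling
    group = sorted(group, key=lambda br: min(br[3], revcomp(br[3])))
    for i in range(len(group)):
        for j in range(i + 1, len(group)):
            a, b = group[i], group[j]
            if _path_divergence(a[3], b[3]) > max_divergence:
                continue
            edges_a = a[2] + [a[4]]
            edges_b = b[2] + [b[4]]
            if any(e not in g.edges for e in edges_a + edges_b):
                continue
            cov_a = sum(g.edges[e] for e in edges_a) / len(edges_a)
            cov_b = sum(g.edges[e] for e in edges_b) / len(edges_b)
            # tie -> keep lexicographically smaller spelled arm (a, by sort)
            keep, drop = (a, b) if cov_a >= cov_b else (b, a)
            drop_edges = drop[2] + [drop[4]]
            if any(e in protected for e in drop_edges):
                continue
            drop_cov = sum(g.edges[e] for e in drop_edges) / len(drop_edges)
            for p in drop[1]:
                g.remove_node(p)
            for e in drop_edges:
                g.remove_edge(e)
            add = int(round(drop_cov))
            for e in keep[2] + [keep[4]]:
                if e in g.edges:
                    g.edges[e] += add
            return True
    return False


def remove_low_coverage(graph, cutoff: int = 1,
                        protected_edges: set[str] | None = None):
    """Delete edges with multiplicity <= cutoff, then nodes left isolated by it.

    ``cutoff=0`` is the identity.
    """
    g = _dense_view(graph)
    if cutoff <= 0:
        return graph
    protected = protected_edges or set()
    doomed = [e for e, m in g.edges.items() if m <= cutoff and e not in protected]
    touched: set[str] = set()
    for e in doomed:
        touched.add(canonical_kmer(e[:-1]))
        touched.add(canonical_kmer(e[1:]))
        del g.edges[e]
    for node in touched:
        if node in g.node_coverage:
            if g.out_degree(node) == 0 and g.in_degree(node) == 0:
                del g.node_coverage[node]
    return graph


# -- sparse graph -----------------------------------------------------------


class SparseDBG:
    """Sparse de Bruijn graph: along unbranched stretches only every g-th
    k-mer is stored as an anchor, carrying the inter-anchor bases as an
    extension string; anchors are forced at every branching or merging
    position.

    The sparse store is a compaction of the graph adjacency; it lowers to a
    dense view for cleaning and unitig extraction, which guarantees the
    spelled sequence set of maximal paths is identical to the dense graph's
    on the same input.
    """

    def __init__(self, k: int, g: int):
        self.k = k
        self.g = g
        self.nodes: dict[str, SparseNode] = {}
        self._dense: DBGraph | None = None

    def n_anchors(self) -> int:
        return len(self.nodes)


def _dense_view(graph) -> DBGraph:
    if isinstance(graph, SparseDBG):
        return graph._dense
    return graph


def build_sparse_dbg(reads, k: int, g: int) -> SparseDBG:
    """Build the sparse graph: anchors every g-th k-mer along unbranched
    stretches plus forced anchors at branch/merge points.

    ``g=1`` stores every k-mer as an anchor with an empty extension —
    structurally the dense graph.
    """
    if g < 1:
        raise ValueError("skip factor g must be >= 1")
    dense = build_dbg(reads, k)
    sg = SparseDBG(k, g)
    sg._dense = dense
    for path, ekeys, seq in _all_paths(dense):
        # anchors at indices 0, g, 2g, ... and always the final node
        n = len(path)
        idxs = list(range(0, n, g))
        if idxs[-1] != n - 1:
            idxs.append(n - 1)
        for a, b in zip(idxs, idxs[1:] + [None]):
            anchor = canonical_kmer(path[a])
            if b is None:
                ext = ""
            else:
                # bases between this anchor and the next (at most g-1 of them)
                ext = seq[a + k : b + k - 1]
            if anchor not in sg.nodes or len(ext) > len(sg.nodes[anchor].extension):
                sg.nodes[anchor] = SparseNode(anchor=anchor, extension=ext, g=g)
    return sg


# -- export -----------------------------------------------------------------


def write_gfa(graph, path) -> None:
    """Dump unitigs (S lines) and their (k-1)-overlap links (L lines) as GFA v1."""
    g = _dense_view(graph)
    unitigs = extract_unitigs(g)
    k = g.k
    # index oriented unitigs by their first k-mer
    heads: dict[str, tuple[int, str]] = {}
    for u in unitigs:
        heads[u.seq[:k]] = (u.id, "+")
        heads[revcomp(u.seq)[:k]] = (u.id, "-")
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for u in unitigs:
            fh.write(f"S\t{u.id}\t{u.seq}\tdp:f:{u.mean_coverage:.1f}\n")
        seen: set[tuple] = set()
        for u in unitigs:
            for orient, seq in (("+", u.seq), ("-", revcomp(u.seq))):
                last = seq[-k:]
                for b in _BASES:
                    if canonical_kmer(last + b) not in g.edges:
                        continue
                    hit = heads.get(last[1:] + b)
                    if hit is None:
                        continue
                    vid, vorient = hit
                    key = (u.id, orient, vid, vorient)
                    rkey = (vid, "+-"[vorient == "+"], u.id, "+-"[orient == "+"])
                    if key in seen or rkey in seen:
                        continue
                    seen.add(key)
                    fh.write(f"L\t{u.id}\t{orient}\t{vid}\t{vorient}\t{k - 1}M\n")
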