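"""k-mer spectrum read correction.

A k-mer seen often enough across the dataset is *trusted*; a sequencing
error turns up to k consecutive windows of a read into rare, untrusted
k-mers.  Correction searches for the substitution(s) that restore every
window to the trusted set.  Two search modes are provided:

* **fast** — greedy left-to-right: at the first untrusted window, try the
  three alternative bases at each position covered only by untrusted
  windows (starting from the last base of the first untrusted window, where
  an isolated error must sit) and accept the unique fix; repeat up to
  ``max_edits`` times.
* **deep** — bounded depth-first search over joint substitutions, scoring
  candidates by (untrusted windows remaining, then total spectrum count of
  the windows); ties are reported as ambiguous and the read left unchanged.

Correction is substitution-only: read length never changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .io_config import Read
from .kmer import KmerSpectrum, SpacedPattern, canonical_kmer, spaced_kmer

log = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class CorrectionResult:
    read_id: str
    status: str  # unchanged | corrected | uncorrectable | ambiguous
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    n_untrusted_before: int = 0
    n_untrusted_after: int = 0
    seq: str = ""


def set_trusted_cutoff(spectrum: KmerSpectrum, mode: str = "auto",
                       fixed_value: int | None = None) -> KmerSpectrum:
    """Set the trusted/untrusted count cutoff on a spectrum (in place).

    ``auto`` places the cutoff at the first local minimum of the
    count-of-counts histogram between the error peak (count 1) and the
    coverage peak; a unimodal histogram falls back to cutoff 2 with a
    warning.  ``fixed`` uses ``fixed_value``.  The cutoff is always >= 1.
    """
    if mode == "fixed":
        if fixed_value is None or fixed_value < 1:
            raise ValueError("fixed mode needs fixed_value >= 1")
        spectrum.trusted_cutoff = fixed_value
        return spectrum
    if mode != "auto":
        raise ValueError(f"unknown cutoff mode {mode!r}")
    if not spectrum.counts:
        raise ValueError("auto cutoff requires a non-empty spectrum")
    hist = spectrum.histogram()
    max_c = max(hist)
    h = [hist.get(c, 0) for c in range(max_c + 2)]  # h[c]; h[max_c+1] == 0
    # coverage peak: the most populated count after the initial descent
    valley = None
    for c in range(2, max_c + 1):
        if h[c] <= h[c - 1] and h[c] <= h[c + 1]:
            # require real k-mer mass beyond the valley (a coverage peak)
            if any(h[d] > h[c] for d in range(c + 1, max_c + 1)):
                valley = c
                break
    if valley is None:
        log.warning("unimodal k-mer histogram: falling back to trusted cutoff 2")
        spectrum.trusted_cutoff = 2
    else:
        spectrum.trusted_cutoff = max(valley, 1)
    return spectrum


def _untrusted_windows(seq: str, spectrum: KmerSpectrum) -> list[int]:
    """Offsets of untrusted k-windows (windows containing N count as untrusted)."""
    k = spectrum.k
    out = []
    for i in range(len(seq) - k + 1):
        if not spectrum.is_trusted(seq[i : i + k]):
            out.append(i)
    return out


def _positions_only_untrusted(seq_len: int, k: int, untrusted: list[int],
                              first: int) -> list[int]:
    """Candidate edit positions: bases covered by no trusted window, ordered
    from the last base of the first untrusted window outward."""
    uset = set(untrusted)
    n_win = seq_len - k + 1
    cands = []
    lo = first
    hi = min(first + k, seq_len)
    for pos in range(lo, hi):
        covering = range(max(0, pos - k + 1), min(pos, n_win - 1) + 1)
        if all(w in uset for w in covering):
            cands.append(pos)
    anchor = min(first + k - 1, seq_len - 1)
    cands.sort(key=lambda p: (abs(p - anchor), -p))
    return cands


def _windows_covering(pos: int, seq_len: int, k: int) -> range:
    return range(max(0, pos - k + 1), min(pos, seq_len - k) + 1)


def _fix_clears_position(seq: str, pos: int, base: str,
                         spectrum: KmerSpectrum) -> bool:
    k = spectrum.k
    trial = seq[:pos] + base + seq[pos + 1:]
    return all(spectrum.is_trusted(trial[w : w + k])
               for w in _windows_covering(pos, len(seq), k))


def _spaced_ok(seq: str, pos: int, spectrum_spaced, pattern) -> bool:
    """Optional corroboration: spaced k-mers covering the edited site must be
    trusted too (skipped when no spaced spectrum is supplied)."""
    if spectrum_spaced is None:
        return True
    span = pattern.span
    ok = True
    for off in range(max(0, pos - span + 1), min(pos, len(seq) - span) + 1):
        try:
            sk = spaced_kmer(seq, off, pattern)
        except ValueError:
            continue
        if not spectrum_spaced.is_trusted(sk):
            ok = False
            break
    return ok


def correct_read_fast(read: Read, spectrum: KmerSpectrum, max_edits: int = 2,
                      spaced_spectrum: KmerSpectrum | None = None,
                      spaced_pattern: SpacedPattern | None = None) -> CorrectionResult:
    """Greedy single-site correction (see module docstring)."""
    k = spectrum.k
    seq = read.seq
    before = _untrusted_windows(seq, spectrum)
    if not before:
        return CorrectionResult(read.id, "unchanged", [], 0, 0, seq)
    edits: list[tuple[int, str, str]] = []
    cur = seq
    for _ in range(max_edits):
        untrusted = _untrusted_windows(cur, spectrum)
        if not untrusted:
            break
        first = untrusted[0]
        applied = False
        for pos in _positions_only_untrusted(len(cur), k, untrusted, first):
            fixes = [b for b in _BASES
                     if b != cur[pos] and _fix_clears_position(cur, pos, b, spectrum)]
            if len(fixes) > 1:
                return CorrectionResult(read.id, "ambiguous", [],
                                        len(before), len(before), seq)
            if len(fixes) == 1:
                trial = cur[:pos] + fixes[0] + cur[pos + 1:]
                if not _spaced_ok(trial, pos, spaced_spectrum, spaced_pattern):
                    continue
                edits.append((pos, cur[pos], fixes[0]))
                cur = trial
                applied = True
                break
        if not applied:
            return CorrectionResult(read.id, "uncorrectable", [],
                                    len(before), len(before), seq)
    after = _untrusted_windows(cur, spectrum)
    if after:
        return CorrectionResult(read.id, "uncorrectable", [],
                                len(before), len(before), seq)
    return CorrectionResult(read.id, "corrected", edits, len(before), 0, cur)


def _score(seq: str, spectrum: KmerSpectrum) -> tuple[int, int]:
    """Candidate score: (untrusted windows — lower better, -sum of window counts)."""
    k = spectrum.k
    n_un = 0
    total = 0
    for i in range(len(seq) - k + 1):
        c = spectrum.count(seq[i : i + k])
        if c < spectrum.trusted_cutoff:
            n_un += 1
        total += c
    return (n_un, -total)


def correct_read_deep(read: Read, spectrum: KmerSpectrum, budget: int = 64,
                      max_edits: int = 2) -> CorrectionResult:
    """Bounded DFS over joint substitutions (see module docstring)."""
    k = spectrum.k
    seq = read.seq
    before = _untrusted_windows(seq, spectrum)
    if not before:
        return CorrectionResult(read.id, "unchanged", [], 0, 0, seq)

    explored = 0
    candidates: list[tuple[tuple[int, int], str, tuple]] = []

    def dfs(cur: str, edits: tuple, depth: int) -> None:
        nonlocal explored
        if explored >= budget:
            return
        untrusted = _untrusted_windows(cur, spectrum)
        if not untrusted:
            candidates.append((_score(cur, spectrum), cur, edits))
            return
        if depth >= max_edits:
            return
        first = untrusted[0]
        for pos in _positions_only_untrusted(len(cur), k, untrusted, first):
            for b in _BASES:
                if b == cur[pos]:
                    continue
                if explored >= budget:
                    return
                explored += 1
                trial = cur[:pos] + b + cur[pos + 1:]
                # only descend when the edit clears every window covering pos
                if _fix_clears_position(cur, pos, b, spectrum) or depth + 1 < max_edits:
                    dfs(trial, edits + ((pos, cur[pos], b),), depth + 1)

    dfs(seq, (), 0)
    if not candidates:
        return CorrectionResult(read.id, "uncorrectable", [],
                                len(before), len(before), seq)
    candidates.sort(key=lambda t: (t[0], t[1]))
    best = candidates[0]
    rivals = [c for c in candidates if c[0] == best[0] and c[1] != best[1]]
    if rivals:
        return CorrectionResult(read.id, "ambiguous", [],
                                len(before), len(before), seq)
    return CorrectionResult(read.id, "corrected", list(best[2]),
                            len(before), 0, best[1])


def correct_library(reads: Iterable[Read], spectrum: KmerSpectrum,
                    mode: str = "fast_then_deep", max_edits: int = 2,
                    budget: int = 64, drop_uncorrectable: bool = False,
                    ) -> tuple[list[Read], dict[str, int]]:
    """Correct a read stream; returns (corrected reads in input order, status counts).

    ``fast_then_deep`` runs the deep search only on reads the fast pass could
    not fully fix, so its corrected count dominates ``fast`` alone on every
    input.
    """
    if mode not in ("fast", "deep", "fast_then_deep"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list[Read] = []
    summary = {"unchanged": 0, "corrected": 0, "uncorrectable": 0, "ambiguous": 0}
    for read in reads:
        if len(read.seq) < spectrum.k:
            summary["uncorrectable"] += 1
            if not drop_uncorrectable:
                out.append(read)
            continue
        if mode in ("fast", "fast_then_deep"):
            res = correct_read_fast(read, spectrum, max_edits=max_edits)
            if mode == "fast_then_deep" and res.status in ("uncorrectable", "ambiguous"):
                deep = correct_read_deep(read, spectrum, budget=budget,
                                         max_edits=max_edits)
                if deep.status == "corrected":
                    res = deep
        else:
            res = correct_read_deep(read, spectrum, budget=budget,
                                    max_edits=max_edits)
        summary[res.status] += 1
        if res.status == "corrected":
            out.append(Read(id=read.id, seq=res.seq, qual=read.qual,
                            mate_id=read.mate_id, library=read.library))
        elif res.status in ("uncorrectable", "ambiguous") and drop_uncorrectable:
            continue
        else:
            out.append(read)
    return out, summary
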