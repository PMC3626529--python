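"""k-mer primitives: canonicalization, counting, and spaced (gapped) k-mers.

All de Bruijn graph machinery in this package works on *canonical* k-mers
(the lexicographic minimum of a k-mer and its reverse complement), so the
two strands of a molecule always hash to the same entry.  k is kept odd
throughout so no k-mer can be its own reverse complement except true
palindromes of even length, which odd k rules out entirely.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N, case preserved)."""
    return seq.translate(_COMP)[::-1]


def canonical_kmer(seq: str) -> str:
    """Return the lexicographically smaller of ``seq`` and its reverse complement.

    Raises ``ValueError`` if the k-mer contains a base outside {A,C,G,T};
    callers are expected to skip such windows.
    """
    if not set(seq) <= VALID_BASES:
        raise ValueError(f"k-mer contains non-ACGT base: {seq!r}")
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def kmerize(seq: str, k: int) -> list[tuple[int, str]]:
    """All N-free k-length windows of ``seq`` as (offset, kmer), offsets increasing.

    Windows containing N (or any non-ACGT character) are skipped.  The k-mers
    are returned *as spelled* (not canonicalized).
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    n = len(seq)
    if n < k:
        return []
    # positions of invalid characters; a window [i, i+k) is valid iff no
    # invalid position falls inside it
    bad = [i for i, c in enumerate(seq) if c not in VALID_BASES]
    out: list[tuple[int, str]] = []
    if not bad:
        return [(i, seq[i : i + k]) for i in range(n - k + 1)]
    bad_idx = 0
    next_bad = bad[0]
    for i in range(n - k + 1):
        while next_bad is not None and next_bad < i:
            bad_idx += 1
            next_bad = bad[bad_idx] if bad_idx < len(bad) else None
        if next_bad is None or next_bad >= i + k:
            out.append((i, seq[i : i + k]))
    return out


@dataclass
class SpacedPattern:
    """A gapped seed: ``n_blocks`` runs of ``block`` matched positions separated
    by ``skip`` ignored positions.

    ``skip=0`` degenerates to a consecutive k-mer of length ``n_blocks*block``.
    """

    block: int
    skip: int
    n_blocks: int = 2

    def __post_init__(self) -> None:
        if self.block < 1 or self.skip < 0 or self.n_blocks < 2:
            raise ValueError("need block >= 1, skip >= 0, n_blocks >= 2")

    @property
    def span(self) -> int:
        return self.n_blocks * self.block + (self.n_blocks - 1) * self.skip

    @property
    def weight(self) -> int:
        """Number of matched positions (the spaced k-mer's length)."""
        return self.n_blocks * self.block


def default_spaced_pattern(k: int, skip: int = 4) -> SpacedPattern:
    """Two blocks of ceil(k/2) with a middle skip — the default gapped seed."""
    return SpacedPattern(block=(k + 1) // 2, skip=skip, n_blocks=2)


def spaced_kmer(seq: str, offset: int, pattern: SpacedPattern) -> str:
    """Extract the spaced k-mer of ``pattern`` at ``offset``.

    Concatenates the matched blocks, skipping ``pattern.skip`` bases between
    them.  Raises ``ValueError`` if the pattern span exceeds the sequence or a
    matched position is not ACGT.
    """
    if offset < 0 or offset + pattern.span > len(seq):
        raise ValueError("spaced pattern span exceeds sequence")
    parts = []
    pos = offset
    for _ in range(pattern.n_blocks):
        parts.append(seq[pos : pos + pattern.block])
        pos += pattern.block + pattern.skip
    out = "".join(parts)
    if not set(out) <= VALID_BASES:
        raise ValueError("spaced k-mer covers a non-ACGT base")
    return out


@dataclass
class KmerSpectrum:
    """Canonical k-mer -> count table with a trusted/untrusted cutoff.

    A k-mer is *trusted* when its canonical count is >= ``trusted_cutoff``.
    Querying a k-mer and its reverse complement always returns the same count.
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    trusted_cutoff: int = 1

    def count(self, kmer: str) -> int:
        try:
            return self.counts.get(canonical_kmer(kmer), 0)
        except ValueError:
            return 0

    def is_trusted(self, kmer: str) -> bool:
        return self.count(kmer) >= self.trusted_cutoff

    def add(self, kmer: str, n: int = 1) -> None:
        c = canonical_kmer(kmer)
        self.counts[c] = self.counts.get(c, 0) + n

    def histogram(self) -> Counter:
        """Count-of-counts histogram: multiplicity -> number of distinct k-mers."""
        return Counter(self.counts.values())

    def total_mass(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def dump_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")


def _canonical_windows(seq: str, k: int) -> Iterator[str]:
    """Canonical k-mers of all valid windows, computed with one revcomp per read."""
    n = len(seq)
    if n < k:
        return
    rc = revcomp(seq)
    bad = [i for i, c in enumerate(seq) if c not in VALID_BASES]
    bad_idx = 0
    next_bad = bad[0] if bad else None
    for i in range(n - k + 1):
        while next_bad is not None and next_bad < i:
            bad_idx += 1
            next_bad = bad[bad_idx] if bad_idx < len(bad) else None
        if next_bad is not None and next_bad < i + k:
            continue
        fwd = seq[i : i + k]
        rev = rc[n - k - i : n - i]
        yield fwd if fwd <= rev else rev


def count_kmers(reads: Iterable, k: int) -> KmerSpectrum:
    """Count canonical k-mers across a read stream.

    Accepts an iterable of objects with a ``.seq`` attribute (or raw strings).
    Deterministic, and invariant under permutation of the stream.  If ``k``
    exceeds every read length the spectrum is empty (with a warning).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    counts: dict[str, int] = {}
    saw_read = False
    saw_window = False
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        saw_read = True
        for ckmer in _canonical_windows(seq, k):
            saw_window = True
            counts[ckmer] = counts.get(ckmer, 0) + 1
    if saw_read and not saw_window:
        log.warning("k=%d longer than every read; spectrum is empty", k)
    return KmerSpectrum(k=k, counts=counts)


def count_spaced_kmers(reads: Iterable, pattern: SpacedPattern) -> KmerSpectrum:
    """Count canonical spaced k-mers (every valid offset) across a read stream.

    The spectrum's ``k`` is the pattern weight (number of matched positions).
    """
    counts: dict[str, int] = {}
    span = pattern.span
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        for off in range(len(seq) - span + 1):
            try:
                sk = canonical_kmer(spaced_kmer(seq, off, pattern))
            except ValueError:
                continue
            counts[sk] = counts.get(sk, 0) + 1
    return KmerSpectrum(k=pattern.weight, counts=counts)
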