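"""Assembly evaluation: N50/NG50 statistics and truth-based alignment metrics.

Alignment uses seeded exact-match chaining (31-mer seeds, maximal ungapped
extension) rather than a full aligner — adequate for the toy-scale,
truth-known genomes this package targets.  The structural-error definition
is operational: an assembled sequence whose consecutive aligned blocks map
to non-collinear or distant reference loci contributes one error per
offending junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .kmer import revcomp


@dataclass
class AssemblyStats:
    n_seqs: int
    total_len: int
    n50: int
    ng50: int | None
    largest: int


@dataclass
class AlignmentReport:
    reference_coverage: float
    structural_errors: int
    blocks: list[tuple[int, int, int, int, str]] = field(default_factory=list)
    # (asm_seq_index, asm_start, ref_start, length, strand)


def n50_stats(lengths: list[int], genome_size: int | None = None) -> AssemblyStats:
    """N50 (and NG50 when ``genome_size`` is given) of a length list.

    N50 is the largest L such that sequences of length >= L sum to at least
    half the assembly; NG50 replaces half the assembly by half the genome
    size and is None when unreachable.
    """
    if not lengths:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    ls = sorted(lengths, reverse=True)
    total = sum(ls)

    def _nx(target: float) -> int | None:
        acc = 0
        for l in ls:
            acc += l
            if acc >= target:
                return l
        return None

    n50 = _nx(total / 2)
    ng50 = _nx(genome_size / 2) if genome_size is not None else None
    return AssemblyStats(n_seqs=len(ls), total_len=total, n50=n50,
                         ng50=ng50, largest=ls[0])


_SEED = 31


def _ref_index(ref: str) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(ref) - _SEED + 1):
        idx.setdefault(ref[i : i + _SEED], []).append(i)
    return idx


def _align_blocks(seq: str, ref: str, idx: dict[str, list[int]]):
    """Greedy seeded chaining of one assembled sequence against the reference.

    Returns maximal ungapped exact blocks (asm_start, ref_start, length,
    strand), walking left to right and jumping past each extended block.
    """
    blocks = []
    n = len(seq)
    i = 0
    while i + _SEED <= n:
        hit = None
        for strand, s in (("+", seq), ("-", None)):
            if strand == "+":
                positions = idx.get(seq[i : i + _SEED])
                if positions:
                    hit = ("+", positions[0])
                    break
            else:
                rc = revcomp(seq[i : i + _SEED])
                positions = idx.get(rc)
                if positions:
                    hit = ("-", positions[0])
                    break
        if hit is None:
            i += 1
            continue
        strand, rpos = hit
        if strand == "+":
            a, r = i, rpos
            while a > 0 and r > 0 and seq[a - 1] == ref[r - 1]:
                a -= 1
                r -= 1
            a2, r2 = i + _SEED, rpos + _SEED
            while a2 < n and r2 < len(ref) and seq[a2] == ref[r2]:
                a2 += 1
                r2 += 1
            blocks.append((a, r, a2 - a, "+"))
            i = a2
        else:
            # seed seq[i:i+S] == revcomp(ref[rpos:rpos+S])
            a, r2 = i, rpos + _SEED
            while a > 0 and r2 < len(ref) and seq[a - 1] == revcomp(ref[r2]):
                a -= 1
                r2 += 1
            a2, r = i + _SEED, rpos
            while a2 < n and r > 0 and seq[a2] == revcomp(ref[r - 1]):
                a2 += 1
                r -= 1
            blocks.append((a, r, a2 - a, "-"))
            i = a2
    return blocks


def reference_coverage(assembly: list[str], reference, min_block: int = 100,
                       max_insert: int = 10_000) -> AlignmentReport:
    """Fraction of reference positions covered by aligned blocks >= min_block,
    plus the junction-level structural error count.

    ``reference`` may be a sequence string or an object with ``haplotypes``
    (haplotype 0 is used).
    """
    ref = reference if isinstance(reference, str) else reference.haplotypes[0]
    idx = _ref_index(ref)
    covered = bytearray(len(ref))
    all_blocks = []
    n_errors = 0
    for si, seq in enumerate(assembly):
        blocks = [b for b in _align_blocks(seq, ref, idx) if b[2] >= min_block]
        for a, r, ln, strand in blocks:
            covered[r : r + ln] = b"\x01" * ln
            all_blocks.append((si, a, r, ln, strand))
        n_errors += _junction_errors(blocks, max_insert)
    cov = sum(covered) / len(ref) if ref else 0.0
    return AlignmentReport(reference_coverage=cov, structural_errors=n_errors,
                           blocks=all_blocks)


def _junction_errors(blocks, max_insert: int) -> int:
    """Count non-collinear / distant junctions between consecutive blocks."""
    n = 0
    for (a1, r1, l1, s1), (a2, r2, l2, s2) in zip(blocks, blocks[1:]):
        if s1 != s2:
            n += 1
            continue
        asm_gap = a2 - (a1 + l1)
        if s1 == "+":
            ref_gap = r2 - (r1 + l1)
        else:
            ref_gap = r1 - (r2 + l2)
        if abs(ref_gap - asm_gap) > 2 * max_insert:
            n += 1
    return n


def count_structural_errors(assembly: list[str], reference,
                            min_block: int = 100,
                            max_insert: int = 10_000) -> int:
    """Junction-level structural error count (see :func:`reference_coverage`)."""
    return reference_coverage(assembly, reference, min_block,
                              max_insert).structural_errors
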