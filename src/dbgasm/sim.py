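"""Truth-known synthetic data: genomes with planted repeats, diploid
heterozygosity, and multi-library paired-end reads with substitution errors.

Every generator is driven by an explicit integer seed and is byte-for-byte
reproducible.  The error model is substitution-only (no indels), matching
the Illumina-style profile the corrector targets.  Insert sizes follow a
normal distribution truncated to [2*read_len, 2*avg_ins]; the first four
fragments of every library are pinned at the two ends of the sequence (two
per end) so that terminal bases are covered at multiplicity >= 2 and
exact-reconstruction tests are well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_config import Library, Read
from .kmer import revcomp

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass
class GenomeTruth:
    """A simulated genome plus everything a test oracle needs to know about it."""

    haplotypes: list[str]
    repeat_annotations: list[tuple[int, int, int]] = field(default_factory=list)
    variant_positions: list[tuple[int, str, str]] = field(default_factory=list)
    seed: int = 0

    @property
    def ploidy(self) -> int:
        return len(self.haplotypes)

    @property
    def length(self) -> int:
        return len(self.haplotypes[0])


@dataclass
class ReadTruth:
    """Provenance of one simulated read: where it came from and what was broken."""

    read_id: str
    haplotype: int
    true_start: int
    strand: str  # '+'/'-' relative to the haplotype
    planted_errors: list[tuple[int, str, str]] = field(default_factory=list)

    def true_seq(self, genome: GenomeTruth, read_len: int) -> str:
        """The error-free read sequence, reconstructed from the genome."""
        hap = genome.haplotypes[self.haplotype]
        sub = hap[self.true_start : self.true_start + read_len]
        return sub if self.strand == "+" else revcomp(sub)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def simulate_genome(length: int, gc: float = 0.5,
                    repeats: list[tuple[int, int]] | None = None,
                    seed: int = 0) -> GenomeTruth:
    """i.i.d. background sequence with exact repeat families planted on top.

    ``repeats`` is a list of (copy_len, n_copies); each family's sequence is
    generated once and pasted at uniformly chosen non-overlapping positions.
    Annotations record (start, end, family_index).  Raises ``ValueError``
    if the repeats cannot be placed without overlap after bounded retries.
    """
    repeats = repeats or []
    total_rep = sum(clen * n for clen, n in repeats)
    if total_rep >= length / 2:
        raise ValueError("total repeat length must be < length/2")
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, length, gc))
    placed: list[tuple[int, int]] = []  # occupied intervals
    annotations: list[tuple[int, int, int]] = []
    for fam_idx, (copy_len, n_copies) in enumerate(repeats):
        unit = _random_seq(rng, copy_len, gc)
        for _ in range(n_copies):
            for _attempt in range(1000):
                start = int(rng.integers(0, length - copy_len + 1))
                if all(start + copy_len <= s or start >= e for s, e in placed):
                    break
            else:
                raise ValueError("could not place repeats without overlap")
            seq[start : start + copy_len] = unit
            placed.append((start, start + copy_len))
            annotations.append((start, start + copy_len, fam_idx))
    annotations.sort()
    return GenomeTruth(haplotypes=["".join(seq)],
                       repeat_annotations=annotations, seed=seed)


def make_diploid(genome: GenomeTruth, het_rate: float, seed: int = 0) -> GenomeTruth:
    """Add a second haplotype: a copy with i.i.d. substitutions at ``het_rate``.

    With ``het_region=(start, end)`` use :func:`make_diploid_region` instead
    to restrict divergence to an interval.
    """
    return make_diploid_region(genome, het_rate, 0, genome.length, seed)


def make_diploid_region(genome: GenomeTruth, het_rate: float,
                        start: int, end: int, seed: int = 0) -> GenomeTruth:
    """Diploid genome whose divergence is confined to [start, end)."""
    if genome.ploidy != 1:
        raise ValueError("input genome must be haploid")
    rng = np.random.default_rng(seed)
    hap0 = genome.haplotypes[0]
    hap1 = list(hap0)
    variants: list[tuple[int, str, str]] = []
    if het_rate > 0:
        hits = np.nonzero(rng.random(end - start) < het_rate)[0]
        for off in hits:
            pos = start + int(off)
            ref = hap0[pos]
            alt = _OTHER[ref][int(rng.integers(0, 3))]
            hap1[pos] = alt
            variants.append((pos, ref, alt))
    return GenomeTruth(haplotypes=[hap0, "".join(hap1)],
                       repeat_annotations=list(genome.repeat_annotations),
                       variant_positions=variants, seed=seed)


def _plant_errors(rng: np.random.Generator, seq: str,
                  error_rate: float) -> tuple[str, list[tuple[int, str, str]]]:
    if error_rate <= 0:
        return seq, []
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if len(hits) == 0:
        return seq, []
    out = list(seq)
    errors = []
    for pos in hits:
        pos = int(pos)
        true = seq[pos]
        if true not in _BASES:
            continue
        obs = _OTHER[true][int(rng.integers(0, 3))]
        out[pos] = obs
        errors.append((pos, true, obs))
    return "".join(out), errors


def simulate_pe_library(genome: GenomeTruth, library: Library, read_len: int = 100,
                        coverage: float = 40.0, error_rate: float = 0.0,
                        seed: int = 0) -> tuple[list[Read], list[Read], list[ReadTruth]]:
    """Simulate one paired-end library at the given fold coverage.

    Pair count = round(coverage * genome_length / (2 * read_len)).  Fragment
    lengths are Normal(avg_ins, ins_sd) truncated to [2*read_len, 2*avg_ins];
    orientation is FR (innie) unless the library says RF (outie mate-pair).
    Diploid genomes are sampled from both haplotypes equally, so ``coverage``
    is the combined depth.  Returns (reads1, reads2, truths); read i of file 1
    pairs with read i of file 2, ids ``<lib>_<i>/1`` and ``<lib>_<i>/2``.
    """
    rng = np.random.default_rng(seed)
    L = genome.length
    ins, sd = library.avg_ins, library.ins_sd
    if ins >= L:
        raise ValueError("insert size exceeds genome length")
    lo, hi = 2 * read_len, 2 * ins
    n_pairs = int(round(coverage * L / (2 * read_len)))
    reads1: list[Read] = []
    reads2: list[Read] = []
    truths: list[ReadTruth] = []
    for i in range(n_pairs):
        frag = int(round(rng.normal(ins, sd))) if sd > 0 else ins
        frag = min(max(frag, lo), min(hi, L))
        if i < 2:
            start = 0  # pinned terminal fragments: deterministic end coverage
        elif i < 4:
            start = L - frag
        else:
            start = int(rng.integers(0, L - frag + 1))
        hap = int(rng.integers(0, genome.ploidy))
        hseq = genome.haplotypes[hap]
        left = hseq[start : start + read_len]
        right = revcomp(hseq[start + frag - read_len : start + frag])
        if library.orientation == "RF":
            left, right = revcomp(left), revcomp(right)
        strand1, strand2 = ("+", "-") if library.orientation == "FR" else ("-", "+")
        obs1, err1 = _plant_errors(rng, left, error_rate)
        obs2, err2 = _plant_errors(rng, right, error_rate)
        base = f"{library.name}_{i}"
        reads1.append(Read(id=f"{base}/1", seq=obs1, mate_id=f"{base}/2", library=library))
        reads2.append(Read(id=f"{base}/2", seq=obs2, mate_id=f"{base}/1", library=library))
        truths.append(ReadTruth(read_id=f"{base}/1", haplotype=hap, true_start=start,
                                strand=strand1, planted_errors=err1))
        truths.append(ReadTruth(read_id=f"{base}/2", haplotype=hap,
                                true_start=start + frag - read_len,
                                strand=strand2, planted_errors=err2))
    return reads1, reads2, truths


def tiling_reads(genome: GenomeTruth, read_len: int, step: int,
                 library: Library | None = None) -> list[Read]:
    """Deterministic error-free single-end reads tiling each haplotype.

    A convenience for graph unit tests; every position is covered and the
    last window is pinned to the sequence end.
    """
    out: list[Read] = []
    for h, hap in enumerate(genome.haplotypes):
        starts = list(range(0, max(len(hap) - read_len, 0) + 1, step))
        if starts[-1] != len(hap) - read_len:
            starts.append(len(hap) - read_len)
        for i, s in enumerate(starts):
            out.append(Read(id=f"tile_h{h}_{i}", seq=hap[s : s + read_len],
                            library=library))
    return out
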