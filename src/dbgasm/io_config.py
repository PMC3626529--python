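"""Sequence I/O and the classic assembler library-configuration dialect.

The config format is the key=value / ``[LIB]`` block dialect popularised by
SOAPdenovo, so published configuration packages keep working::

    max_rd_len=100
    [LIB]
    avg_ins=180
    reverse_seq=0
    asm_flags=3
    rank=1
    q1=lib180_1.fq
    q2=lib180_2.fq

``reverse_seq=0`` means forward-reverse (FR, short-insert paired-end);
``reverse_seq=1`` means reverse-forward (RF, long-insert mate-pair).
Unknown keys are ignored with a warning.  All coordinates in this package
are 0-based, half-open, on the plus strand of the stored sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Malformed library configuration."""


class FormatError(ValueError):
    """Malformed sequence file."""


@dataclass
class Library:
    """One paired-end library: insert-size model, orientation and scaffolding rank."""

    name: str
    avg_ins: int
    ins_sd: int = 0
    orientation: str = "FR"  # FR short-insert, RF mate-pair
    rank: int = 1
    read_files: list[str] = field(default_factory=list)
    max_read_len: int = 150
    asm_flags: int = 3

    def __post_init__(self) -> None:
        if self.avg_ins <= 0:
            raise ConfigError(f"library {self.name}: avg_ins must be > 0")
        if self.rank < 1:
            raise ConfigError(f"library {self.name}: rank must be >= 1")
        if self.orientation not in ("FR", "RF"):
            raise ConfigError(f"library {self.name}: orientation must be FR or RF")
        if self.ins_sd == 0:
            # classic rule of thumb: ~10% of the insert size
            self.ins_sd = max(1, self.avg_ins // 10)


@dataclass
class Read:
    """A sequencing read with optional quality and library provenance."""

    id: str
    seq: str
    qual: str | None = None
    mate_id: str | None = None
    library: Library | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(f"read {self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.seq)


# keys understood in a [LIB] block; everything else warns
_LIB_KEYS = {"avg_ins", "ins_sd", "reverse_seq", "asm_flags", "rank", "rd_len_cutoff",
             "q1", "q2", "q", "f1", "f2", "f", "p", "name"}
_INT_KEYS = {"max_rd_len", "avg_ins", "ins_sd", "reverse_seq", "asm_flags", "rank",
             "rd_len_cutoff"}


def parse_library_config(path) -> list[Library]:
    """Parse a library configuration file into Library records.

    Returns libraries sorted by (rank, avg_ins) ascending — the order in which
    scaffolding consumes them.  A ``[LIB]`` block without ``avg_ins`` is a
    :class:`ConfigError`, as is any non-integer numeric field.
    """
    path = Path(path)
    text = path.read_text()
    max_rd_len = 150
    libs: list[dict] = []
    cur: dict | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.upper() == "[LIB]":
            cur = {"read_files": [], "lineno": lineno}
            libs.append(cur)
            continue
        if "=" not in line:
            log.warning("%s:%d: ignoring malformed line %r", path, lineno, raw)
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key in _INT_KEYS:
            try:
                ival = int(val)
            except ValueError:
                raise ConfigError(f"{path}:{lineno}: {key} must be an integer, got {val!r}")
        if cur is None:
            if key == "max_rd_len":
                max_rd_len = ival
            else:
                log.warning("%s:%d: ignoring key %r outside [LIB]", path, lineno, key)
            continue
        if key not in _LIB_KEYS:
            log.warning("%s:%d: ignoring unknown key %r", path, lineno, key)
            continue
        if key in ("q1", "q2", "f1", "f2", "q", "f", "p"):
            cur["read_files"].append(val)
        elif key in _INT_KEYS:
            cur[key] = ival
        else:
            cur[key] = val

    out: list[Library] = []
    for i, d in enumerate(libs):
        if "avg_ins" not in d:
            raise ConfigError(f"{path}: [LIB] block at line {d['lineno']} missing avg_ins")
        out.append(Library(
            name=d.get("name", f"lib{i + 1}"),
            avg_ins=d["avg_ins"],
            ins_sd=d.get("ins_sd", 0),
            orientation="RF" if d.get("reverse_seq", 0) else "FR",
            rank=d.get("rank", 1),
            read_files=d["read_files"],
            max_read_len=d.get("rd_len_cutoff", max_rd_len),
            asm_flags=d.get("asm_flags", 3),
        ))
    out.sort(key=lambda lib: (lib.rank, lib.avg_ins))
    return out


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                c = line[0]
                break
        else:
            return "fasta"  # empty file: arbitrary but harmless
    if c == ">":
        return "fasta"
    if c == "@":
        return "fastq"
    raise FormatError(f"{path}: cannot auto-detect format (starts with {c!r})")


def read_sequences(path, format: str = "auto",
                   library: Library | None = None) -> Iterator[Read]:
    """Stream reads from a FASTA/FASTQ file in file order.

    Lowercase bases are uppercased; characters outside {A,C,G,T,N} are mapped
    to N (total count logged).  A truncated FASTQ record raises
    :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    n_mapped = 0
    try:
        for rec in SeqIO.parse(str(path), format):
            seq = str(rec.seq).upper()
            cleaned = []
            for c in seq:
                if c in "ACGTN":
                    cleaned.append(c)
                else:
                    cleaned.append("N")
                    n_mapped += 1
            qual = None
            if "phred_quality" in rec.letter_annotations:
                qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield Read(id=rec.id, seq="".join(cleaned), qual=qual, library=library)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    finally:
        if n_mapped:
            log.warning("%s: mapped %d non-ACGTN characters to N", path, n_mapped)


def write_assembly(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    """Write (id, sequence) records as 80-column wrapped FASTA.

    Duplicate ids raise ``ValueError`` before anything is written; an empty
    record list produces an empty file.  Round-trips losslessly through
    :func:`read_sequences`.
    """
    records = list(records)
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate record id {dup!r}")
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[Read], path) -> None:
    """Write reads as Sanger FASTQ (constant 'I' quality when absent)."""
    with open(path, "w") as fh:
        for r in reads:
            q = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{q}\n")
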