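"""Sequence I/O, configuration and shared error types.

FASTA/FASTQ readers are hand-rolled (rather than delegated to a library)
because the error contract requires parse failures to name the offending
line number; both formats are read transparently from gzip-compressed
files.  Results are always written to files or standard output; logging
goes to standard error.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger("tandemasm.io")

_BAD_CHAR = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed sequence record; carries the file path and line number."""

    def __init__(self, path, line: int, message: str):
        self.path = str(path)
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


class ParameterError(ValueError):
    """Invalid parameter value for a model or graph operation."""


@dataclass
class Read:
    """A single sequencing read.

    ``quality``, if present, must have the same length as ``sequence``;
    ``mate_id`` optionally links the read to its pair.
    """

    id: str
    sequence: str
    quality: str | None = None
    mate_id: str | None = None

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyConfig:
    """Knobs for the assembly pipeline.

    ``k`` is the de Bruijn graph dimension; it must satisfy
    1 < k < (minimum read length), which is checked against the actual
    read set when assembly starts.  ``genome_size_override`` replaces the
    distinct-k-mer genome size estimate when given.  ``confidence_q`` is
    the confidence level used by the required-coverage planner.
    """

    k: int = 55
    low_weight_cutoff: int | None = None  # None -> automatic, from coverage
    tip_length_factor: int = 2  # max tip length = factor * k edges
    genome_size_override: int | None = None
    confidence_q: float = 0.95
    single_strand_mode: bool = False
    random_seed: int = 0
    normalize: bool = True
    resolve_repeats: bool = True
    weight_ratio: float = 0.2  # tip-vs-branch weight ratio
    min_contig_length: int = 0  # report filter only, never trims output

    def __post_init__(self):
        if self.k <= 1:
            raise ParameterError(f"k must be > 1, got {self.k}")
        if not 0.0 <= self.confidence_q <= 1.0:
            raise ParameterError(
                f"confidence_q must be in [0, 1], got {self.confidence_q}")
        if self.genome_size_override is not None and self.genome_size_override <= 0:
            raise ParameterError("genome_size_override must be positive")
        if self.low_weight_cutoff is not None and self.low_weight_cutoff < 0:
            raise ParameterError("low_weight_cutoff must be >= 0")


def _open_text(path) -> io.TextIOWrapper:
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh), encoding="ascii")
    return io.TextIOWrapper(fh, encoding="ascii")


def _clean_seq(raw: str, path, line: int) -> str:
    seq = raw.upper()
    m = _BAD_CHAR.search(seq)
    if m:
        raise ParseError(path, line, f"invalid sequence character {m.group()!r}")
    return seq


def _read_fasta(fh, path) -> list[Read]:
    reads: list[Read] = []
    header: str | None = None
    header_line = 0
    parts: list[str] = []

    def flush():
        if header is None:
            return
        if not parts:
            raise ParseError(path, header_line, f"record {header!r} has no sequence")
        reads.append(Read(id=header, sequence="".join(parts)))

    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if len(line) > 1 else ""
            if not header:
                raise ParseError(path, lineno, "empty FASTA header")
            header_line = lineno
            parts = []
        else:
            if header is None:
                raise ParseError(path, lineno, "sequence data before first '>' header")
            parts.append(_clean_seq(line, path, lineno))
    flush()
    return reads


def _read_fastq(fh, path) -> list[Read]:
    reads: list[Read] = []
    lineno = 0
    while True:
        block = []
        for _ in range(4):
            raw = fh.readline()
            lineno += 1
            if not raw:
                break
            block.append(raw.rstrip("\n"))
        if not block or (len(block) == 1 and not block[0].strip()):
            break
        if len(block) < 4:
            raise ParseError(path, lineno, "truncated FASTQ record")
        head, seq_raw, plus, qual = block
        first = lineno - 3
        if not head.startswith("@"):
            raise ParseError(path, first, "FASTQ header must start with '@'")
        if not plus.startswith("+"):
            raise ParseError(path, first + 2, "FASTQ separator must start with '+'")
        seq = _clean_seq(seq_raw.strip(), path, first + 1)
        if len(qual) != len(seq):
            raise ParseError(
                path, first + 3,
                f"quality length {len(qual)} != sequence length {len(seq)}")
        rid = head[1:].split()[0] if len(head) > 1 else ""
        if not rid:
            raise ParseError(path, first, "empty FASTQ read id")
        reads.append(Read(id=rid, sequence=seq, quality=qual))
    return reads


def read_sequences(path, format: str = "auto") -> list[Read]:
    """Read all records from a FASTA/FASTQ file (optionally gzipped).

    Records are returned in file order; lowercase bases are uppercased;
    characters outside {A,C,G,T,N} raise :class:`ParseError` naming the
    line.  An empty file yields an empty list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("fasta", "fastq", "auto"):
        raise ParameterError(f"unknown format {format!r}")
    with _open_text(path) as fh:
        if format == "auto":
            pos = fh.tell()
            first = ""
            for line in fh:
                if line.strip():
                    first = line.strip()[0]
                    break
            fh.seek(pos)
            if first == "":
                return []
            format = "fasta" if first == ">" else "fastq"
        if format == "fasta":
            return _read_fasta(fh, path)
        return _read_fastq(fh, path)


def _wrap(seq: str, width: int = 80) -> Iterator[str]:
    for i in range(0, len(seq), width):
        yield seq[i:i + width]


def write_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as 80-column-wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for chunk in _wrap(seq):
                fh.write(chunk + "\n")


def write_contigs(contigs: Iterable[str], path) -> None:
    """Write contigs as FASTA with ids ``contig_<index>_len_<length>``."""
    if contigs is None:
        raise ValueError("contigs must not be None")
    write_fasta(
        ((f"contig_{i}_len_{len(seq)}", seq) for i, seq in enumerate(contigs, 1)),
        path,
    )


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


_TRUE = {"1", "true", "yes", "on"}
_FALSE = {"0", "false", "no", "off"}


def _parse_value(text: str):
    t = text.strip()
    low = t.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    for cast in (int, float):
        try:
            return cast(t)
        except ValueError:
            pass
    return t


def load_config(path) -> dict:
    """Parse a ``key = value`` config file mirroring the CLI flags."""
    values: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(path, lineno, "expected 'key = value'")
            key, _, val = line.partition("=")
            values[key.strip().replace("-", "_")] = _parse_value(val)
    return values


def setup_logging(verbose: bool = True) -> None:
    """Route all pipeline logging to stderr with timestamps."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%d %H:%M:%S",
    )
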