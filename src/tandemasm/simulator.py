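"""Reference and paired-end read simulation.

References are built as alternating random spacers and tandem arrays
(optionally with explicit motifs); reads are drawn as paired 100-bp-style
fragments with normally distributed insert sizes, uniform substitution
errors and an optional low-rate indel process.  Everything is
deterministic under the seed, so all downstream experiments are
reproducible without external data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ParameterError, Read, revcomp

logger = logging.getLogger("tandemasm.sim")

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACGT"}


@dataclass
class RepeatSpec:
    """Declarative description of one tandem array."""

    motif_length: int
    repeat_count: int
    motif: str | None = None

    def __post_init__(self):
        if self.motif_length < 1:
            raise ParameterError("motif_length must be >= 1")
        if self.repeat_count < 2:
            raise ParameterError("repeat_count must be >= 2")
        if self.motif is not None and len(self.motif) != self.motif_length:
            raise ParameterError(
                f"explicit motif length {len(self.motif)} != motif_length "
                f"{self.motif_length}")

    @property
    def array_length(self) -> int:
        return self.motif_length * self.repeat_count


@dataclass
class SimulatedReference:
    """Generated reference plus ground truth.

    ``truth`` holds (0-based array start, RepeatSpec-with-motif) pairs;
    the substring at each start equals the motif repeated repeat_count
    times.
    """

    sequence: str
    truth: list[tuple[int, RepeatSpec]]
    circular: bool = False
    seed: int = 0

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSimParams:
    read_length: int = 100
    coverage: float = 100.0
    insert_mean: float = 250.0
    insert_std: float = 25.0
    substitution_rate: float = 0.01
    simulate_indels: bool = False
    indel_rate: float = 1e-4
    seed: int = 0
    forward_only: bool = False

    def __post_init__(self):
        if self.insert_mean < self.read_length:
            raise ParameterError("insert_mean must be >= read_length")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ParameterError("substitution_rate must be in [0, 1]")
        if self.coverage <= 0:
            raise ParameterError("coverage must be positive")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return bytes(_BASE_BYTES[rng.integers(0, 4, size=n)]).decode("ascii")


def default_reference_specs() -> list[RepeatSpec]:
    """The 20-array benchmark design: motifs of 100..500 bp, each
    repeated 2..5 times, ordered by motif length then count."""
    return [RepeatSpec(d, m)
            for d in (100, 200, 300, 400, 500) for m in (2, 3, 4, 5)]


def make_reference(specs: Sequence[RepeatSpec],
                   spacer_length: int | Sequence[int] = 1000,
                   circular: bool = False, seed: int = 0) -> SimulatedReference:
    """Build spacer + array_1 + spacer + ... + array_n + spacer.

    Spacers are i.i.d. uniform over {A,C,G,T}; motifs are random unless
    given explicitly.  ``spacer_length`` may be a single length or one
    length per gap (len(specs) + 1 values).
    """
    if not specs:
        raise ParameterError("at least one RepeatSpec is required")
    if isinstance(spacer_length, int):
        spacers = [spacer_length] * (len(specs) + 1)
    else:
        spacers = list(spacer_length)
        if len(spacers) != len(specs) + 1:
            raise ParameterError(
                f"need {len(specs) + 1} spacer lengths, got {len(spacers)}")
    if any(s < 0 for s in spacers):
        raise ParameterError("spacer lengths must be >= 0")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    truth: list[tuple[int, RepeatSpec]] = []
    pos = 0
    for spec, gap in zip(specs, spacers):
        spacer = _random_dna(rng, gap)
        parts.append(spacer)
        pos += len(spacer)
        motif = spec.motif if spec.motif is not None else _random_dna(
            rng, spec.motif_length)
        filled = RepeatSpec(spec.motif_length, spec.repeat_count, motif)
        array = motif * spec.repeat_count
        parts.append(array)
        truth.append((pos, filled))
        pos += len(array)
    parts.append(_random_dna(rng, spacers[-1]))
    return SimulatedReference("".join(parts), truth, circular, seed)


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float,
            indel_rate: float) -> str:
    if sub_rate > 0:
        n_sub = rng.binomial(len(seq), sub_rate)
        if n_sub:
            chars = list(seq)
            for p in rng.choice(len(chars), size=n_sub, replace=False):
                alts = _OTHER[chars[p]]
                chars[p] = alts[rng.integers(len(alts))]
            seq = "".join(chars)
    if indel_rate > 0:
        n_ind = rng.binomial(len(seq), indel_rate)
        if n_ind:
            chars = list(seq)
            pos = rng.choice(len(chars), size=min(n_ind, len(chars)),
                             replace=False)
            for p in sorted(pos, reverse=True):
                if rng.random() < 0.5:
                    del chars[p]
                else:
                    chars.insert(p, _BASES[rng.integers(4)])
            seq = "".join(chars)
    return seq


def simulate_reads(reference: SimulatedReference,
                   params: ReadSimParams) -> tuple[list[Read], list[Read]]:
    """Simulate ceil(coverage * G / (2L)) read pairs.

    Fragment starts are uniform over the genome (wrapping when
    circular); fragment lengths are Normal(insert_mean, insert_std)
    rounded and truncated to at least 2L-1.  Mate 1 is the fragment's
    5' end, mate 2 the reverse complement of its 3' end (unless
    ``forward_only``).  Deterministic under the seed.
    """
    seq = reference.sequence
    G = len(seq)
    L = params.read_length
    if G <= params.insert_mean:
        raise ParameterError(
            f"reference length {G} must exceed insert_mean {params.insert_mean}")
    n_pairs = math.ceil(params.coverage * G / (2 * L))
    rng = np.random.default_rng(params.seed)
    flens = np.rint(rng.normal(params.insert_mean, params.insert_std,
                               size=n_pairs)).astype(np.int64)
    flens = np.clip(flens, 2 * L - 1, G)
    if reference.circular:
        starts = rng.integers(0, G, size=n_pairs)
        doubled = seq + seq
    else:
        starts = rng.integers(0, G - flens + 1)
        doubled = seq
    reads1: list[Read] = []
    reads2: list[Read] = []
    for i in range(n_pairs):
        s = int(starts[i])
        f = int(flens[i])
        frag = doubled[s:s + f]
        r1 = frag[:L]
        r2 = frag[-L:]
        if not params.forward_only:
            r2 = revcomp(r2)
        indel = params.indel_rate if params.simulate_indels else 0.0
        r1 = _mutate(rng, r1, params.substitution_rate, indel)
        r2 = _mutate(rng, r2, params.substitution_rate, indel)
        reads1.append(Read(f"sim_{i}/1", r1, "I" * len(r1), mate_id=f"sim_{i}/2"))
        reads2.append(Read(f"sim_{i}/2", r2, "I" * len(r2), mate_id=f"sim_{i}/1"))
    return reads1, reads2


def write_truth(reference: SimulatedReference, path) -> None:
    """TSV ground truth: start, end (0-based half-open), motif, count."""
    with open(path, "w") as fh:
        fh.write("start\tend\tmotif\tcount\n")
        for start, spec in reference.truth:
            fh.write(f"{start}\t{start + spec.array_length}\t"
                     f"{spec.motif}\t{spec.repeat_count}\n")


def load_truth(path) -> list[tuple[int, RepeatSpec]]:
    truth = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            start, _end, motif, count = line.rstrip("\n").split("\t")
            truth.append(
                (int(start), RepeatSpec(len(motif), int(count), motif)))
    return truth
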