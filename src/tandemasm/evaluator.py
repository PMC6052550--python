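"""Tandem-array detection in contigs and assembly scoring.

Counting is exact-match only: the repetition count of a motif in a
contig is the length of the longest maximal tandem run of any cyclic
rotation of the motif, divided by the motif length (so partial trailing
copies give fractional counts).  Rotations are considered because an
assembly may enter an array at any phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .contig_builder import AssemblyResult
from .io_formats import ParameterError, revcomp
from .simulator import RepeatSpec, SimulatedReference

logger = logging.getLogger("tandemasm.eval")


@dataclass
class TandemArrayCall:
    """One detected tandem array inside a sequence."""

    contig_id: str
    start: int
    motif: str
    repeat_count: float
    array_length: int


def _run_bounds(seq: str, i: int, d: int) -> tuple[int, int]:
    """Maximal d-periodic run containing the match at [i, i+d)."""
    a = i
    while a > 0 and seq[a - 1] == seq[a - 1 + d]:
        a -= 1
    b = i + d
    n = len(seq)
    while b < n and seq[b] == seq[b - d]:
        b += 1
    return a, b


def _run_to_count(run_length: int, d: int) -> float:
    """Repetition count of a maximal d-periodic run.

    Whole copies plus the fractional tail; tails shorter than half a
    motif are attributed to chance extension into flanking sequence and
    dropped (a single flank base matching the period would otherwise
    turn an exact m-copy array into m + 1/d).  This is the reading under
    which counting is rotation-invariant while exact arrays score whole
    numbers.
    """
    full, tail = divmod(run_length, d)
    if 2 * tail < d:
        tail = 0
    return full + tail / d


def count_motif_repeats(contig: str, motif: str) -> float:
    """Maximum over all rotations and positions of the repetition count
    of the maximal tandem run; 0 when the motif is absent."""
    if not motif:
        raise ParameterError("motif must be non-empty")
    d = len(motif)
    best = 0.0
    for r in range(d):
        rot = motif[r:] + motif[:r]
        i = contig.find(rot)
        while i != -1:
            a, b = _run_bounds(contig, i, d)
            best = max(best, _run_to_count(b - a, d))
            i = contig.find(rot, max(i + 1, b - d + 1))
    return best


def find_tandem_arrays(sequence: str, min_motif: int, max_motif: int,
                       min_repeats: float = 2.0,
                       contig_id: str = "") -> list[TandemArrayCall]:
    """Exact maximal tandem arrays with motif length in
    [min_motif, max_motif] and repeat count >= min_repeats.  Overlapping
    calls are reduced to the longest array, ties to the smallest motif.
    """
    if not 1 <= min_motif <= max_motif:
        raise ParameterError("need 1 <= min_motif <= max_motif")
    n = len(sequence)
    calls: list[TandemArrayCall] = []
    seen: set[tuple[int, int]] = set()
    for d in range(min_motif, max_motif + 1):
        i = 0
        while i + 2 * d <= n:
            if sequence[i] == sequence[i + d] and \
                    sequence[i:i + d] == sequence[i + d:i + 2 * d]:
                a, b = _run_bounds(sequence, i, d)
                if (a, d) not in seen:
                    seen.add((a, d))
                    full, tail = divmod(b - a, d)
                    if 2 * tail < d:
                        tail = 0
                    count = full + tail / d
                    if count >= min_repeats:
                        calls.append(TandemArrayCall(
                            contig_id, a, sequence[a:a + d], count,
                            full * d + tail))
                i = b - d + 1
            else:
                i += 1
    calls.sort(key=lambda c: (-c.array_length, len(c.motif), c.start))
    kept: list[TandemArrayCall] = []
    taken: list[tuple[int, int]] = []
    for c in calls:
        span = (c.start, c.start + c.array_length)
        if any(span[0] < e and s < span[1] for s, e in taken):
            continue
        taken.append(span)
        kept.append(c)
    kept.sort(key=lambda c: c.start)
    return kept


@dataclass
class RepeatScore:
    """Per-truth-array recovery record."""

    start: int
    motif: str
    expected: int
    recovered: float
    contig_index: int  # -1 when the motif is absent from every contig


@dataclass
class AssemblyScore:
    rows: list[RepeatScore]
    n_contigs: int
    n50: int
    longest: int

    @property
    def n_correct(self) -> int:
        return sum(1 for r in self.rows if round(r.recovered, 1) == r.expected)


def score_assembly(result: AssemblyResult,
                   truth: SimulatedReference | Sequence[tuple[int, RepeatSpec]],
                   ) -> AssemblyScore:
    """Score each truth array by the repeat count recovered in the
    best-matching contig (0 when the motif is absent); the motif's
    reverse complement is also considered since assembly orientation is
    arbitrary."""
    entries = truth.truth if isinstance(truth, SimulatedReference) else list(truth)
    rows = []
    for start, spec in entries:
        if spec.motif is None:
            raise ParameterError("truth entries must carry explicit motifs")
        best = 0.0
        best_i = -1
        rc = revcomp(spec.motif)
        for i, contig in enumerate(result.contigs):
            got = max(count_motif_repeats(contig, spec.motif),
                      count_motif_repeats(contig, rc))
            if got > best:
                best, best_i = got, i
        rows.append(RepeatScore(start, spec.motif, spec.repeat_count,
                                best, best_i))
    return AssemblyScore(rows, result.n_contigs, result.n50, result.longest)


def write_score_report(score: AssemblyScore, path) -> None:
    """TSV: one row per truth array (expected vs recovered) + summary."""
    with open(path, "w") as fh:
        fh.write("start\tmotif_length\texpected\trecovered\tcontig\n")
        for r in score.rows:
            fh.write(f"{r.start}\t{len(r.motif)}\t{r.expected}\t"
                     f"{round(r.recovered, 1)}\t{r.contig_index}\n")
        fh.write(f"# correct {score.n_correct}/{len(score.rows)}; "
                 f"contigs={score.n_contigs} n50={score.n50} "
                 f"longest={score.longest}\n")
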