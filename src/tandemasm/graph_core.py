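"""Weighted de Bruijn graph construction and error cleaning.

Vertices are (k-1)-mers and every distinct observed k-mer becomes one
directed edge whose integer weight is the k-mer's occurrence count in the
read set.  Cleaning removes the three classes of sequencing-error
artifact: low-weight edges, tips (short dead ends branching off a heavier
path) and bubbles (parallel paths between the same vertex pair).
Cleaning never creates edges, so the edge count is non-increasing across
all ``remove_*`` operations.
"""

from __future__ import annotations

import logging
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .io_formats import ParameterError, Read, revcomp

logger = logging.getLogger("tandemasm.graph")


class GraphError(ValueError):
    pass


# ---------------------------------------------------------------------------
# k-mer counting


def extract_kmers(read: str, k: int) -> list[str]:
    """Return the L-k+1 overlapping k-length words of ``read``, in order.

    Empty when the read is shorter than k.  ``k`` must be at least 2.
    """
    if k < 2:
        raise ParameterError(f"k must be >= 2, got {k}")
    n = len(read) - k + 1
    if n <= 0:
        return []
    return [read[i:i + k] for i in range(n)]


@dataclass
class KmerCountTable:
    """Occurrence counts of fixed-length DNA words.

    Invariant: every key has length exactly ``k`` and every count is >= 1.
    In single-strand mode the counts over all keys sum to
    sum over reads of max(0, length - k + 1).
    """

    k: int
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    def filter_min_count(self, cutoff: int) -> "KmerCountTable":
        """New table keeping only k-mers with count >= cutoff."""
        return KmerCountTable(
            self.k, {w: c for w, c in self.counts.items() if c >= cutoff})


def _add_kmers(counter: Counter, seq: str, k: int) -> None:
    # Reads containing N are split at N positions; fragments shorter than
    # k contribute nothing.
    for frag in seq.split("N") if "N" in seq else (seq,):
        n = len(frag) - k + 1
        if n > 0:
            counter.update([frag[i:i + k] for i in range(n)])


def count_kmers(reads: Iterable[Read | str], k: int,
                single_strand: bool = True) -> KmerCountTable:
    """Aggregate k-mer counts over a read set.

    When ``single_strand`` is false each read contributes the k-mers of
    both its sequence and its reverse complement.
    """
    counter: Counter = Counter()
    n_reads = 0
    for r in reads:
        seq = r.sequence if isinstance(r, Read) else r
        n_reads += 1
        _add_kmers(counter, seq, k)
        if not single_strand:
            _add_kmers(counter, revcomp(seq), k)
    if n_reads == 0:
        raise GraphError("no input reads")
    if not counter:
        raise GraphError(
            f"no k-mers extracted: all {n_reads} reads are shorter than k={k}")
    return KmerCountTable(k, dict(counter))


# ---------------------------------------------------------------------------
# graph


class DeBruijnGraph:
    """Directed graph over (k-1)-mer vertices with integer edge weights.

    For every edge (u, v) the last k-2 characters of u equal the first
    k-2 characters of v and the edge's k-mer is ``u + v[-1]``.  Weights
    are non-negative; weight-0 edges exist only transiently during
    contig traversal.
    """

    __slots__ = ("k", "_out", "_in")

    def __init__(self, k: int):
        if k < 2:
            raise ParameterError(f"k must be >= 2, got {k}")
        self.k = k
        self._out: dict[str, dict[str, int]] = {}
        self._in: dict[str, dict[str, int]] = {}

    # -- vertices ----------------------------------------------------------
    def add_vertex(self, v: str) -> None:
        if v not in self._out:
            self._out[v] = {}
            self._in[v] = {}

    def __contains__(self, v: str) -> bool:
        return v in self._out

    def vertices(self) -> Iterator[str]:
        return iter(self._out)

    @property
    def n_vertices(self) -> int:
        return len(self._out)

    # -- edges -------------------------------------------------------------
    def add_edge(self, u: str, v: str, weight: int = 1) -> None:
        if len(u) != self.k - 1 or len(v) != self.k - 1:
            raise GraphError(f"vertex labels must have length {self.k - 1}")
        if u[1:] != v[:-1]:
            raise GraphError(f"edge ({u}, {v}) violates the (k-2)-overlap rule")
        self.add_vertex(u)
        self.add_vertex(v)
        w = self._out[u].get(v, 0) + weight
        self._out[u][v] = w
        self._in[v][u] = w

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._out.get(u, {})

    def weight(self, u: str, v: str) -> int:
        return self._out[u][v]

    def set_weight(self, u: str, v: str, w: int) -> None:
        if w < 0:
            raise GraphError("edge weights must be non-negative")
        self._out[u][v] = w
        self._in[v][u] = w

    def remove_edge(self, u: str, v: str) -> None:
        del self._out[u][v]
        del self._in[v][u]

    def out_edges(self, v: str) -> dict[str, int]:
        return self._out[v]

    def in_edges(self, v: str) -> dict[str, int]:
        return self._in[v]

    def out_degree(self, v: str) -> int:
        return len(self._out[v])

    def in_degree(self, v: str) -> int:
        return len(self._in[v])

    def edges(self) -> Iterator[tuple[str, str, int]]:
        for u, targets in self._out.items():
            for v, w in targets.items():
                yield u, v, w

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self._out.values())

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges())

    def edge_kmer(self, u: str, v: str) -> str:
        return u + v[-1]

    # -- maintenance -------------------------------------------------------
    def prune_isolated(self, candidates: Iterable[str] | None = None) -> None:
        """Drop vertices with no incident edges."""
        vs = list(candidates) if candidates is not None else list(self._out)
        for v in vs:
            if v in self._out and not self._out[v] and not self._in[v]:
                del self._out[v]
                del self._in[v]

    def copy(self) -> "DeBruijnGraph":
        g = DeBruijnGraph(self.k)
        g._out = {v: dict(t) for v, t in self._out.items()}
        g._in = {v: dict(t) for v, t in self._in.items()}
        return g


def build_graph(table: KmerCountTable) -> DeBruijnGraph:
    """One edge per distinct k-mer, weighted by its count."""
    if not table.counts:
        raise GraphError("cannot build a graph from an empty k-mer table")
    g = DeBruijnGraph(table.k)
    for kmer, count in table.counts.items():
        g.add_edge(kmer[:-1], kmer[1:], count)
    return g


# ---------------------------------------------------------------------------
# cleaning


def auto_weight_cutoff(counts: dict[str, int] | KmerCountTable) -> int:
    """Coverage-tied low-weight cutoff: max(2, round(0.1 * modal weight)).

    With sequencing errors the raw histogram mode sits at 1 (error
    k-mers), so the mode is taken above the first rising point (the
    valley between the error peak and the coverage peak).
    """
    if isinstance(counts, KmerCountTable):
        counts = counts.counts
    if not counts:
        return 2
    hist = Counter(counts.values())
    max_c = max(hist)
    valley = None
    prev = hist.get(1, 0)
    for c in range(2, max_c + 1):
        h = hist.get(c, 0)
        if h > prev:
            valley = c
            break
        prev = h
    if valley is None:
        pool = hist
    else:
        pool = {c: n for c, n in hist.items() if c >= valley}
    modal = max(pool, key=lambda c: (pool[c], c))
    return max(2, int(0.1 * modal + 0.5))


def remove_low_weight_edges(graph: DeBruijnGraph, cutoff: int) -> DeBruijnGraph:
    """Delete every edge with weight < cutoff; prune isolated vertices."""
    if cutoff < 0:
        raise ParameterError("cutoff must be >= 0")
    doomed = [(u, v) for u, v, w in graph.edges() if w < cutoff]
    touched = set()
    for u, v in doomed:
        graph.remove_edge(u, v)
        touched.add(u)
        touched.add(v)
    graph.prune_isolated(touched)
    if doomed:
        logger.info("removed %d edges below weight %d", len(doomed), cutoff)
    return graph


def _walk_tip_back(graph: DeBruijnGraph, sink: str, max_len: int):
    """Tip ending at ``sink``: edges back to the branch vertex, or None."""
    edges = []
    cur = sink
    while len(edges) <= max_len:
        ins = graph.in_edges(cur)
        if len(ins) != 1:
            return None  # merge point or orphan: not a tip
        (u,) = ins
        edges.append((u, cur))
        if graph.out_degree(u) > 1:
            return edges  # u is the branch vertex
        if graph.in_degree(u) != 1:
            return None  # source or merge: a real path end, not a tip
        cur = u
    return None


def _walk_tip_fwd(graph: DeBruijnGraph, source: str, max_len: int):
    edges = []
    cur = source
    while len(edges) <= max_len:
        outs = graph.out_edges(cur)
        if len(outs) != 1:
            return None
        (v,) = outs
        edges.append((cur, v))
        if graph.in_degree(v) > 1:
            return edges  # v is the branch vertex
        if graph.out_degree(v) != 1:
            return None
        cur = v
    return None


def remove_tips(graph: DeBruijnGraph, max_tip_length: int,
                weight_ratio: float = 0.2) -> DeBruijnGraph:
    """Remove short dead-end paths that are much lighter than the path
    they branch off.

    A tip is a maximal unbranched path of at most ``max_tip_length``
    edges ending at a vertex with no outgoing edges (or starting at one
    with no incoming edges).  It is deleted when its minimum edge weight
    is below ``weight_ratio`` times the heaviest competing edge at the
    branch point.  Iterates to a fixpoint.
    """
    if max_tip_length < 1:
        raise ParameterError("max_tip_length must be >= 1")
    removed_total = 0
    for _ in range(100):
        removed = 0
        # dead ends (no out-edges)
        for sink in sorted(v for v in graph.vertices()
                           if graph.out_degree(v) == 0 and graph.in_degree(v) >= 1):
            if sink not in graph or graph.out_degree(sink) != 0:
                continue
            tip = _walk_tip_back(graph, sink, max_tip_length)
            if tip is None:
                continue
            branch, first = tip[-1]
            competing = max(w for t, w in graph.out_edges(branch).items()
                            if t != first)
            if min(graph.weight(u, v) for u, v in tip) < weight_ratio * competing:
                for u, v in tip:
                    graph.remove_edge(u, v)
                graph.prune_isolated({x for e in tip for x in e})
                removed += 1
        # dead starts (no in-edges)
        for source in sorted(v for v in graph.vertices()
                             if graph.in_degree(v) == 0 and graph.out_degree(v) >= 1):
            if source not in graph or graph.in_degree(source) != 0:
                continue
            tip = _walk_tip_fwd(graph, source, max_tip_length)
            if tip is None:
                continue
            last, branch = tip[-1]
            competing = max(w for t, w in graph.in_edges(branch).items()
                            if t != last)
            if min(graph.weight(u, v) for u, v in tip) < weight_ratio * competing:
                for u, v in tip:
                    graph.remove_edge(u, v)
                graph.prune_isolated({x for e in tip for x in e})
                removed += 1
        removed_total += removed
        if removed == 0:
            break
    if removed_total:
        logger.info("removed %d tips", removed_total)
    return graph


def _follow_simple_path(graph: DeBruijnGraph, start: str, first: str,
                        max_len: int):
    """Follow start->first through 1-in/1-out vertices.

    Returns the vertex path ending at the first vertex that is not
    1-in/1-out (a join or branch point), or None if no such vertex is
    reached within ``max_len`` edges.
    """
    path = [start, first]
    cur = first
    while len(path) - 1 <= max_len:
        if graph.in_degree(cur) != 1 or graph.out_degree(cur) != 1:
            return path
        (nxt,) = graph.out_edges(cur)
        path.append(nxt)
        cur = nxt
    return None


def remove_bubbles(graph: DeBruijnGraph, max_bubble_length: int) -> DeBruijnGraph:
    """Pop simple bubbles: two vertex-disjoint unbranched paths of at
    most ``max_bubble_length`` edges joining the same ordered vertex
    pair.  The lower-total-weight path is deleted and its per-edge
    weight added to the survivor; ties keep the lexicographically
    smaller path.  Nested bubbles are handled by fixpoint iteration.
    """
    if max_bubble_length < 1:
        raise ParameterError("max_bubble_length must be >= 1")
    popped_total = 0
    for _ in range(1000):
        popped = False
        for b in sorted(v for v in graph.vertices() if graph.out_degree(v) >= 2):
            if b not in graph or graph.out_degree(b) < 2:
                continue
            paths = []
            for t in sorted(graph.out_edges(b)):
                p = _follow_simple_path(graph, b, t, max_bubble_length)
                if p is not None and p[-1] != b:
                    paths.append(p)
            found = None
            for i in range(len(paths)):
                for j in range(i + 1, len(paths)):
                    a, c = paths[i], paths[j]
                    if a[-1] != c[-1]:
                        continue
                    if set(a[1:-1]) & set(c[1:-1]):
                        continue
                    found = (a, c)
                    break
                if found:
                    break
            if not found:
                continue
            a, c = found
            wa = sum(graph.weight(a[i], a[i + 1]) for i in range(len(a) - 1))
            wc = sum(graph.weight(c[i], c[i + 1]) for i in range(len(c) - 1))
            # lower total weight is deleted; ties keep the lex-smaller path
            if wa != wc:
                loser, keeper, w_lost = (a, c, wa) if wa < wc else (c, a, wc)
            elif tuple(a) < tuple(c):
                loser, keeper, w_lost = c, a, wc
            else:
                loser, keeper, w_lost = a, c, wa
            per_edge = int(w_lost / (len(loser) - 1) + 0.5)
            for i in range(len(loser) - 1):
                graph.remove_edge(loser[i], loser[i + 1])
            graph.prune_isolated(loser)
            for i in range(len(keeper) - 1):
                graph.set_weight(keeper[i], keeper[i + 1],
                                 graph.weight(keeper[i], keeper[i + 1]) + per_edge)
            popped = True
            popped_total += 1
        if not popped:
            break
    if popped_total:
        logger.info("popped %d bubbles", popped_total)
    return graph


def clean_graph(graph: DeBruijnGraph, cutoff: int, max_tip_length: int,
                weight_ratio: float = 0.2,
                max_bubble_length: int | None = None) -> DeBruijnGraph:
    """Standard cleaning order: low-weight edges, then tips and bubbles
    interleaved to a fixpoint."""
    if max_bubble_length is None:
        max_bubble_length = max_tip_length
    remove_low_weight_edges(graph, cutoff)
    for _ in range(5):
        before = graph.n_edges
        remove_tips(graph, max_tip_length, weight_ratio)
        remove_bubbles(graph, max_bubble_length)
        if graph.n_edges == before:
            break
    return graph


# ---------------------------------------------------------------------------
# debug dumps


def write_edge_list(graph: DeBruijnGraph, path) -> None:
    """Tab-separated ``u<TAB>v<TAB>weight`` dump."""
    with open(path, "w") as fh:
        for u, v, w in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\t{w}\n")


def write_gfa(graph: DeBruijnGraph, path) -> None:
    """GFA v1 dump for visualization (segments = vertices, links = edges)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for v in sorted(graph.vertices()):
            fh.write(f"S\t{v}\t{v}\n")
        for u, v, w in sorted(graph.edges()):
            fh.write(f"L\t{u}\t+\t{v}\t+\t{graph.k - 2}M\tRC:i:{w}\n")
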