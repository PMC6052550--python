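"""Contig generation by weight-consuming graph traversal.

A vertex is unambiguous when each side has at most one edge, or exactly
two edges of which exactly one lies on a "simple return path" — a
positive-weight directed path from the edge's target back to its source
whose cycle contains at least one vertex with more than one in-edge and
at least one with more than one out-edge.  Traversal extends a contig
through unambiguous vertices, appending one base per edge and
decrementing the edge's weight (the edge is removed at zero); at a
vertex with two out-edges the return-path edge is taken while it retains
weight, the other afterwards — this is what spells a tandem motif the
correct number of times.  An ambiguous vertex ends the current contig
and seeds new ones.

Ambiguity and return-path preferences are classified once on the input
graph, before any weight is consumed; all tie-breaks are lexicographic,
so identical graphs yield identical ordered contig sets.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

from .graph_core import DeBruijnGraph
from .io_formats import revcomp

logger = logging.getLogger("tandemasm.contigs")

#: Return-path searches are depth-bounded so that, on a circular genome,
#: the genome-wide cycle itself does not count as a return path for every
#: edge (which would make every loop entry/exit ambiguous and shatter the
#: assembly).  The bound only needs to exceed the longest tandem motif.
DEFAULT_MAX_RETURN_DEPTH = 1000


@dataclass
class AssemblyResult:
    """Ordered contig set with summary statistics."""

    contigs: list[str]
    n_contigs: int = field(init=False)
    n50: int = field(init=False)
    longest: int = field(init=False)

    def __post_init__(self):
        self.n_contigs = len(self.contigs)
        self.longest = max((len(c) for c in self.contigs), default=0)
        self.n50 = compute_n50([len(c) for c in self.contigs])

    def total_bases(self) -> int:
        return sum(len(c) for c in self.contigs)

    def filtered(self, min_length: int) -> "AssemblyResult":
        """Report-level filter; the full contig set is never trimmed on disk."""
        return AssemblyResult([c for c in self.contigs if len(c) >= min_length])


def compute_n50(lengths: list[int]) -> int:
    """Length of the shortest contig in the minimal set covering at least
    half of the total assembled bases."""
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if 2 * acc >= total:
            return ln
    return 0


def _bfs_path(graph: DeBruijnGraph, src: str, dst: str, max_depth: int):
    """Shortest positive-weight directed path src -> dst of at most
    ``max_depth`` edges, or None."""
    if src == dst:
        return [src]
    parent = {src: None}
    frontier = [src]
    for _ in range(max_depth):
        nxt_frontier = []
        for cur in frontier:
            for nxt in graph.out_edges(cur):
                if nxt in parent:
                    continue
                parent[nxt] = cur
                if nxt == dst:
                    path = [dst]
                    while path[-1] != src:
                        path.append(parent[path[-1]])
                    path.reverse()
                    return path
                nxt_frontier.append(nxt)
        if not nxt_frontier:
            return None
        frontier = nxt_frontier
    return None


def simple_return_path(graph: DeBruijnGraph, edge: tuple[str, str],
                       max_depth: int = DEFAULT_MAX_RETURN_DEPTH) -> bool:
    """True iff a directed path from the edge's target back to its source
    exists (within ``max_depth`` edges) and the resulting cycle contains
    a vertex with more than one in-edge and a vertex with more than one
    out-edge."""
    u, v = edge
    if not graph.has_edge(u, v):
        return False
    path = _bfs_path(graph, v, u, max_depth)
    if path is None:
        return False
    cycle = set(path)
    return (any(graph.in_degree(x) > 1 for x in cycle)
            and any(graph.out_degree(x) > 1 for x in cycle))


def is_ambiguous(graph: DeBruijnGraph, v: str,
                 max_depth: int = DEFAULT_MAX_RETURN_DEPTH) -> bool:
    """Ambiguity rule: a side with >= 3 edges is always ambiguous; a side
    with exactly 2 is unambiguous only when exactly one of its edges has
    a simple return path."""
    outs = graph.out_edges(v)
    ins = graph.in_edges(v)
    for side_edges in (
        [(v, t) for t in outs],
        [(u, v) for u in ins],
    ):
        if len(side_edges) >= 3:
            return True
        if len(side_edges) == 2:
            n_return = sum(
                simple_return_path(graph, e, max_depth) for e in side_edges)
            if n_return != 1:
                return True
    return False


def _weak_components(graph: DeBruijnGraph) -> list[set[str]]:
    seen: set[str] = set()
    comps = []
    for v in graph.vertices():
        if v in seen:
            continue
        comp = {v}
        q = deque([v])
        seen.add(v)
        while q:
            cur = q.popleft()
            for nxt in list(graph.out_edges(cur)) + list(graph.in_edges(cur)):
                if nxt not in seen:
                    seen.add(nxt)
                    comp.add(nxt)
                    q.append(nxt)
        comps.append(comp)
    return comps


def find_start_vertices(graph: DeBruijnGraph) -> list[str]:
    """Vertices with no in-edges and at least one out-edge, in
    lexicographic order; components without such a vertex (perfect
    cycles) contribute their lexicographically smallest vertex."""
    starts = sorted(v for v in graph.vertices()
                    if graph.in_degree(v) == 0 and graph.out_degree(v) >= 1)
    start_set = set(starts)
    for comp in _weak_components(graph):
        if not comp & start_set and any(graph.out_degree(v) for v in comp):
            starts.append(min(comp))
    return starts


def generate_contigs(graph: DeBruijnGraph, double_strand: bool = False,
                     max_restarts: int = 100000,
                     max_return_depth: int = DEFAULT_MAX_RETURN_DEPTH,
                     ) -> AssemblyResult:
    """Spell contigs from a balanced graph, consuming edge weights.

    In double-strand mode a contig equal to the reverse complement of an
    earlier contig is dropped from the output.  The input graph is not
    modified.
    """
    g = graph.copy()

    # classify once, before any weight is consumed
    ambiguous = {v for v in g.vertices() if is_ambiguous(g, v, max_return_depth)}
    preferred: dict[str, str] = {}
    for v in g.vertices():
        if v in ambiguous:
            continue
        outs = g.out_edges(v)
        if len(outs) == 2:
            for t in outs:
                if simple_return_path(g, (v, t), max_return_depth):
                    preferred[v] = t
                    break

    contigs: list[str] = []
    worklist: deque[str] = deque(find_start_vertices(g))
    restarts = 0

    def consume(u: str, t: str) -> None:
        w = g.weight(u, t) - 1
        if w == 0:
            g.remove_edge(u, t)
        else:
            g.set_weight(u, t, w)

    def walk(start: str, forced_first: str | None = None) -> str:
        parts = [start]
        v = start
        if forced_first is not None:
            consume(v, forced_first)
            parts.append(forced_first[-1])
            v = forced_first
        while True:
            if v in ambiguous and (len(parts) > 1 or forced_first is None):
                worklist.append(v)
                break
            outs = g.out_edges(v) if v in g else {}
            if not outs:
                break
            if len(outs) == 1:
                (t,) = outs
            elif v in preferred and preferred[v] in outs:
                t = preferred[v]
            elif v in preferred:
                others = sorted(x for x in outs)
                t = others[0]
            else:
                # vertex became branching only through traversal bookkeeping
                t = sorted(outs)[0]
            consume(v, t)
            parts.append(t[-1])
            v = t
        return "".join(parts)

    def drain(v: str) -> None:
        nonlocal restarts
        while v in g and g.out_edges(v):
            restarts += 1
            if restarts > max_restarts:
                return
            if v in ambiguous:
                first = sorted(g.out_edges(v))[0]
                contigs.append(walk(v, forced_first=first))
            else:
                contigs.append(walk(v))

    while True:
        while worklist:
            if restarts > max_restarts:
                break
            drain(worklist.popleft())
        if restarts > max_restarts:
            logger.warning("traversal restart limit reached; %d edges with "
                           "positive weight left unconsumed", g.n_edges)
            break
        # leftover positive-weight edges (detached cycles, weight noise)
        remaining = [v for v in g.vertices() if g.out_degree(v) >= 1]
        if not remaining:
            break
        sources = sorted(v for v in remaining if g.in_degree(v) == 0)
        if sources:
            worklist.extend(sources)
        else:
            worklist.append(min(remaining))

    if double_strand:
        seen: set[str] = set()
        kept = []
        for c in contigs:
            if revcomp(c) in seen:
                continue
            seen.add(c)
            kept.append(c)
        contigs = kept

    return AssemblyResult(contigs)
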