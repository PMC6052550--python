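"""Detection and balancing of tandem-repeat loops in the normalized graph.

A tandem array appears as a cycle attached to the rest of the graph by a
single in-edge and a single out-edge: exactly one cycle vertex (the
entry) has two in-edges and one out-edge, exactly one (the exit) has one
in-edge and two out-edges, and every other cycle vertex is 1-in/1-out.
Balancing first makes each of the two branches weight-uniform, then
adjusts the less numerous branch so that every loop vertex reaches
degree zero, where a vertex's degree is the sum of its in-edge weights
minus the sum of its out-edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .graph_core import DeBruijnGraph, GraphError
from .io_formats import ParameterError

logger = logging.getLogger("tandemasm.repeats")


@dataclass
class LoopStructure:
    """A detected tandem-repeat loop.

    ``body`` is the vertex path entry -> exit inside the loop, ``back``
    the return path exit -> entry.  Both include their endpoints; all
    interior vertices are 1-in/1-out.
    """

    entry: str
    exit: str
    body: list[str]
    back: list[str]

    def body_edges(self) -> list[tuple[str, str]]:
        return [(self.body[i], self.body[i + 1]) for i in range(len(self.body) - 1)]

    def back_edges(self) -> list[tuple[str, str]]:
        return [(self.back[i], self.back[i + 1]) for i in range(len(self.back) - 1)]

    def vertices(self) -> set[str]:
        return set(self.body) | set(self.back)


def vertex_degree(graph: DeBruijnGraph, v: str) -> int:
    """Sum of in-edge weights minus sum of out-edge weights."""
    if v not in graph:
        raise GraphError(f"unknown vertex {v!r}")
    return sum(graph.in_edges(v).values()) - sum(graph.out_edges(v).values())


def _chain_from(graph: DeBruijnGraph, start: str, first: str, limit: int):
    """Follow start -> first through 1-in/1-out vertices until a vertex
    that is not 1-in/1-out; returns the vertex path or None on overrun."""
    path = [start, first]
    cur = first
    for _ in range(limit):
        if graph.in_degree(cur) != 1 or graph.out_degree(cur) != 1:
            return path
        (nxt,) = graph.out_edges(cur)
        path.append(nxt)
        cur = nxt
    return None


def detect_tandem_loops(graph: DeBruijnGraph) -> list[LoopStructure]:
    """Find every cycle with the valid 1-entry/1-exit degree pattern.

    Cycles with more than one entry- or exit-type vertex are not
    returned.
    """
    loops = []
    limit = graph.n_edges + 1
    for entry in sorted(v for v in graph.vertices()
                        if graph.in_degree(v) == 2 and graph.out_degree(v) == 1):
        (first,) = graph.out_edges(entry)
        body = _chain_from(graph, entry, first, limit)
        if body is None:
            continue
        exit_v = body[-1]
        if exit_v == entry:
            continue
        if graph.in_degree(exit_v) != 1 or graph.out_degree(exit_v) != 2:
            continue
        if any(x in (entry, exit_v) for x in body[1:-1]):
            continue
        # On a circular genome both out-edges of the exit can lead back to
        # the entry (one through the motif loop, one the long way around
        # the chromosome); the motif loop is the shorter one.
        candidates = []
        for t in sorted(graph.out_edges(exit_v)):
            cand = _chain_from(graph, exit_v, t, limit)
            if cand is not None and cand[-1] == entry:
                candidates.append(cand)
        if not candidates:
            continue
        back = min(candidates, key=len)
        interior_body = set(body[1:-1])
        interior_back = set(back[1:-1])
        if interior_body & interior_back:
            continue
        if entry in interior_back or exit_v in interior_back:
            continue
        loops.append(LoopStructure(entry, exit_v, body, back))
    return loops


def _median_half_up(values: list[int]) -> int:
    s = sorted(values)
    m = len(s)
    if m == 0:
        raise ParameterError("empty branch")
    if m % 2 == 1:
        mid = float(s[m // 2])
    else:
        mid = (s[m // 2 - 1] + s[m // 2]) / 2.0
    return int(mid + 0.5) if mid >= 0 else -int(-mid + 0.5)


def equalize_branch_weights(graph: DeBruijnGraph,
                            branch: list[tuple[str, str]]) -> DeBruijnGraph:
    """Set every edge of an unbranched path to the rounded (half-up)
    median of the path's weights."""
    if not branch:
        return graph
    med = _median_half_up([graph.weight(u, v) for u, v in branch])
    for u, v in branch:
        graph.set_weight(u, v, med)
    return graph


def _external_edges(graph: DeBruijnGraph, loop: LoopStructure):
    """(external in-edge weight at entry, external out-edge weight at exit),
    or None if the external pattern is not exactly 1-in/1-out."""
    back_prev = loop.back[-2]
    ext_in = [(u, w) for u, w in graph.in_edges(loop.entry).items() if u != back_prev]
    # exit's loop-internal out-edge is the first back edge
    back_first = loop.back[1]
    ext_out = [(v, w) for v, w in graph.out_edges(loop.exit).items()
               if v != back_first]
    if len(ext_in) != 1 or len(ext_out) != 1:
        return None
    return ext_in[0], ext_out[0]


def balance_loop(graph: DeBruijnGraph, loop: LoopStructure) -> DeBruijnGraph:
    """Balance a weight-uniform loop so every loop vertex has degree 0.

    The branch with more vertices keeps its weight; the other branch
    gets the unique uniform weight implied by the single external
    in-weight and out-weight.  If no consistent non-negative solution
    exists the loop is left unchanged and a diagnostic is logged.
    """
    ext = _external_edges(graph, loop)
    if ext is None:
        logger.warning("loop at %s: external degree pattern not 1-in/1-out; "
                       "left unchanged", loop.entry)
        return graph
    (_, ext_in), (_, ext_out) = ext
    if ext_in != ext_out:
        logger.warning(
            "loop at %s: external in-weight %d != out-weight %d; no consistent "
            "solution, left unchanged", loop.entry, ext_in, ext_out)
        return graph
    body_edges = loop.body_edges()
    back_edges = loop.back_edges()
    w_body = graph.weight(*body_edges[0])
    w_back = graph.weight(*back_edges[0])
    # "more numerous" = more vertices; ties adjust the back branch, which
    # carries the m-1 return traversals and is the natural free variable
    if len(loop.body) >= len(loop.back):
        new_back = w_body - ext_in
        if new_back < 0:
            logger.warning("loop at %s: negative back weight %d; left unchanged",
                           loop.entry, new_back)
            return graph
        target, new_w, old_w = back_edges, new_back, w_back
    else:
        target, new_w, old_w = body_edges, w_back + ext_in, w_body
    if new_w != old_w:
        for u, v in target:
            graph.set_weight(u, v, new_w)
    return graph


def resolve_all(graph: DeBruijnGraph, max_sweeps: int = 100) -> DeBruijnGraph:
    """Equalize and balance every detected loop, iterating until no loop
    changes.  Non-loop edges are never modified."""
    for sweep in range(max_sweeps):
        changed = False
        for loop in detect_tandem_loops(graph):
            before = [graph.weight(u, v)
                      for u, v in loop.body_edges() + loop.back_edges()]
            equalize_branch_weights(graph, loop.body_edges())
            equalize_branch_weights(graph, loop.back_edges())
            balance_loop(graph, loop)
            after = [graph.weight(u, v)
                     for u, v in loop.body_edges() + loop.back_edges()]
            if after != before:
                changed = True
        if not changed:
            return graph
    logger.warning("loop balancing did not converge after %d sweeps", max_sweeps)
    return graph


def format_loop_report(graph: DeBruijnGraph, loops: list[LoopStructure]) -> str:
    """Human-readable diagnostic listing each detected loop."""
    lines = [f"{len(loops)} tandem-repeat loop(s) detected"]
    for lp in loops:
        w_body = [graph.weight(u, v) for u, v in lp.body_edges()]
        w_back = [graph.weight(u, v) for u, v in lp.back_edges()]
        lines.append(
            f"  entry={lp.entry} exit={lp.exit} "
            f"body_edges={len(w_body)} back_edges={len(w_back)} "
            f"body_w={w_body[0] if w_body else '-'} "
            f"back_w={w_back[0] if w_back else '-'}")
    return "\n".join(lines)
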