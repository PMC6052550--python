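"""Statistical model of edge weights and its two products.

For N error-free reads of identical length L drawn uniformly from a
circular genome of length G, the weight of a non-repetitive edge is
N(L-k+1)/G in expectation, and (Delta/d) times that for edges inside a
tandem array of total length n and motif length d, with
Delta = n - k + 1.  Two consequences are implemented here:

* weight normalization, which rescales read-space counts into
  per-genome copy numbers via the factor p = G / (N(L-k+1)) and
  half-up rounding w' = floor(p*w + 0.5);
* the required-coverage planner
  c = k/(L-k+1) * (2 * Phi^-1((1+q)/2))^2 * Delta/d
  giving the depth needed to recover a repeat count at confidence q.

The Poisson rate lambda = N*L*(L-k+1)*Delta / (G*k*d) is kept as a
separate diagnostic; it carries an extra L/k factor relative to the
expectation above, so normalization deliberately uses only the p/round
pair, which is exactly the reciprocal of the non-repetitive expectation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.stats import norm as _norm

from .graph_core import DeBruijnGraph, GraphError
from .io_formats import ParameterError

logger = logging.getLogger("tandemasm.coverage")


@dataclass
class CoverageParams:
    """Parameters of the edge-weight model.

    N reads of length L, graph dimension k, genome length G; a tandem
    repeat of total length n built from a motif of length d.  Delta is
    always derived as n - k + 1, never stored.  q is the confidence
    level used by the coverage planner.
    """

    N: int
    L: int
    k: int
    G: int
    n: int | None = None
    d: int | None = None
    q: float = 0.95

    def __post_init__(self):
        for name in ("N", "L", "k", "G"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.L <= self.k:
            raise ParameterError(f"read length L={self.L} must exceed k={self.k}")
        if self.n is not None:
            if self.n <= self.k:
                raise ParameterError(
                    f"tandem repeat length n={self.n} must exceed k={self.k}")
            if self.d is None or not 0 < self.d <= self.n:
                raise ParameterError("motif length d must satisfy 0 < d <= n")
        if not 0.0 <= self.q <= 1.0:
            raise ParameterError("q must be in [0, 1]")

    @property
    def delta(self) -> int:
        if self.n is None:
            raise ParameterError("no tandem repeat parameters (n, d) set")
        return self.n - self.k + 1

    @property
    def coverage(self) -> float:
        return self.N * self.L / self.G


def expected_edge_weight(params: CoverageParams, repetitive: bool = False) -> float:
    """Expected edge weight: N(L-k+1)/G, times Delta/d inside a repeat."""
    base = params.N * (params.L - params.k + 1) / params.G
    if not repetitive:
        return base
    return params.delta / params.d * base


def poisson_lambda(params: CoverageParams) -> float:
    """Diagnostic Poisson rate N*L*(L-k+1)*Delta / (G*k*d)."""
    return (params.N * params.L * (params.L - params.k + 1) * params.delta
            / (params.G * params.k * params.d))


def normalization_factor(G: int, N: int, L: int, k: int) -> float:
    """p = G / (N(L-k+1))."""
    if L <= k:
        raise ParameterError(f"read length L={L} must exceed k={k}")
    denom = N * (L - k + 1)
    if denom <= 0:
        raise ParameterError("N(L-k+1) must be positive")
    return G / denom


def normalize_weight(w: int, p: float) -> int:
    """Half-up rounding w' = floor(p*w + 0.5) (not banker's rounding)."""
    if w < 0:
        raise ParameterError("edge weight must be non-negative")
    return math.floor(p * w + 0.5)


def normalize_graph(graph: DeBruijnGraph, params: CoverageParams | None = None,
                    p: float | None = None) -> DeBruijnGraph:
    """Replace every edge weight by its normalized copy number.

    Edges whose normalized weight is 0 are deleted.  ``p`` may be given
    directly; otherwise it is derived from ``params``.
    """
    if p is None:
        if params is None:
            raise ParameterError("either params or p is required")
        p = normalization_factor(params.G, params.N, params.L, params.k)
    doomed = []
    for u, v, w in list(graph.edges()):
        w2 = normalize_weight(w, p)
        if w2 == 0:
            doomed.append((u, v))
        else:
            graph.set_weight(u, v, w2)
    touched = set()
    for u, v in doomed:
        graph.remove_edge(u, v)
        touched.update((u, v))
    graph.prune_isolated(touched)
    if doomed:
        logger.info("normalization dropped %d zero-copy edges", len(doomed))
    return graph


def weight_distribution_normal(n: int, d: int, k: int) -> tuple[float, float]:
    """Normal approximation of normalized repeat-edge weights:
    mean Delta/d, standard deviation sqrt(Delta/d)."""
    if n <= k:
        raise ParameterError(f"n={n} must exceed k={k}")
    if d <= 0:
        raise ParameterError("d must be positive")
    mu = (n - k + 1) / d
    return mu, math.sqrt(mu)


def required_coverage(q: float, k: int, L: int, n: int, d: int) -> float:
    """Depth of coverage needed to recover an n/d tandem array at
    confidence q: k/(L-k+1) * (2*Phi^-1((1+q)/2))^2 * Delta/d."""
    if not 0.0 < q < 1.0:
        raise ParameterError("q must be in (0, 1)")
    if n <= k:
        raise ParameterError(f"n={n} must exceed k={k}")
    if L <= k:
        raise ParameterError(f"L={L} must exceed k={k}")
    if d <= 0:
        raise ParameterError("d must be positive")
    z = _norm.ppf((1.0 + q) / 2.0)
    return k / (L - k + 1) * (2.0 * z) ** 2 * (n - k + 1) / d


def estimate_genome_size(graph: DeBruijnGraph, double_strand: bool = False) -> int:
    """Genome size estimate = number of distinct k-mers (edges), halved
    when both strands were counted.  A user-provided genome size always
    wins over this estimate."""
    n = graph.n_edges
    if n == 0:
        raise GraphError("cannot estimate genome size from an empty graph")
    if double_strand:
        return max(1, round(n / 2))
    return n
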