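"""End-to-end assembly orchestration.

Step order: count k-mers -> build graph -> clean (low weight, tips,
bubbles) -> normalize edge weights into per-genome copy numbers ->
balance tandem-repeat loops -> weight-consuming contig traversal.

Normalization uses p = G / (effective k-mer total), where the effective
total is the summed edge weight of the *cleaned* graph (per strand in
double-strand mode).  Using the raw read-derived N(L-k+1) would bias
copy numbers low, because with a 1% substitution rate a large fraction
of raw k-mers contain an error and are removed during cleaning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .contig_builder import AssemblyResult, generate_contigs
from .coverage_model import estimate_genome_size, normalize_graph
from .graph_core import (DeBruijnGraph, auto_weight_cutoff, build_graph,
                         clean_graph, count_kmers)
from .io_formats import AssemblyConfig, ParameterError, Read
from .repeat_resolver import detect_tandem_loops, resolve_all

logger = logging.getLogger("tandemasm.pipeline")

MIN_RELIABLE_COVERAGE = 100.0


@dataclass
class AssemblyInfo:
    """Run diagnostics reported alongside the contigs."""

    n_reads: int
    total_bases: int
    genome_size: int
    genome_size_estimated: bool
    coverage: float
    weight_cutoff: int
    normalization_factor: float | None
    n_loops: int
    n_edges_raw: int
    n_edges_clean: int


def assemble(reads: Sequence[Read],
             config: AssemblyConfig | None = None,
             ) -> tuple[AssemblyResult, AssemblyInfo]:
    """Assemble a read set into contigs.

    Reads from both mates of a pair are passed as one flat collection;
    pairing information is never used (unitig mode).
    """
    if config is None:
        config = AssemblyConfig()
    if not reads:
        raise ParameterError("no input reads")
    min_len = min(len(r) for r in reads)
    if config.k >= min_len:
        raise ParameterError(
            f"k={config.k} must be smaller than the minimum read length "
            f"{min_len}")
    single = config.single_strand_mode
    strands = 1 if single else 2

    table = count_kmers(reads, config.k, single_strand=single)
    cutoff = (config.low_weight_cutoff if config.low_weight_cutoff is not None
              else auto_weight_cutoff(table))
    logger.info("counted %d distinct %d-mers (cutoff %d)", len(table),
                config.k, cutoff)
    # dropping sub-cutoff k-mers before graph construction is equivalent
    # to remove_low_weight_edges on the full graph, but far cheaper
    n_edges_raw = len(table)
    graph = build_graph(table.filter_min_count(cutoff))
    clean_graph(graph, cutoff=0, max_tip_length=config.tip_length_factor * config.k,
                weight_ratio=config.weight_ratio)
    logger.info("cleaned graph: %d vertices, %d edges", graph.n_vertices,
                graph.n_edges)

    if config.genome_size_override is not None:
        G = config.genome_size_override
        estimated = False
    else:
        G = estimate_genome_size(graph, double_strand=not single)
        estimated = True
        logger.info("estimated genome size %d from distinct k-mers", G)

    total_bases = sum(len(r) for r in reads)
    coverage = total_bases / G
    p = None
    n_loops = 0
    if config.normalize:
        if coverage < MIN_RELIABLE_COVERAGE:
            logger.warning(
                "observed coverage %.1fx is below the %.0fx needed for "
                "reliable repeat-count normalization; results may be wrong",
                coverage, MIN_RELIABLE_COVERAGE)
        p = strands * G / graph.total_weight()
        normalize_graph(graph, p=p)
        if config.resolve_repeats:
            n_loops = len(detect_tandem_loops(graph))
            if n_loops:
                logger.info("balancing %d tandem-repeat loop(s)", n_loops)
            resolve_all(graph)
    else:
        # presence-only unitig mode: every surviving k-mer spelled once
        for u, v, _w in list(graph.edges()):
            graph.set_weight(u, v, 1)

    result = generate_contigs(graph, double_strand=not single)
    info = AssemblyInfo(
        n_reads=len(reads),
        total_bases=total_bases,
        genome_size=G,
        genome_size_estimated=estimated,
        coverage=coverage,
        weight_cutoff=cutoff,
        normalization_factor=p,
        n_loops=n_loops,
        n_edges_raw=n_edges_raw,
        n_edges_clean=graph.n_edges,
    )
    return result, info
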