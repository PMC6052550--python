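"""Shared fixtures: the k=4 worked-example graph and small builders."""

import pytest

from tandemasm.graph_core import DeBruijnGraph, KmerCountTable, build_graph

# The hand-derived weighted 4-mer multiset of the worked example: five
# contigs {CCAT, CATGGGAG, CATTAACCC, TTTCCC, CCCGACGACGACT} with the
# GAC loop traversed three times.
WORKED_EXAMPLE_4MERS = {
    "CCAT": 1, "CATG": 1, "ATGG": 1, "TGGG": 1, "GGGA": 1, "GGAG": 1,
    "CATT": 1, "ATTA": 1, "TTAA": 1, "TAAC": 1, "AACC": 1, "ACCC": 1,
    "TTTC": 1, "TTCC": 1, "TCCC": 1, "CCCG": 1, "CCGA": 1,
    "CGAC": 3, "GACG": 2, "ACGA": 2, "GACT": 1,
}

WORKED_EXAMPLE_CONTIGS = {
    "CCAT", "CATGGGAG", "CATTAACCC", "TTTCCC", "CCCGACGACGACT",
}


@pytest.fixture
def fig_table() -> KmerCountTable:
    return KmerCountTable(4, dict(WORKED_EXAMPLE_4MERS))


@pytest.fixture
def fig_graph(fig_table) -> DeBruijnGraph:
    return build_graph(fig_table)


def tiny_graph(edges, k: int = 2) -> DeBruijnGraph:
    """Graph from (u, v, w) triples; with k=2 any single-char labels work."""
    g = DeBruijnGraph(k)
    for u, v, w in edges:
        g.add_edge(u, v, w)
    return g


@pytest.fixture
def loop_graph() -> DeBruijnGraph:
    """Valid tandem loop: entry e (2-in/1-out), exit x (1-in/2-out),
    body e->a->b->x at weight 3, back x->c->e at weight 1, external
    s->e and x->t at weight 1."""
    return tiny_graph([
        ("s", "e", 1),
        ("e", "a", 3), ("a", "b", 3), ("b", "x", 3),
        ("x", "c", 1), ("c", "e", 1),
        ("x", "t", 1),
    ])
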