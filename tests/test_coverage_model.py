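import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemasm.coverage_model import (CoverageParams, estimate_genome_size,
                                      expected_edge_weight,
                                      normalization_factor, normalize_graph,
                                      normalize_weight, poisson_lambda,
                                      required_coverage,
                                      weight_distribution_normal)
from tandemasm.graph_core import GraphError, KmerCountTable, build_graph, count_kmers
from tandemasm.io_formats import ParameterError
from tandemasm.simulator import (ReadSimParams, RepeatSpec, make_reference,
                                 simulate_reads)

from conftest import tiny_graph


def params(**kw):
    base = dict(N=1000, L=100, k=55, G=46000)
    base.update(kw)
    return CoverageParams(**base)


# ---------------------------------------------------------------------------
# closed-form operations


def test_expected_edge_weight_unit():
    assert expected_edge_weight(params()) == pytest.approx(1.0)


def test_expected_edge_weight_repetitive():
    p = params(n=200, d=100)
    assert p.delta == 146
    assert expected_edge_weight(p, repetitive=True) == pytest.approx(1.46)


def test_expected_edge_weight_linear_in_N():
    assert expected_edge_weight(params(N=2000)) == pytest.approx(
        2 * expected_edge_weight(params()))


def test_poisson_lambda_value():
    # 1000*100*46*146 / (46000*55*100)
    lam = poisson_lambda(params(n=200, d=100))
    assert lam == pytest.approx(671_600_000 / 253_000_000)
    assert lam == pytest.approx(2.654545, abs=1e-5)


def test_poisson_lambda_linear_in_N_and_delta():
    base = poisson_lambda(params(n=200, d=100))
    assert poisson_lambda(params(N=2000, n=200, d=100)) == pytest.approx(2 * base)
    # delta doubles: n=345 gives delta=291 vs 146... use exact ratio instead
    p2 = params(n=346, d=100)
    assert poisson_lambda(p2) / base == pytest.approx(p2.delta / 146)


def test_poisson_lambda_reduces_to_expectation_times_L_over_k():
    # algebraic limit: with delta=d the rate is (L/k) * N(L-k+1)/G
    p = params(n=55 + 100 - 1, d=100)  # delta == d
    assert p.delta == p.d
    lam = poisson_lambda(p)
    assert lam == pytest.approx(p.L / p.k * expected_edge_weight(p))


def test_coverage_params_validation():
    with pytest.raises(ParameterError):
        params(n=40, d=10)  # n <= k
    with pytest.raises(ParameterError):
        params(n=200, d=300)  # d > n
    with pytest.raises(ParameterError):
        CoverageParams(N=1000, L=50, k=55, G=1000)  # L <= k
    with pytest.raises(ParameterError):
        params(q=1.5)


def test_normalization_factor_identity_point():
    assert normalization_factor(G=46000, N=1000, L=100, k=55) == pytest.approx(1.0)


def test_normalization_factor_value():
    p = normalization_factor(G=42000, N=63000, L=100, k=55)
    assert p == pytest.approx(42000 / 2_898_000)
    assert p == pytest.approx(0.014493, abs=1e-6)


def test_normalization_factor_rejects_L_le_k():
    with pytest.raises(ParameterError):
        normalization_factor(G=1000, N=10, L=55, k=55)


def test_normalize_weight_zero():
    assert normalize_weight(0, 0.33) == 0


def test_normalize_weight_half_up():
    # floor(p*w + 0.5): 2.5 rounds UP, not banker's
    assert normalize_weight(5, 0.5) == 3


def test_normalize_weight_example():
    assert normalize_weight(207, 0.014493) == 3


@given(st.integers(0, 10**6), st.floats(1e-6, 10.0))
def test_normalize_weight_matches_printed_formula(w, p):
    assert normalize_weight(w, p) == math.floor(p * w + 0.5)


def test_weight_distribution_single_copy_limit():
    # n = k + d - 1 means delta == d
    assert weight_distribution_normal(n=55 + 100 - 1, d=100, k=55) == (1.0, 1.0)


def test_weight_distribution_value():
    mu, sigma = weight_distribution_normal(n=200, d=100, k=55)
    assert mu == pytest.approx(1.46)
    assert sigma == pytest.approx(1.208305, abs=1e-5)


def test_weight_distribution_monotone_in_n():
    mus = [weight_distribution_normal(n, 100, 55)[0] for n in (100, 200, 400)]
    assert mus == sorted(mus) and mus[0] < mus[-1]


def test_required_coverage_unit_quantile():
    # q = 0.6827 makes the standard normal quantile ~1
    q = 0.6827
    c = required_coverage(q, k=55, L=100, n=200, d=100)
    assert c == pytest.approx(55 / 46 * 4 * 1.46, rel=1e-3)


def test_required_coverage_value():
    c = required_coverage(0.95, k=55, L=100, n=200, d=100)
    assert c == pytest.approx(55 / 46 * (2 * 1.959964) ** 2 * 1.46, abs=1e-3)
    assert c == pytest.approx(26.83, abs=0.01)


def test_required_coverage_monotonicity():
    base = required_coverage(0.95, 55, 100, 200, 100)
    assert required_coverage(0.99, 55, 100, 200, 100) > base
    assert required_coverage(0.95, 55, 100, 300, 100) > base
    assert required_coverage(0.95, 55, 100, 300, 150) < \
        required_coverage(0.95, 55, 100, 300, 100)


@given(st.floats(0.05, 0.94), st.floats(0.001, 0.05))
@settings(max_examples=30)
def test_required_coverage_strictly_increasing_in_q(q, dq):
    lo = required_coverage(q, 55, 100, 500, 100)
    hi = required_coverage(q + dq, 55, 100, 500, 100)
    assert hi > lo


def test_required_coverage_rejects_bad_q():
    for q in (0.0, 1.0, -0.1, 1.1):
        with pytest.raises(ParameterError):
            required_coverage(q, 55, 100, 200, 100)


@given(st.integers(100, 10**6), st.integers(56, 300), st.integers(10**3, 10**7),
       st.integers(2, 50), st.integers(1, 400))
@settings(max_examples=100)
def test_coverage_identity(N, L, G, dd, extra):
    # expected weight x normalization factor == 1 (non-rep) or delta/d (rep)
    k = 55
    if L <= k:
        return
    d = dd + k  # ensure n > k below
    n = d + extra
    p = CoverageParams(N=N, L=L, k=k, G=G, n=n, d=d)
    f = normalization_factor(G, N, L, k)
    assert expected_edge_weight(p) * f == pytest.approx(1.0)
    assert expected_edge_weight(p, repetitive=True) * f == pytest.approx(
        p.delta / p.d)


# ---------------------------------------------------------------------------
# graph-level normalization


def test_normalize_graph_p1_identity():
    g = tiny_graph([("a", "b", 3), ("b", "c", 7)])
    normalize_graph(g, p=1.0)
    assert g.weight("a", "b") == 3 and g.weight("b", "c") == 7


def test_normalize_graph_requires_params_or_p():
    g = tiny_graph([("a", "b", 3)])
    with pytest.raises(ParameterError):
        normalize_graph(g)


def test_normalize_graph_drops_zero_edges():
    g = tiny_graph([("a", "b", 1), ("b", "c", 100)])
    normalize_graph(g, p=0.01)
    assert not g.has_edge("a", "b")
    assert g.weight("b", "c") == 1


def _simulate_graph(specs, spacers, k, coverage, seed):
    ref = make_reference(specs, spacer_length=spacers, circular=True, seed=seed)
    sim = ReadSimParams(read_length=100, coverage=coverage, insert_mean=250,
                        insert_std=25, substitution_rate=0.0,
                        forward_only=True, seed=seed + 1)
    r1, r2 = simulate_reads(ref, sim)
    g = build_graph(count_kmers([r.sequence for r in r1 + r2], k))
    return ref, g


def test_normalize_graph_repeat_free_all_ones():
    ref, g = _simulate_graph([RepeatSpec(25, 2)], [900, 900], 21, 100, 21)
    # keep only the repeat-free majority for the all-ones check
    p = len(ref) / g.total_weight()
    normalize_graph(g, p=p)
    weights = [w for _, _, w in g.edges()]
    assert weights.count(1) / len(weights) > 0.99


def test_normalize_graph_tandem_copy_numbers():
    # d=100 motif repeated 3x: loop edges carry the per-genome copy number
    k = 21
    ref, g = _simulate_graph([RepeatSpec(100, 3)], [1000, 1000], k, 200, 33)
    p = len(ref) / g.total_weight()
    normalize_graph(g, p=p)
    # oracle: multiplicity of each k-mer in the circular reference
    circ = ref.sequence + ref.sequence[:k - 1]
    from collections import Counter
    mult = Counter(circ[i:i + k] for i in range(len(ref)))
    for kmer, m in mult.items():
        assert g.weight(kmer[:-1], kmer[1:]) == m


def test_eq4_simulation_consistency():
    # empirical mean of normalized loop weights within 3*sigma/sqrt(m)
    # of delta/d for n=500, d=100, k=55 at >=100x
    k = 55
    ref, g = _simulate_graph([RepeatSpec(100, 5)], [1000, 1000], k, 120, 77)
    p = len(ref) / g.total_weight()
    normalize_graph(g, p=p)
    from collections import Counter
    circ = ref.sequence + ref.sequence[:k - 1]
    mult = Counter(circ[i:i + k] for i in range(len(ref)))
    loop = [kmer for kmer, m in mult.items() if m > 1]
    assert len(loop) == 100
    mu, sigma = weight_distribution_normal(n=500, d=100, k=k)
    mean = sum(g.weight(x[:-1], x[1:]) for x in loop) / len(loop)
    assert abs(mean - mu) <= 3 * sigma / math.sqrt(len(loop))


# ---------------------------------------------------------------------------
# genome size


def test_estimate_genome_size_simulation():
    ref, g = _simulate_graph([RepeatSpec(20, 2)], [5000, 4960], 21, 60, 5)
    est = estimate_genome_size(g)
    assert abs(est - len(ref)) <= 30  # ~G distinct k-mers on a circle


def test_estimate_genome_size_single_edge():
    assert estimate_genome_size(tiny_graph([("a", "b", 5)])) == 1


def test_estimate_genome_size_empty_graph():
    from tandemasm.graph_core import DeBruijnGraph
    with pytest.raises(GraphError):
        estimate_genome_size(DeBruijnGraph(4))


def test_genome_size_override_precedence():
    from tandemasm.io_formats import AssemblyConfig, Read
    from tandemasm.pipeline import assemble
    ref, _g = _simulate_graph([RepeatSpec(20, 2)], [700, 700], 21, 100, 6)
    sim = ReadSimParams(read_length=100, coverage=100, insert_mean=250,
                        insert_std=25, substitution_rate=0.0,
                        forward_only=True, seed=8)
    r1, r2 = simulate_reads(ref, sim)
    cfg = AssemblyConfig(k=21, single_strand_mode=True,
                         genome_size_override=123456)
    _res, info = assemble(r1 + r2, cfg)
    assert info.genome_size == 123456 and not info.genome_size_estimated
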