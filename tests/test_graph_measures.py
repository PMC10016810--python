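"""Graph measures against hand values and independent brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from disconnectome.graph_measures import (
    BinaryGraph,
    MEASURE_NAMES,
    binarize_to_density,
    binary_measure_suite,
    connectome_measures,
    global_efficiency_weighted,
    patient_measure_average,
    weighted_density,
    weighted_measure_suite,
)
from disconnectome.virtual_lesion import Connectome


def conn(w):
    return Connectome(weights=np.asarray(w, dtype=float))


def sym(n, rng):
    w = rng.random((n, n))
    w = np.triu(w, 1)
    return conn(w + w.T)


class TestWeightedDensity:
    def test_uniform_weights_saturate(self):
        w = np.ones((4, 4)) - np.eye(4)
        assert weighted_density(conn(0.3 * w)) == pytest.approx(1.0)

    def test_zero_matrix_convention(self):
        assert weighted_density(conn(np.zeros((3, 3)))) == 0.0

    def test_three_node_hand_value(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.2
        w[0, 2] = w[2, 0] = 0.1
        assert weighted_density(conn(w)) == pytest.approx((1 + 0.5 + 0) / 3)


class TestBinarize:
    def test_k3_keeps_single_strongest_edge(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.1
        b = binarize_to_density(conn(w), 1 / 3)
        assert b.n_edges == 1
        assert b.adjacency[0, 1] == 1

    def test_full_and_empty_targets(self):
        rng = np.random.default_rng(0)
        c = sym(5, rng)
        assert binarize_to_density(c, 1.0).n_edges == 10
        assert binarize_to_density(c, 0.0).n_edges == 0

    def test_zero_weight_pairs_never_become_edges(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        b = binarize_to_density(conn(w), 1.0)
        assert b.n_edges == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_density_matches_target_within_one_edge(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        c = sym(n, rng)  # continuous weights: distinct with prob 1
        m = n * (n - 1) / 2
        target = rng.uniform(0.1, 0.9)
        b = binarize_to_density(c, target)
        assert abs(b.n_edges / m - target) <= 1 / m + 1e-12


class TestBinarySuiteHandValues:
    def test_triangle(self):
        b = BinaryGraph(np.ones((3, 3), dtype=int) - np.eye(3, dtype=int))
        m = binary_measure_suite(b)
        assert m["density"] == pytest.approx(1.0)
        assert m["transitivity"] == pytest.approx(1.0)
        assert m["clustering_coef_mean"] == pytest.approx(1.0)
        assert m["betweenness_centrality_mean"] == 0.0

    def test_path_of_three(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        m = binary_measure_suite(BinaryGraph(a))
        assert m["density"] == pytest.approx(2 / 3)
        assert m["transitivity"] == 0.0
        assert m["betweenness_centrality_median"] == 0.0
        assert m["betweenness_centrality_mean"] == pytest.approx(1 / 3)

    def test_star_flow_coefficient(self):
        a = np.zeros((5, 5), dtype=int)
        a[0, 1:] = 1
        a[1:, 0] = 1
        m = binary_measure_suite(BinaryGraph(a))
        # centre routes every leaf pair (flow 1); leaves have degree 1 (flow 0)
        assert m["flow_coef_mean"] == pytest.approx(1 / 5)

    def test_empty_graph_conventions(self):
        m = binary_measure_suite(BinaryGraph(np.zeros((4, 4), dtype=int)))
        assert m["density"] == 0.0
        assert m["modularity"] == 0.0
        assert m["degree_median"] == 0.0


class TestWeightedSuiteHandValues:
    def test_disconnected_algebraic_connectivity_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        m = weighted_measure_suite(conn(w))
        assert m["algebraic_connectivity"] <= 1e-9

    def test_complete_k4(self):
        w = 1.0 * (np.ones((4, 4)) - np.eye(4))
        m = weighted_measure_suite(conn(w))
        assert m["algebraic_connectivity"] == pytest.approx(4.0)
        assert m["global_efficiency_w"] == pytest.approx(1.0)

    def test_participation_hand_values(self):
        # two 2-cliques joined weakly: with modules {0,1} and {2,3},
        # node 0's strength sits entirely in its own module -> ~0
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        m = weighted_measure_suite(conn(w))
        assert m["participation_coef_w_mean"] == pytest.approx(0.0)
        # node with strength split 50/50 across two modules -> 1 - 2*(1/2)^2
        frac = np.array([0.5, 0.5])
        assert 1 - (frac**2).sum() == pytest.approx(0.5)

    def test_quasi_idempotence_undefined_flagged(self):
        w = 1.0 * (np.ones((4, 4)) - np.eye(4))  # all strengths equal
        m = weighted_measure_suite(conn(w))
        assert np.isnan(m["quasi_idempotence"])


class TestPatientAverage:
    def test_mean_of_constants(self):
        mv = {k: 0.5 for k in MEASURE_NAMES}
        means, counts = patient_measure_average([dict(mv)] * 60)
        assert means == mv
        assert all(c == 60 for c in counts.values())

    def test_two_point_mean(self):
        a = {"density": 0.0}
        b = {"density": 1.0}
        means, _ = patient_measure_average([a, b])
        assert means["density"] == pytest.approx(0.5)

    def test_missing_values_pairwise(self):
        vs = [{"q": 1.0}, {"q": np.nan}, {"q": 3.0}]
        means, counts = patient_measure_average(vs)
        assert means["q"] == pytest.approx(2.0)
        assert counts["q"] == 2


# ---------------------------------------------------------------------------
# brute-force oracle suite on all connected graphs with <= 6 nodes


def atlas_graphs(max_nodes=6):
    for g in nx.graph_atlas_g()[1:]:
        if g.number_of_nodes() > max_nodes:
            break
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            yield g


def brute_betweenness(g):
    """Betweenness by exhaustive simple-path enumeration."""
    nodes = sorted(g.nodes)
    bc = {v: 0.0 for v in nodes}

    def simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                yield path
                continue
            for u in g[v]:
                if u not in path:
                    stack.append((u, path + [u]))

    for s, t in itertools.combinations(nodes, 2):
        paths = list(simple_paths(s, t))
        if not paths:
            continue
        d = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == d]
        for v in nodes:
            if v in (s, t):
                continue
            frac = sum(v in p for p in shortest) / len(shortest)
            bc[v] += frac
    return np.array([bc[v] for v in nodes])


def brute_transitivity(g):
    nodes = sorted(g.nodes)
    triangles = sum(
        1
        for a, b, c in itertools.combinations(nodes, 3)
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c)
    )
    triples = sum(
        1
        for v in nodes
        for a, b in itertools.combinations(sorted(g[v]), 2)
    )
    return 3 * triangles / triples if triples else 0.0


def brute_floyd_warshall(a):
    n = len(a)
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], d[i, k] + d[k, j])
    return d


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


@pytest.mark.parametrize(
    "g", list(atlas_graphs()), ids=lambda g: f"atlas_n{g.number_of_nodes()}e{g.number_of_edges()}"
)
def test_measures_match_bruteforce_oracles(g):
    """Every measure agrees with an independent brute-force computation
    on every connected graph with at most 6 nodes."""
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    b = BinaryGraph(a.astype(int))
    m = binary_measure_suite(b, seed=0)

    # betweenness by exhaustive path enumeration
    bc = brute_betweenness(g)
    assert m["betweenness_centrality_mean"] == pytest.approx(bc.mean(), abs=1e-10)
    assert m["betweenness_centrality_median"] == pytest.approx(
        np.median(bc), abs=1e-10
    )

    # transitivity by triangle counting
    assert m["transitivity"] == pytest.approx(brute_transitivity(g), abs=1e-12)

    # global efficiency by hand-rolled Floyd-Warshall (binary weights)
    c = conn(a)
    d = brute_floyd_warshall(a)
    n = len(a)
    inv = np.where((d > 0) & np.isfinite(d), 1.0 / np.where(d > 0, d, 1), 0.0)
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum() / (n * (n - 1))
    assert global_efficiency_weighted(c) == pytest.approx(eff, abs=1e-10)

    # eigenvector centrality satisfies the eigen equation
    w = weighted_measure_suite(c, seed=0)
    evals = np.linalg.eigvalsh(a)
    lam = evals[-1]
    # recompute the centrality vector exactly as the suite does
    from disconnectome.graph_measures import _eigenvector_centrality

    v = _eigenvector_centrality(a)
    assert np.linalg.norm(a @ v - lam * v) <= 1e-8

    # Louvain modularity never exceeds the best partition (exhaustive)
    best = max(
        nx.community.modularity(g, [set(blk) for blk in part])
        for part in set_partitions(nodes)
    )
    assert m["modularity"] <= best + 1e-9


def test_louvain_finds_optimum_on_two_clique_toy():
    g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    g.add_edge(0, 3)
    a = nx.to_numpy_array(g)
    m = binary_measure_suite(BinaryGraph(a.astype(int)), seed=0)
    best = max(
        nx.community.modularity(g, [set(blk) for blk in part])
        for part in set_partitions(sorted(g.nodes))
    )
    assert m["modularity"] == pytest.approx(best, abs=1e-12)


# ---------------------------------------------------------------------------
# structural properties


@pytest.mark.parametrize("seed", range(5))
def test_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    c = sym(7, rng)
    perm = rng.permutation(7)
    cp = conn(c.weights[np.ix_(perm, perm)])
    m1 = connectome_measures(c, seed=3)
    m2 = connectome_measures(cp, seed=3)
    for k in MEASURE_NAMES:
        if k in ("modularity", "modularity_w", "participation_coef_w_mean"):
            # Louvain restarts see relabelled nodes; allow partition noise
            assert m1[k] == pytest.approx(m2[k], abs=0.05)
        else:
            assert m1[k] == pytest.approx(m2[k], abs=1e-8), k


@pytest.mark.parametrize("scale", [0.25, 4.0])
def test_scale_behaviour(scale):
    rng = np.random.default_rng(2)
    c = sym(8, rng)
    cs = conn(scale * c.weights)
    assert weighted_density(cs) == pytest.approx(weighted_density(c))
    m1 = weighted_measure_suite(c, seed=1)
    m2 = weighted_measure_suite(cs, seed=1)
    for k in (
        "global_efficiency_w",
        "participation_coef_w_mean",
        "quasi_idempotence",
        "modularity_w",
    ):
        assert m2[k] == pytest.approx(m1[k], abs=1e-10), k
    assert m2["algebraic_connectivity"] == pytest.approx(
        scale * m1["algebraic_connectivity"]
    )
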