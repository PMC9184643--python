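"""Correlation graphs, synchrony summaries, efficiency, modules, phases."""

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from monnet.network import (
    BinaryGraph,
    CorrelationGraph,
    PhaseProfile,
    binarize,
    correlation_vs_distance,
    detect_modules,
    estimate_phase_boundaries,
    graph_efficiency,
    local_global_summary,
    pairwise_correlation,
)


def efficiency_oracle(A):
    """Brute-force efficiencies from all-pairs shortest paths."""
    n = A.shape[0]
    sp = floyd_warshall(A.astype(float), unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    e_glob = inv.sum() / (n * (n - 1)) if n > 1 else 0.0
    locs = []
    for v in range(n):
        nb = np.flatnonzero(A[v])
        if len(nb) < 2:
            locs.append(0.0)
            continue
        sub = A[np.ix_(nb, nb)]
        m = len(nb)
        spn = floyd_warshall(sub.astype(float), unweighted=True)
        with np.errstate(divide="ignore"):
            invn = 1.0 / spn
        invn[~np.isfinite(invn)] = 0.0
        np.fill_diagonal(invn, 0.0)
        locs.append(invn.sum() / (m * (m - 1)))
    return e_glob, float(np.mean(locs))


def two_cliques(k=4):
    A = np.zeros((2 * k, 2 * k))
    A[:k, :k] = 1.0
    A[k:, k:] = 1.0
    np.fill_diagonal(A, 0.0)
    return A


class TestPairwiseCorrelation:
    def test_identical_traces_r_one(self, rng):
        x = rng.random(100)
        G = pairwise_correlation(np.vstack([x, x]))
        assert G.C[0, 1] == pytest.approx(1.0)

    def test_negated_trace_r_minus_one(self, rng):
        x = rng.random(100)
        G = pairwise_correlation(np.vstack([x, -x]))
        assert G.C[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        X = rng.random((5, 100))
        G = pairwise_correlation(X)
        for i in range(5):
            for j in range(5):
                a, b = X[i] - X[i].mean(), X[j] - X[j].mean()
                r = (a @ b) / np.sqrt((a @ a) * (b @ b))
                assert abs(G.C[i, j] - r) < 1e-12

    def test_constant_trace_masked(self, rng):
        X = np.vstack([rng.random(50), np.full(50, 2.0), rng.random(50)])
        G = pairwise_correlation(X)
        assert not G.valid[1]
        assert np.isnan(G.C[1, 0]) and np.isnan(G.C[0, 1])

    def test_single_source_rejected(self):
        with pytest.raises(ValueError):
            pairwise_correlation(np.ones((1, 10)))


class TestLocalGlobalSummary:
    def test_uniform_matrix(self):
        C = np.full((4, 4), 0.3)
        np.fill_diagonal(C, 1.0)
        G = CorrelationGraph(C, membership=np.array([0, 0, 1, 1]))
        s = local_global_summary(G)
        assert s["local"] == pytest.approx(0.3)
        assert s["global"] == pytest.approx(0.3)
        assert s["overall"] == pytest.approx(0.3)

    def test_hand_arithmetic_two_spheroids(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.9  # within spheroid 0
        C[2, 3] = C[3, 2] = 0.8  # within spheroid 1
        for i in (0, 1):
            for j in (2, 3):
                C[i, j] = C[j, i] = 0.2
        G = CorrelationGraph(C, membership=np.array([0, 0, 1, 1]))
        s = local_global_summary(G)
        assert s["local"] == pytest.approx(0.85)
        assert s["global"] == pytest.approx(0.2)

    def test_single_spheroid_global_missing(self):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        s = local_global_summary(CorrelationGraph(C, membership=np.zeros(3, int)))
        assert np.isnan(s["global"]) and s["local"] == pytest.approx(0.5)

    def test_overall_is_pair_count_weighted_combination(self, rng):
        X = rng.random((8, 60))
        G = pairwise_correlation(X, membership=np.repeat([0, 1], 4))
        s = local_global_summary(G)
        nl, ng = s["n_local_pairs"], s["n_global_pairs"]
        combo = (s["local"] * nl + s["global"] * ng) / (nl + ng)
        assert s["overall"] == pytest.approx(combo)


class TestCorrelationVsDistance:
    def test_single_distance_single_bin(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        pos = np.array([[0, 0], [0, 0], [30, 0], [30, 0]], float)
        G = CorrelationGraph(C, membership=np.array([0, 0, 1, 1]), positions=pos)
        tab = correlation_vs_distance(G, bin_width=50.0)
        assert len(tab) == 1 and tab.n_pairs.iloc[0] == 4

    def test_hand_built_three_pairs(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.9
        C[0, 2] = C[2, 0] = 0.5
        C[1, 2] = C[2, 1] = 0.1
        pos = np.array([[0, 0], [10, 0], [95, 0]], float)
        G = CorrelationGraph(C, membership=np.array([0, 1, 2]), positions=pos)
        tab = correlation_vs_distance(G, bin_width=50.0).set_index("distance")
        assert tab.loc[25.0, "mean_r"] == pytest.approx(0.9)  # d=10
        assert tab.loc[75.0, "mean_r"] == pytest.approx(0.3)  # d=85 and 95
        assert tab.loc[75.0, "n_pairs"] == 2

    def test_no_across_pairs_empty(self):
        C = np.full((3, 3), 0.5)
        np.fill_diagonal(C, 1.0)
        G = CorrelationGraph(C, membership=np.zeros(3, int),
                             positions=np.zeros((3, 2)))
        assert len(correlation_vs_distance(G)) == 0


class TestBinarize:
    def test_threshold_one_only_perfect_pairs(self, rng):
        x = rng.random(50)
        X = np.vstack([x, x, rng.random(50)])
        B = binarize(pairwise_correlation(X), 1.0)
        assert B.adjacency[0, 1] and not B.adjacency[0, 2]

    def test_uniform_above_threshold_complete(self):
        C = np.full((5, 5), 0.9)
        np.fill_diagonal(C, 1.0)
        B = binarize(CorrelationGraph(C), 0.8)
        assert B.adjacency.sum() == 5 * 4

    def test_mixed_matrix_enumeration(self):
        C = np.eye(3)
        C[0, 1] = C[1, 0] = 0.85
        C[0, 2] = C[2, 0] = 0.8  # boundary: included (>=)
        C[1, 2] = C[2, 1] = 0.79
        B = binarize(CorrelationGraph(C), 0.8)
        expected = {(0, 1), (0, 2)}
        got = {tuple(sorted(e)) for e in zip(*np.nonzero(np.triu(B.adjacency)))}
        assert got == expected


class TestGraphEfficiency:
    def test_complete_graph(self):
        A = np.ones((5, 5)) - np.eye(5)
        assert graph_efficiency(BinaryGraph(A.astype(bool), 0.8)) == (1.0, 1.0)

    def test_three_node_path(self):
        A = np.zeros((3, 3), bool)
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = True
        eg, _ = graph_efficiency(BinaryGraph(A, 0.8))
        assert eg == pytest.approx(5 / 6)

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(4, 31)
            A = rng.random((n, n)) < 0.2
            A = np.triu(A, 1)
            A = A | A.T
            eg, el = graph_efficiency(BinaryGraph(A, 0.8))
            oeg, oel = efficiency_oracle(A)
            assert eg == pytest.approx(oeg, abs=1e-12)
            assert el == pytest.approx(oel, abs=1e-12)

    def test_monotone_under_edge_addition(self, rng):
        n = 12
        A = np.zeros((n, n), bool)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        order = rng.permutation(len(pairs))
        prev = 0.0
        for i, j in (pairs[k] for k in order[:30]):
            A[i, j] = A[j, i] = True
            eg, _ = graph_efficiency(BinaryGraph(A.copy(), 0.8))
            assert eg >= prev - 1e-12
            prev = eg


class TestDetectModules:
    def test_two_disconnected_cliques(self):
        part = detect_modules(two_cliques(4), threshold=0.5, seed=0)
        assert part.n_modules == 2
        assert part.modularity == pytest.approx(0.5)

    def test_complete_graph_single_module(self):
        A = np.ones((6, 6)) - np.eye(6)
        part = detect_modules(A, threshold=0.5, seed=0)
        assert part.n_modules == 1

    def test_planted_four_cliques_recovered(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            A = np.zeros((32, 32))
            for b in range(4):
                A[b * 8 : (b + 1) * 8, b * 8 : (b + 1) * 8] = 1.0
            inter = rng.random((32, 32)) < 0.05
            A = np.maximum(A, np.triu(inter, 1) + np.triu(inter, 1).T)
            np.fill_diagonal(A, 0.0)
            part = detect_modules(A, threshold=0.5, seed=seed)
            hits += part.n_modules == 4
        assert hits >= 0.95 * 50

    def test_disconnected_components_never_merged(self):
        A = two_cliques(5)
        for seed in range(10):
            part = detect_modules(A, threshold=0.5, resolution=0.3, seed=seed)
            labels = part.labels
            assert len(set(labels[:5]) & set(labels[5:])) == 0

    def test_isolated_nodes_singletons(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        part = detect_modules(A, threshold=0.5, seed=0)
        assert part.n_modules == 3  # {0,1}, {2}, {3}


class TestPhaseBoundaries:
    def test_triangular_profile_half_peak(self):
        prof = PhaseProfile([10, 20, 30], [0.0, 0.8, 0.0])
        assert estimate_phase_boundaries(prof) == (15.0, 25.0)

    def test_monotone_rising_upper_open(self):
        prof = PhaseProfile([10, 20, 30], [0.0, 0.4, 0.8])
        with pytest.warns(UserWarning, match="upper"):
            low, high = estimate_phase_boundaries(prof)
        # half-peak (0.4) is attained exactly at DIV 20 on the rising flank
        assert high is None and low == pytest.approx(20.0)

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError, match="no peak"):
            estimate_phase_boundaries(PhaseProfile([1, 2, 3], [0.5, 0.5, 0.5]))

    def test_interpolation_on_asymmetric_profile(self):
        prof = PhaseProfile([0, 10, 20, 40], [0.0, 1.0, 0.6, 0.0])
        low, high = estimate_phase_boundaries(prof)
        assert low == pytest.approx(5.0)
        assert high == pytest.approx(20 + 20 * 0.1 / 0.6)
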