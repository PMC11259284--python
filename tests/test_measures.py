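import itertools

import numpy as np
import pytest

import plastinet as pn
from plastinet.connectivity import empty_connectivity
from plastinet.dynamics import SpikeRaster


def _raster(trains: list[np.ndarray]) -> SpikeRaster:
    neuron = np.concatenate(
        [np.full(len(t), i, dtype=np.int32) for i, t in enumerate(trains)]
    )
    time = np.concatenate([np.asarray(t, dtype=float) for t in trains])
    return SpikeRaster(neuron=neuron, time=time)


class TestOrderParameter:
    def test_identical_trains_give_unity(self):
        train = np.arange(0.0, 10_000.0, 250.0)
        r = _raster([train.copy() for _ in range(5)])
        R = pn.order_parameter(r, 5, t=9000.0, window=4000.0)
        assert R == pytest.approx(1.0, abs=1e-9)

    def test_splay_state_gives_zero(self):
        # N staggered trains: phases are N-th roots of unity at all times
        N = 8
        period = 400.0
        trains = [np.arange(k * period / N, 20_000.0, period) for k in range(N)]
        R = pn.order_parameter(_raster(trains), N, t=18_000.0, window=8000.0)
        assert R == pytest.approx(0.0, abs=1e-9)

    def test_antiphase_pair_gives_zero(self):
        a = np.arange(0.0, 20_000.0, 100.0)
        b = np.arange(50.0, 20_000.0, 100.0)
        R = pn.order_parameter(_raster([a, b]), 2, t=15_000.0, window=5000.0)
        assert R == pytest.approx(0.0, abs=1e-9)

    def test_neurons_without_phase_are_excluded(self):
        train = np.arange(0.0, 10_000.0, 250.0)
        silent = np.array([])
        R = pn.order_parameter(_raster([train, train, silent]), 3,
                               t=9000.0, window=4000.0)
        assert R == pytest.approx(1.0, abs=1e-9)

    def test_quadrature_step_converged(self):
        rng = np.random.default_rng(0)
        trains = [np.sort(rng.uniform(0, 20_000.0, 80)) for _ in range(20)]
        r = _raster(trains)
        R1 = pn.order_parameter(r, 20, t=15_000.0, window=5000.0, sample_step=1.0)
        R2 = pn.order_parameter(r, 20, t=15_000.0, window=5000.0, sample_step=0.5)
        assert abs(R1 - R2) < 1e-3


class TestRateAndCV:
    def test_two_point_population(self):
        trains = [np.arange(0, 10_000.0, 1000.0 / 3.0),
                  np.arange(0, 10_000.0, 200.0)]
        mean, cv, rates = pn.rate_and_cv(_raster(trains), 10_000.0, 2)
        assert rates[0] == pytest.approx(3.0) and rates[1] == pytest.approx(5.0)
        assert mean == pytest.approx(4.0)
        assert cv == pytest.approx(0.25)

    def test_equal_rates_lock_cv_to_zero(self):
        trains = [np.arange(0, 10_000.0, 250.0) + k for k in range(4)]
        _, cv, _ = pn.rate_and_cv(_raster(trains), 10_000.0, 4)
        assert cv == 0.0

    def test_empty_raster_flags_undefined_cv(self):
        mean, cv, _ = pn.rate_and_cv(_raster([np.array([])]), 1000.0, 1)
        assert mean == 0.0 and np.isnan(cv)


class TestMeanWeights:
    def test_uniform_unit_weights(self):
        conn = empty_connectivity(4)
        conn.adjacency[1, 0] = conn.adjacency[2, 3] = 1
        conn.weights[1, 0] = conn.weights[2, 3] = 1.0
        mean, W_i = pn.mean_weights(conn)
        assert mean == 1.0

    def test_single_contact(self):
        conn = empty_connectivity(3)
        conn.adjacency[1, 0] = 1
        conn.weights[1, 0] = 0.3
        mean, W_i = pn.mean_weights(conn)
        assert W_i[1] == pytest.approx(0.3)
        assert np.isnan(W_i[0]) and np.isnan(W_i[2])
        assert mean == pytest.approx(0.3)

    def test_matches_bruteforce_double_sum(self, rng):
        N = 12
        conn = empty_connectivity(N)
        mask = (rng.random((N, N)) < 0.4) & ~np.eye(N, dtype=bool)
        conn.adjacency[mask] = 1
        conn.weights[mask] = rng.random(int(mask.sum()))
        mean, W_i = pn.mean_weights(conn)
        # loop-free oracle straight from the defining double sum
        vals = []
        for i in range(N):
            num = sum(conn.weights[i, j] for j in range(N) if conn.adjacency[i, j])
            den = sum(conn.adjacency[i, j] for j in range(N))
            if den:
                vals.append(num / den)
                assert W_i[i] == pytest.approx(num / den, rel=1e-12)
        assert mean == pytest.approx(np.mean(vals), rel=1e-12)


class TestDegreeDensities:
    def test_empty_graph(self):
        b_in, b_out, beta = pn.node_degree_densities(empty_connectivity(5))
        assert np.all(b_in == 0) and np.all(b_out == 0) and beta == 0

    def test_all_to_all(self):
        conn = empty_connectivity(6)
        conn.adjacency[~np.eye(6, dtype=bool)] = 1
        b_in, b_out, beta = pn.node_degree_densities(conn)
        assert np.allclose(b_in, 5 / 6) and np.allclose(b_out, 5 / 6)
        assert beta == 1.0

    def test_handshake_identity(self, rng):
        conn = empty_connectivity(15)
        mask = (rng.random((15, 15)) < 0.3) & ~np.eye(15, dtype=bool)
        conn.adjacency[mask] = 1
        b_in, b_out, _ = pn.node_degree_densities(conn)
        assert b_in.mean() == pytest.approx(b_out.mean(), rel=1e-12)


def _assortativity_bruteforce(adj):
    """Edge-by-edge Pearson coefficients from the defining sums."""
    N = adj.shape[0]
    indeg = adj.sum(axis=1)
    outdeg = adj.sum(axis=0)
    edges = [(j, i) for i in range(N) for j in range(N) if adj[i, j]]
    E = len(edges)
    deg = {"in": indeg, "out": outdeg}
    out = {}
    for eps in ("in", "out"):
        for ups in ("in", "out"):
            U = np.array([deg[eps][j] for j, i in edges], dtype=float)
            V = np.array([deg[ups][i] for j, i in edges], dtype=float)
            sU, sV = U.std(), V.std()
            if sU == 0 or sV == 0:
                out[(eps, ups)] = float("nan")
            else:
                out[(eps, ups)] = float(
                    np.sum((U - U.mean()) * (V - V.mean())) / (E * sU * sV)
                )
    return out


class TestAssortativity:
    def test_large_random_graph_is_non_assortative(self, rng):
        N = 300
        conn = empty_connectivity(N)
        mask = (rng.random((N, N)) < 0.05) & ~np.eye(N, dtype=bool)
        conn.adjacency[mask] = 1
        res = pn.degree_assortativity(conn)
        for v in res.rho.values():
            assert abs(v) < 0.05

    def test_cycle_has_undefined_coefficients(self):
        conn = empty_connectivity(3)
        for j, i in [(0, 1), (1, 2), (2, 0)]:
            conn.adjacency[i, j] = 1
        res = pn.degree_assortativity(conn)
        assert all(np.isnan(v) for v in res.rho.values())

    def test_toy_digraph_matches_bruteforce(self):
        # nodes 0..3, edges 0->1, 2->1, 1->3, 0->3
        conn = empty_connectivity(4)
        for j, i in [(0, 1), (2, 1), (1, 3), (0, 3)]:
            conn.adjacency[i, j] = 1
        res = pn.degree_assortativity(conn)
        brute = _assortativity_bruteforce(conn.adjacency)
        for key in brute:
            if np.isnan(brute[key]):
                assert np.isnan(res.rho[key])
            else:
                assert res.rho[key] == pytest.approx(brute[key], abs=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_small_random_digraphs_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(3, 7))
        conn = empty_connectivity(N)
        mask = (rng.random((N, N)) < 0.5) & ~np.eye(N, dtype=bool)
        conn.adjacency[mask] = 1
        if conn.n_contacts < 2:
            return
        res = pn.degree_assortativity(conn)
        brute = _assortativity_bruteforce(conn.adjacency)
        for key in brute:
            same_nan = np.isnan(brute[key]) and np.isnan(res.rho[key])
            assert same_nan or res.rho[key] == pytest.approx(brute[key], abs=1e-12)

    def test_matches_networkx_pearson_coefficient(self, rng):
        nx = pytest.importorskip("networkx")
        N = 40
        conn = empty_connectivity(N)
        mask = (rng.random((N, N)) < 0.2) & ~np.eye(N, dtype=bool)
        conn.adjacency[mask] = 1
        G = nx.DiGraph()
        G.add_nodes_from(range(N))
        post, pre = np.nonzero(conn.adjacency)
        G.add_edges_from(zip(pre.tolist(), post.tolist()))
        res = pn.degree_assortativity(conn)
        for eps, ups in itertools.product(("in", "out"), repeat=2):
            ref = nx.degree_pearson_correlation_coefficient(G, x=eps, y=ups)
            assert res.rho[(eps, ups)] == pytest.approx(ref, abs=1e-10)


class TestDegreeFrequencyCorrelation:
    def test_shuffled_degrees_are_uncorrelated(self, rng):
        N = 200
        conn = empty_connectivity(N)
        mask = (rng.random((N, N)) < 0.1) & ~np.eye(N, dtype=bool)
        conn.adjacency[mask] = 1
        f = rng.normal(3.0, 0.5, N)
        c_in, c_out = pn.degree_frequency_correlation(conn, f)
        assert abs(c_in) < 0.15 and abs(c_out) < 0.15

    def test_exact_linear_dependence(self):
        N = 20
        conn = empty_connectivity(N)
        f = np.linspace(2.0, 4.0, N)
        # in-degree exactly linear (decreasing) in the rate
        for i in range(N):
            for j in range(N - 1 - i):
                conn.adjacency[i, (i + 1 + j) % N] = 1
        c_in, _ = pn.degree_frequency_correlation(conn, f)
        assert c_in == pytest.approx(-1.0, abs=1e-9)


class TestConvergenceTest:
    def test_constant_series_converges_at_n_min(self):
        ok, n = pn.convergence_test([0.5] * 10, [4.0] * 10, n_min=3, n_max=31)
        assert ok and n == 3

    def test_alternating_series_never_converges(self):
        W = [0.5, 0.6] * 16
        f = [4.0] * 32
        ok, n = pn.convergence_test(W, f, n_min=2, n_max=31)
        assert not ok and n == 31

    def test_zero_series_treated_as_converged(self):
        ok, _ = pn.convergence_test([0.0] * 6, [0.0] * 6, n_min=2, n_max=31)
        assert ok


class TestWeightFraction:
    def test_counts_low_mode(self):
        conn = empty_connectivity(4)
        conn.adjacency[0, 1] = conn.adjacency[1, 2] = conn.adjacency[2, 3] = 1
        conn.weights[0, 1] = 0.05
        conn.weights[1, 2] = 0.5
        conn.weights[2, 3] = 0.95
        assert pn.weight_fraction_below(conn, 0.1) == pytest.approx(1 / 3)
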