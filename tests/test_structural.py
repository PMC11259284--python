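import numpy as np
import pytest

import plastinet as pn
from plastinet.connectivity import empty_connectivity
from plastinet.structural import RateEstimator, StructuralEvent


@pytest.fixture()
def sp():
    return pn.SPParams()


class TestLogistic:
    def test_midpoint(self):
        assert pn.logistic(4.5, 4.5, 0.2) == 0.5

    def test_floor_probability_at_target(self, sp):
        # the slope nu is defined so the addition factor equals the
        # floor probability when the neuron sits at the target rate
        assert pn.logistic(sp.f_T, sp.f_minus, -sp.nu) == pytest.approx(
            sp.p_tilde_T, rel=1e-9
        )
        assert pn.logistic(sp.f_T, sp.f_plus, sp.nu) == pytest.approx(
            sp.p_tilde_T, rel=1e-9
        )

    def test_saturation_one_delta_f_below_target(self, sp):
        assert pn.logistic(sp.f_T - sp.delta_f, sp.f_minus, -sp.nu) == pytest.approx(
            1.0 - sp.p_tilde_T, rel=1e-9
        )

    def test_derived_constants(self, sp):
        assert sp.f_minus == 4.0 and sp.f_plus == 5.0
        assert sp.nu == pytest.approx(1.0 / (2.0 * np.log(99.0)), rel=1e-12)

    def test_monotonicity(self):
        f = np.linspace(0, 10, 101)
        up = pn.logistic(f, 4.5, 0.2)
        down = pn.logistic(f, 4.5, -0.2)
        assert np.all(np.diff(up) > 0) and np.all(np.diff(down) < 0)


class TestAdditionProbability:
    def test_saturates_at_homeostatic_maximum(self, sp):
        assert pn.p_add(0.0, 0.0, sp) == pytest.approx(sp.P_h, rel=1e-3)

    def test_trickle_at_target_rate(self, sp):
        assert pn.p_add(sp.f_T, 0.0, sp) == pytest.approx(1e-4, rel=1e-6)

    def test_reference_curve_point(self):
        # P_h=1, f=4 Hz (= f_minus, logistic midpoint), l=0.1, l0=0.5
        p = pn.SPParams(P_h=1.0)
        assert pn.p_add(4.0, 0.1, p) == pytest.approx(0.5 * np.exp(-0.2), rel=1e-9)

    def test_monotone_decreasing_in_rate_and_distance(self, sp):
        f = np.linspace(0, 10, 50)
        assert np.all(np.diff(pn.p_add(f, 0.1, sp)) <= 0)
        l = np.linspace(0, 1.5, 50)
        assert np.all(np.diff(pn.p_add(3.0, l, sp)) < 0)


class TestPruningProbability:
    def test_zero_weight_at_target_rate(self):
        p = pn.SPParams(P_w=0.3)
        expected = 0.3 + 0.01 * p.p_tilde_T
        assert pn.p_prune(p.f_T, 0.0, p) == pytest.approx(expected, rel=1e-6)

    def test_strong_weight_suppresses_weight_term(self):
        p = pn.SPParams(P_w=1.0)
        assert pn.p_prune(p.f_T, 1.0, p) == pytest.approx(
            p.P_h * p.p_tilde_T, rel=1e-6
        )

    def test_homeostatic_saturation_at_high_rate(self, sp):
        assert pn.p_prune(1e3, 0.5, sp) == pytest.approx(sp.P_h, rel=1e-9)

    def test_monotone_hazards(self):
        p = pn.SPParams(P_w=0.5)
        w = np.linspace(0, 0.01, 50)  # strictly decreasing near w ~ w_min
        assert np.all(np.diff(pn.p_prune(4.5, w, p)) < 0)
        f = np.linspace(0, 10, 50)
        assert np.all(np.diff(pn.p_prune(f, 0.5, p)) >= 0)

    def test_cap_at_one(self):
        p = pn.SPParams(P_w=1.0, P_h=0.01)
        assert pn.p_prune(100.0, 0.0, p) <= 1.0


class TestRateEstimator:
    def test_pure_decay_without_spikes(self):
        est = RateEstimator(f_hat=np.array([4.0]), tau_slow=1000.0)
        out = pn.update_rate_estimate(est, [np.array([])], 500.0)
        assert out.f_hat[0] == pytest.approx(4.0 * np.exp(-0.5), rel=1e-12)

    def test_single_spike_jump_size(self):
        tau = 1.8e6  # 30 minutes in ms
        est = RateEstimator.zeros(1, tau)
        out = pn.update_rate_estimate(est, [np.array([1000.0])], 1000.0)
        assert out.f_hat[0] == pytest.approx(1000.0 / tau, rel=1e-12)

    def test_steady_state_tracks_stationary_train(self):
        # 4.5 Hz periodic train over many filter constants
        # per-spike jump is 1000/tau Hz, so tau >> period keeps the
        # sawtooth ripple small relative to the mean
        tau = 30_000.0
        period = 1000.0 / 4.5
        total = 600_000.0
        chunk = 10_000.0
        train = np.arange(0.0, total, period)
        est = RateEstimator.zeros(1, tau)
        for k in range(int(total / chunk)):
            lo, hi = k * chunk, (k + 1) * chunk
            spikes = train[(train >= lo) & (train < hi)] - lo
            est = pn.update_rate_estimate(est, [spikes], chunk)
        assert est.f_hat[0] == pytest.approx(4.5, rel=0.1)

    def test_rejects_out_of_interval_spikes(self):
        est = RateEstimator.zeros(1, 1000.0)
        with pytest.raises(ValueError):
            pn.update_rate_estimate(est, [np.array([2000.0])], 1000.0)


def _frozen_setup(N=6, seed=0):
    geometry = pn.place_neurons(int(np.sqrt(N)) if int(np.sqrt(N)) ** 2 == N else 3,
                                jitter_scale=0.0)
    return geometry


class TestStructuralUpdate:
    def test_growth_phase_expected_additions(self):
        # empty network, rates far below target: every absent pair adds
        # with probability P_h * exp(-l / l0)
        geometry = pn.place_neurons(6, jitter_scale=0.0)
        N = geometry.N
        sp = pn.SPParams(P_h=0.2)
        rates = RateEstimator(f_hat=np.zeros(N), tau_slow=sp.tau_slow)
        off = ~np.eye(N, dtype=bool)
        expected = (sp.P_h * np.exp(-geometry.distance / sp.l0))[off].sum()
        var = (
            (sp.P_h * np.exp(-geometry.distance / sp.l0))
            * (1 - sp.P_h * np.exp(-geometry.distance / sp.l0))
        )[off].sum()
        counts = []
        for s in range(30):
            conn = empty_connectivity(N)
            pn.sp_update(conn, geometry, rates, sp, regime="stdp_sp", rng_seed=s)
            counts.append(conn.n_contacts)
        se = np.sqrt(var / 30)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_high_rate_blocks_additions_and_prunes_homeostatically(self):
        geometry = pn.place_neurons(4, jitter_scale=0.0)
        N = geometry.N
        sp = pn.SPParams(P_h=0.5, P_w=0.0)
        rates = RateEstimator(f_hat=np.full(N, 50.0), tau_slow=sp.tau_slow)
        conn = empty_connectivity(N)
        off = ~np.eye(N, dtype=bool)
        conn.adjacency[off] = 1
        conn.weights[off] = 0.5
        n0 = conn.n_contacts
        removed = []
        for s in range(20):
            c = conn.copy()
            pn.sp_update(c, geometry, rates, sp, regime="stdp_sp", rng_seed=s)
            removed.append(n0 - c.n_contacts)
            assert c.n_contacts <= n0  # no additions at saturating rate
        se = np.sqrt(n0 * sp.P_h * (1 - sp.P_h) / 20)
        assert abs(np.mean(removed) - sp.P_h * n0) < 3 * se

    def test_update_is_synchronous_and_exclusive(self):
        # decided from the pre-update snapshot: an entry changes by at
        # most one, and a newborn contact is never pruned in the same
        # update
        geometry = pn.place_neurons(5, jitter_scale=0.0)
        N = geometry.N
        sp = pn.SPParams(P_h=1.0, P_w=1.0, w_min=10.0)  # extreme hazards
        rates = RateEstimator(f_hat=np.full(N, 4.5), tau_slow=sp.tau_slow)
        conn = empty_connectivity(N)
        rng = np.random.default_rng(3)
        mask = (rng.random((N, N)) < 0.5) & ~np.eye(N, dtype=bool)
        conn.adjacency[mask] = 1
        conn.weights[mask] = 0.0  # prune hazard ~ 1 for live contacts
        before = conn.adjacency.copy()
        pn.sp_update(conn, geometry, rates, sp, regime="stdp_sp", rng_seed=4,
                     iteration=5)
        diff = conn.adjacency.astype(int) - before.astype(int)
        assert np.abs(diff).max() <= 1
        born = diff == 1
        assert np.all(conn.birth_time[born] == 5)

    def test_new_weight_support_by_regime(self):
        geometry = pn.place_neurons(5, jitter_scale=0.0)
        N = geometry.N
        sp = pn.SPParams(P_h=1.0)
        rates = RateEstimator(f_hat=np.zeros(N), tau_slow=sp.tau_slow)
        for regime, hi in (("hsp_only", 1.0), ("stdp_sp", 0.2), ("stdp_hsp", 0.2)):
            conn = empty_connectivity(N)
            pn.sp_update(conn, geometry, rates, sp, regime=regime, rng_seed=9)
            w = conn.weights[conn.adjacency == 1]
            assert w.size > 30
            assert w.max() <= hi and w.min() >= 0.0
            assert w.max() > 0.5 * hi  # actually fills the support

    def test_hsp_regimes_ignore_weight_dependent_pruning(self):
        # P_w is configured but must not act under stdp_hsp
        geometry = pn.place_neurons(4, jitter_scale=0.0)
        N = geometry.N
        sp = pn.SPParams(P_h=0.0, P_w=1.0)
        rates = RateEstimator(f_hat=np.full(N, 4.5), tau_slow=sp.tau_slow)
        conn = empty_connectivity(N)
        off = ~np.eye(N, dtype=bool)
        conn.adjacency[off] = 1  # all weights 0 -> P_w would prune all
        pn.sp_update(conn, geometry, rates, sp, regime="stdp_hsp", rng_seed=1)
        assert conn.n_contacts == int(off.sum())

    def test_rejects_size_mismatch(self):
        geometry = pn.place_neurons(4, jitter_scale=0.0)
        rates = RateEstimator.zeros(7, 1e6)
        with pytest.raises(ValueError):
            pn.sp_update(empty_connectivity(16), geometry, rates, pn.SPParams())


class TestBirthDeathEquilibrium:
    def test_occupancy_matches_detailed_balance(self):
        # frozen rate and weight: long-run occupancy of a single ordered
        # pair equals p_add / (p_add + p_prune)
        geometry = pn.fixture_network("two_neuron").geometry
        sp = pn.SPParams(P_h=0.5, P_w=0.1, w_min=1.0)
        f = 4.0
        w_birth = 0.1
        pa = float(pn.p_add(f, geometry.distance[0, 1], sp))
        pp = float(pn.p_prune(f, w_birth, sp))
        rates = RateEstimator(f_hat=np.full(2, f), tau_slow=sp.tau_slow)
        conn = empty_connectivity(2)
        rng = np.random.default_rng(42)
        n_updates = 20_000
        occupied = 0
        for it in range(n_updates):
            pn.sp_update(conn, geometry, rates, sp, regime="stdp_sp",
                         rng_seed=rng, iteration=it)
            conn.weights[conn.adjacency == 1] = w_birth  # freeze the weight
            occupied += int(conn.adjacency[1, 0])
        target = pa / (pa + pp)
        # the chain mixes fast (hazards ~0.2); treat samples as weakly
        # dependent with an inflation factor on the binomial SE
        se = np.sqrt(target * (1 - target) / n_updates) * 4
        assert abs(occupied / n_updates - target) < 3 * se

    def test_lifetimes_are_geometric(self):
        geometry = pn.fixture_network("two_neuron").geometry
        sp = pn.SPParams(P_h=0.5, P_w=0.3, w_min=1.0)
        f = 4.0
        w_birth = 0.2
        pp = float(pn.p_prune(f, w_birth, sp))
        rates = RateEstimator(f_hat=np.full(2, f), tau_slow=sp.tau_slow)
        conn = empty_connectivity(2)
        events: list[StructuralEvent] = []
        rng = np.random.default_rng(7)
        for it in range(20_000):
            pn.sp_update(conn, geometry, rates, sp, regime="stdp_sp",
                         rng_seed=rng, iteration=it, event_log=events)
            conn.weights[conn.adjacency == 1] = w_birth
        lifetimes = np.array(
            [e.lifetime for e in events if e.event == "prune"], dtype=float
        )
        assert lifetimes.size > 300
        mean_life = lifetimes.mean()
        se = lifetimes.std() / np.sqrt(lifetimes.size)
        assert abs(mean_life - 1.0 / pp) < 3 * se
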