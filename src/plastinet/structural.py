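"""Stochastic structural plasticity: a birth-death process on contacts.

Between structural updates the graph is frozen and the fast dynamics
(spiking, STDP) relax to a meta-steady state.  A structural update then
visits every ordered neuron pair once, synchronously, deciding from the
pre-update snapshot:

* an absent contact ``j -> i`` is created with probability
  ``P_add = P_h * G(f_i, f_minus, -nu) * exp(-l_ij / l0)`` — homeostatic
  (more likely the further the postsynaptic rate sits below target) and
  local (exponentially suppressed with distance);
* a live contact is removed with probability
  ``P_prn = P_w * exp(-w_ij / w_min) + P_h * G(f_i, f_plus, nu)`` —
  weight-dependent pruning of weak contacts plus homeostatic pruning of
  inputs to over-target neurons.

The postsynaptic rate entering these hazards is the slow low-pass
filtered rate of :class:`RateEstimator`, not the instantaneous rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityState
from .geometry import NetworkGeometry
from .params import SPParams


def logistic(omega, omega0: float, nu: float):
    """Logistic factor ``1 / (1 + exp(-(omega - omega0) / nu))``.

    Monotone increasing in ``omega`` for ``nu > 0``, decreasing for
    ``nu < 0``.  Accepts scalars or arrays.
    """
    if nu == 0:
        raise ValueError("nu must be non-zero")
    return 1.0 / (1.0 + np.exp(-(np.asarray(omega, dtype=float) - omega0) / nu))


def p_add(f_i, l_ij, params: SPParams):
    """Contact-addition probability for postsynaptic rate and distance."""
    return (
        params.P_h
        * logistic(f_i, params.f_minus, -params.nu)
        * np.exp(-np.asarray(l_ij, dtype=float) / params.l0)
    )


def p_prune(f_i, w_ij, params: SPParams):
    """Contact-removal probability; capped at 1."""
    raw = params.P_w * np.exp(
        -np.asarray(w_ij, dtype=float) / params.w_min
    ) + params.P_h * logistic(f_i, params.f_plus, params.nu)
    return np.minimum(raw, 1.0)


@dataclass
class RateEstimator:
    """Per-neuron low-pass filtered firing rate (Hz).

    The filter obeys ``tau_slow * df/dt = -f + spike train``: exponential
    decay between spikes and a jump of ``1 / tau_slow`` (in 1/ms, i.e.
    ``1000 / tau_slow_ms`` Hz) at each spike.  With the 30-minute default
    the filter averages firing over the last several structural updates.
    """

    f_hat: np.ndarray          # filtered rates, Hz
    tau_slow: float            # filter constant, ms

    @classmethod
    def zeros(cls, N: int, tau_slow: float) -> "RateEstimator":
        return cls(f_hat=np.zeros(N), tau_slow=tau_slow)

    @classmethod
    def from_rates(cls, rates_hz: np.ndarray, tau_slow: float) -> "RateEstimator":
        """Warm start the filter at given empirical rates."""
        return cls(f_hat=np.asarray(rates_hz, dtype=float).copy(), tau_slow=tau_slow)


def update_rate_estimate(
    est: RateEstimator,
    spike_trains: list[np.ndarray],
    interval: float,
) -> RateEstimator:
    """Advance the filter by ``interval`` ms given per-neuron spike times.

    Spike times are relative to the interval start, within
    ``[0, interval]``.  The update is the exact piecewise solution, not a
    discretization: decay by ``exp(-interval / tau)`` plus one decayed
    jump per spike.
    """
    tau = est.tau_slow
    jump_hz = 1000.0 / tau
    decay = np.exp(-interval / tau)
    new = est.f_hat * decay
    for i, times in enumerate(spike_trains):
        t = np.asarray(times, dtype=float)
        if t.size:
            if t.min() < 0 or t.max() > interval:
                raise ValueError("spike times must lie within the interval")
            new[i] += jump_hz * np.exp(-(interval - t) / tau).sum()
    return RateEstimator(f_hat=new, tau_slow=tau)


@dataclass
class StructuralEvent:
    iteration: int
    event: str       # "add" or "prune"
    pre: int
    post: int
    weight: float    # weight at the event
    lifetime: int    # iterations lived (pruning only; -1 for additions)


def sp_update(
    conn: ConnectivityState,
    geometry: NetworkGeometry,
    rates: RateEstimator,
    params: SPParams,
    regime: str = "stdp_sp",
    rng_seed: int | np.random.Generator = 0,
    iteration: int = 0,
    event_log: list[StructuralEvent] | None = None,
) -> ConnectivityState:
    """One synchronous structural update; mutates and returns ``conn``.

    ``regime`` selects the new-contact weight support and whether
    weight-dependent pruning applies: under ``hsp_only`` new contacts get
    weights uniform on [0, 1] and ``P_w`` is forced to 0; under
    ``stdp_hsp`` new weights are uniform on [0, 0.2] and ``P_w`` is 0;
    under ``stdp_sp`` new weights are uniform on [0, 0.2] and ``P_w``
    applies as configured.  Additions and removals are decided from the
    pre-update state, so a contact added now is first exposed to pruning
    at the next update.
    """
    if regime not in ("hsp_only", "stdp_hsp", "stdp_sp"):
        raise ValueError(f"unknown plasticity regime: {regime}")
    N = conn.N
    if rates.f_hat.shape[0] != N:
        raise ValueError("rate estimator and connectivity sizes mismatch")
    rng = np.random.default_rng(rng_seed)

    p_w = params.P_w if regime == "stdp_sp" else 0.0
    eff = params if p_w == params.P_w else SPParams(
        P_h=params.P_h, P_w=p_w, l0=params.l0, f_T=params.f_T,
        delta_f=params.delta_f, p_tilde_T=params.p_tilde_T,
        w_min=params.w_min, tau_slow=params.tau_slow,
    )

    f_col = rates.f_hat[:, None]                    # postsynaptic rate per row i
    add_prob = p_add(f_col, geometry.distance, eff)
    prune_prob = p_prune(f_col, conn.weights, eff)

    off = ~np.eye(N, dtype=bool)
    live = (conn.adjacency == 1) & off
    absent = (conn.adjacency == 0) & off

    u = rng.random((N, N))
    born = absent & (u < add_prob)
    died = live & (u < prune_prob)

    w_hi = 1.0 if regime == "hsp_only" else 0.2
    if event_log is not None:
        for i, j in zip(*np.nonzero(died)):
            event_log.append(StructuralEvent(
                iteration=iteration, event="prune", pre=int(j), post=int(i),
                weight=float(conn.weights[i, j]),
                lifetime=int(iteration - conn.birth_time[i, j]),
            ))
    conn.adjacency[died] = 0
    conn.weights[died] = 0.0
    conn.birth_time[died] = -1

    n_born = int(born.sum())
    new_w = rng.uniform(0.0, w_hi, size=n_born)
    conn.adjacency[born] = 1
    conn.weights[born] = new_w
    conn.birth_time[born] = iteration
    if event_log is not None:
        for (i, j), w in zip(zip(*np.nonzero(born)), new_w):
            event_log.append(StructuralEvent(
                iteration=iteration, event="add", pre=int(j), post=int(i),
                weight=float(w), lifetime=-1,
            ))
    return conn


def write_event_log(events: list[StructuralEvent], path) -> None:
    """TSV structural-event log for contact-lifetime analyses."""
    with open(path, "w") as fh:
        fh.write("iteration\tevent\tpre\tpost\tweight_at_event\tlifetime_iterations\n")
        for e in events:
            fh.write(
                f"{e.iteration}\t{e.event}\t{e.pre}\t{e.post}\t"
                f"{e.weight!r}\t{e.lifetime}\n"
            )
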