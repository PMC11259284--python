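"""Network state container and the time-stepping front end.

:func:`integrate_interval` advances the full network (membrane and
threshold potentials, synaptic and noise conductances, delayed
deliveries, optional STDP weight updates, optional stimulation) for a
fixed duration and returns the spike raster of the interval.  The heavy
loop lives in :mod:`plastinet._kernel`; this module owns the state
bookkeeping that lets consecutive intervals chain exactly: the synaptic
delay ring buffer, refractory clocks and STDP traces all persist on the
:class:`NeuronEnsembleState` between calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import run_network
from .connectivity import ConnectivityState
from .params import NeuronParameters, STDPParams

#: default integrator step, ms; divides tau_spike (1 ms), t_d (3 ms) and
#: the stimulation pulse sub-durations (0.5 / 0.2 / 1.5 ms)
DEFAULT_DT = 0.1


@dataclass
class SpikeRaster:
    """Spike events of one integration interval, in time order per neuron."""

    neuron: np.ndarray  # int32 neuron indices
    time: np.ndarray    # float64 spike times, ms (absolute)

    @property
    def n_spikes(self) -> int:
        return int(self.neuron.shape[0])

    def per_neuron(self, N: int) -> list[np.ndarray]:
        """Split into per-neuron sorted spike-time arrays."""
        out = [self.time[self.neuron == i] for i in range(N)]
        return [np.sort(t) for t in out]

    def counts(self, N: int) -> np.ndarray:
        return np.bincount(self.neuron, minlength=N).astype(np.int64)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time_ms\tneuron_index\n")
            order = np.argsort(self.time, kind="stable")
            for k in order:
                fh.write(f"{self.time[k]!r}\t{self.neuron[k]}\n")


def concat_rasters(rasters: list[SpikeRaster]) -> SpikeRaster:
    if not rasters:
        return SpikeRaster(np.empty(0, np.int32), np.empty(0, np.float64))
    return SpikeRaster(
        np.concatenate([r.neuron for r in rasters]),
        np.concatenate([r.time for r in rasters]),
    )


@dataclass
class NeuronEnsembleState:
    V: np.ndarray             # membrane potentials, mV
    V_th: np.ndarray          # dynamic thresholds, mV
    g_syn: np.ndarray         # synaptic conductances, mS/cm^2
    g_noise: np.ndarray       # noise conductances, mS/cm^2
    g_leak: np.ndarray        # static leak conductances, mS/cm^2
    refractory: np.ndarray    # remaining clamp steps (int64)
    time: float = 0.0         # absolute time at the state, ms
    chi: np.ndarray | None = None   # presynaptic STDP traces
    psi: np.ndarray | None = None   # postsynaptic STDP traces
    ring: np.ndarray | None = None        # delivery ring buffer (slots, N)
    ring_count: np.ndarray | None = None
    ring_pos: int = 0
    dt: float | None = None   # step the ring buffer was built for

    @property
    def N(self) -> int:
        return self.V.shape[0]


def init_state(
    g_leak: np.ndarray,
    params: NeuronParameters = NeuronParameters(),
    rng_seed: int | np.random.Generator = 0,
) -> NeuronEnsembleState:
    """Fresh ensemble state: V uniform in [V_reset, V_rest], V_th at rest,
    conductances zero."""
    rng = np.random.default_rng(rng_seed)
    g_leak = np.asarray(g_leak, dtype=np.float64)
    N = g_leak.shape[0]
    return NeuronEnsembleState(
        V=rng.uniform(params.V_reset, params.V_rest, size=N),
        V_th=np.full(N, params.V_th_rest),
        g_syn=np.zeros(N),
        g_noise=np.zeros(N),
        g_leak=g_leak,
        refractory=np.zeros(N, dtype=np.int64),
    )


def _check_divides(dt: float, value: float, name: str) -> int:
    steps = value / dt
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(f"dt={dt} must divide {name}={value}")
    return int(round(steps))


def integrate_interval(
    state: NeuronEnsembleState,
    conn: ConnectivityState,
    params: NeuronParameters = NeuronParameters(),
    stdp: STDPParams | None = None,
    stimulus=None,
    duration: float = 1000.0,
    dt: float = DEFAULT_DT,
    rng_seed: int = 0,
    forced_spikes=None,
    spike_capacity_hz: float = 120.0,
) -> SpikeRaster:
    """Advance the network by ``duration`` ms; mutates ``state`` (and
    ``conn.weights`` when ``stdp`` is given).

    Parameters
    ----------
    stdp
        STDP constants; ``None`` freezes the weights.
    stimulus
        A :class:`plastinet.stimulation.StimulusField` covering the
        interval ``[state.time, state.time + duration]``, or ``None``.
    forced_spikes
        Optional sequence of ``(neuron, time_ms)`` pairs; each makes the
        neuron fire at the given (grid-aligned, end-of-step) time even if
        its membrane has not crossed threshold.  Intended for controlled
        single-synapse experiments.
    spike_capacity_hz
        Sizing bound for the output buffer, as a network-mean rate.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_steps = _check_divides(dt, duration, "duration")
    spike_steps = _check_divides(dt, params.tau_spike, "tau_spike")
    delay_steps = _check_divides(dt, params.t_d, "t_d")

    N = state.N
    if conn.adjacency.shape[0] != N:
        raise ValueError("connectivity and state sizes mismatch")

    slots = delay_steps + 2
    if state.ring is None or state.dt != dt or state.ring.shape[0] != slots:
        if state.ring is not None and state.dt != dt:
            raise ValueError("dt changed mid-run; pending deliveries would be lost")
        state.ring = np.zeros((slots, N), dtype=np.int64)
        state.ring_count = np.zeros(slots, dtype=np.int64)
        state.ring_pos = 0
        state.dt = dt

    stdp_on = stdp is not None
    if stdp_on and (state.chi is None or state.chi.shape[0] != N):
        state.chi = np.zeros(N)
        state.psi = np.zeros(N)
    chi = state.chi if state.chi is not None else np.zeros(1)
    psi = state.psi if state.psi is not None else np.zeros(1)
    if stdp_on:
        eta = stdp.eta
        etabR = stdp.eta * stdp.b / stdp.tau_R
        dec_chi = np.exp(-dt / stdp.tau_plus)
        dec_psi = np.exp(-dt / (stdp.tau_R * stdp.tau_plus))
    else:
        eta = etabR = 0.0
        dec_chi = dec_psi = 1.0

    if stimulus is not None:
        stim_x, stim_gain = stimulus.step_amplitudes(state.time, n_steps, dt)
        stim_on = True
    else:
        stim_x = np.zeros((1, 1))
        stim_gain = np.zeros((N, 1))
        stim_on = False

    if forced_spikes:
        pairs = sorted(
            (int(round(t / dt)) - 1, int(n)) for n, t in forced_spikes
        )
        forced_step = np.array([p[0] for p in pairs], dtype=np.int64)
        forced_neuron = np.array([p[1] for p in pairs], dtype=np.int64)
        if forced_step.size and forced_step[0] < 0:
            raise ValueError("forced spike before the interval start")
    else:
        forced_step = np.empty(0, dtype=np.int64)
        forced_neuron = np.empty(0, dtype=np.int64)

    cap = max(1024, int(N * duration / 1000.0 * spike_capacity_hz))
    spike_neuron = np.empty(cap, dtype=np.int64)
    spike_time = np.empty(cap, dtype=np.float64)

    p_noise = params.f_noise * dt / 1000.0
    if p_noise >= 0.1:
        raise ValueError("f_noise * dt too large for per-step Bernoulli thinning")

    n_spikes, overflow, ring_pos = run_network(
        state.V, state.V_th, state.g_syn, state.g_noise, state.refractory,
        conn.adjacency, conn.weights, chi, psi,
        state.ring, state.ring_count,
        state.g_leak,
        n_steps, dt, state.time, state.ring_pos,
        params.C, params.V_rest, params.V_reset, params.V_th_rest,
        params.V_syn, params.V_spike, params.V_th_spike,
        params.tau_th, spike_steps, delay_steps,
        params.kappa, np.exp(-dt / params.tau_syn), p_noise, params.kappa_noise,
        stdp_on, eta, etabR, dec_chi, dec_psi,
        stim_on, stim_x, stim_gain,
        forced_step, forced_neuron,
        int(rng_seed) % (2**31 - 1),
        spike_neuron, spike_time,
    )
    if overflow:
        raise RuntimeError(
            "spike buffer overflow; raise spike_capacity_hz "
            f"(capacity was {cap} spikes)"
        )
    state.ring_pos = ring_pos
    state.time += duration
    return SpikeRaster(
        neuron=spike_neuron[:n_spikes].copy().astype(np.int32),
        time=spike_time[:n_spikes].copy(),
    )


def poisson_event_times(
    rate: float, duration: float, rng_seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Event times (ms) of a homogeneous Poisson process on [0, duration].

    ``rate`` is in Hz; inter-event intervals are i.i.d. exponential with
    mean ``1000 / rate`` ms.  Empty for ``rate == 0``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return np.empty(0)
    rng = np.random.default_rng(rng_seed)
    mean_ms = 1000.0 / rate
    # draw in chunks until past the horizon
    out = []
    t = 0.0
    n_guess = max(16, int(duration / mean_ms * 1.2) + 8)
    while t < duration:
        gaps = rng.exponential(mean_ms, size=n_guess)
        times = t + np.cumsum(gaps)
        out.append(times)
        t = times[-1]
    times = np.concatenate(out)
    return times[times < duration]
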