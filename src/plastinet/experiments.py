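"""Experiment orchestration: steady states, the adiabatic structural
loop, and stimulation protocols.

The timescale separation is handled adiabatically: the fast dynamics
(spiking plus STDP) are integrated in measurement intervals of ``T``
(60 s by default) until the network-averaged weight and rate both
converge to relative accuracy ``upsilon``; only then, in regimes with
structural plasticity, is one discrete structural update applied and the
relaxation restarted.  A master seed expands into named independent
streams (wiring, weights, membrane init, noise, structural updates,
stimulus) so that e.g. the same wiring can be reused across initial
weight conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import CalibrationResult, sample_gleak
from .connectivity import (
    ConnectivityState,
    empty_connectivity,
    init_weights,
    random_connectivity,
)
from .dynamics import (
    DEFAULT_DT,
    NeuronEnsembleState,
    SpikeRaster,
    init_state,
    integrate_interval,
)
from .geometry import NetworkGeometry, place_neurons
from .measures import (
    NetworkSummary,
    mean_weights,
    order_parameter,
    rate_and_cv,
    relative_change,
)
from .params import NeuronParameters, SPParams, STDPParams, StimulusParams
from .stimulation import build_stimulus
from .structural import (
    RateEstimator,
    StructuralEvent,
    sp_update,
    update_rate_estimate,
)

REGIMES = ("stdp_only", "hsp_only", "stdp_hsp", "stdp_sp")

_STREAMS = ("wiring", "weights", "membrane", "noise", "sp", "stimulus", "calibration")


def seed_streams(master_seed: int) -> dict[str, np.random.SeedSequence]:
    """Expand a master seed into named independent seed sequences."""
    root = np.random.SeedSequence(master_seed)
    children = root.spawn(len(_STREAMS))
    return dict(zip(_STREAMS, children))


def _seed_int(ss: np.random.SeedSequence, k: int = 0) -> int:
    """Deterministic 31-bit integer seed number ``k`` from a stream."""
    return int(ss.generate_state(k + 1)[k]) % (2**31 - 1)


@dataclass
class ConvergenceConfig:
    T: float = 60_000.0      # measurement interval, ms
    upsilon: float = 1e-3    # relative accuracy of the steady-state test
    n_min: int = 60          # minimum interval pairs before convergence
    n_max: int = 200         # give up after this many intervals


@dataclass
class ExperimentConfig:
    regime: str = "stdp_only"
    m: int = 20
    L: float = 1.0
    beta0: float = 0.075
    mean_weight0: float = 0.8
    f0: float = 3.0          # mean natural rate, Hz
    sigma_f: float = 0.5     # natural-rate SD, Hz
    l0_wiring: float | None = 0.5   # distance constant of initial wiring (x L)
    neuron: NeuronParameters = field(default_factory=NeuronParameters)
    stdp: STDPParams = field(default_factory=STDPParams)
    sp: SPParams = field(default_factory=SPParams)
    convergence: ConvergenceConfig = field(default_factory=ConvergenceConfig)
    max_sp_iterations: int = 100
    dt: float = DEFAULT_DT
    order_window: float = 2000.0    # order-parameter window, ms
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")

    @property
    def stdp_active(self) -> bool:
        return self.regime in ("stdp_only", "stdp_hsp", "stdp_sp")

    @property
    def sp_regime(self) -> str | None:
        return self.regime if self.regime != "stdp_only" else None


@dataclass
class ExperimentRecord:
    config: ExperimentConfig
    summaries: list[NetworkSummary] = field(default_factory=list)
    sp_summaries: list[NetworkSummary] = field(default_factory=list)
    sp_intervals: list[int] = field(default_factory=list)  # realized n per iter
    events: list[StructuralEvent] = field(default_factory=list)
    converged: bool = False
    n_intervals: int = 0
    final_raster: SpikeRaster | None = None
    natural_rates: np.ndarray | None = None
    network: "BuiltNetwork | None" = None

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "interval": k,
                    "R": s.R,
                    "mean_rate": s.mean_rate,
                    "cv": s.cv_rate,
                    "mean_weight": s.mean_weight,
                    "beta": s.beta,
                }
                for k, s in enumerate(self.summaries)
            ]
        )


@dataclass
class BuiltNetwork:
    geometry: NetworkGeometry
    conn: ConnectivityState
    state: NeuronEnsembleState
    g_leak: np.ndarray
    natural_rates: np.ndarray


def build_network(
    config: ExperimentConfig, calib: CalibrationResult
) -> BuiltNetwork:
    """Construct geometry, wiring, weights and initial membrane state."""
    streams = seed_streams(config.master_seed)
    geometry = place_neurons(
        config.m, config.L, rng_seed=np.random.default_rng(streams["wiring"])
    )
    if config.regime == "hsp_only" or config.beta0 == 0.0:
        conn = empty_connectivity(geometry.N)
    else:
        l0 = None if config.l0_wiring is None else config.l0_wiring * config.L
        conn = random_connectivity(
            geometry,
            config.beta0,
            l0=l0,
            rng_seed=np.random.default_rng(streams["wiring"].spawn(1)[0]),
        )
        init_weights(
            conn,
            config.mean_weight0,
            rng_seed=np.random.default_rng(streams["weights"]),
        )
    g_leak = sample_gleak(
        config.f0,
        config.sigma_f,
        calib,
        geometry.N,
        rng_seed=np.random.default_rng(streams["membrane"]),
    )
    state = init_state(
        g_leak,
        config.neuron,
        rng_seed=np.random.default_rng(streams["membrane"].spawn(1)[0]),
    )
    natural = calib.alpha1 * g_leak + calib.alpha2
    return BuiltNetwork(geometry, conn, state, g_leak, natural)


def _relax(
    config: ExperimentConfig,
    net: BuiltNetwork,
    noise_stream: np.random.SeedSequence,
    conv: ConvergenceConfig,
    record: ExperimentRecord,
    est: RateEstimator | None,
    stimulus=None,
    stdp_override: bool | None = None,
):
    """Integrate T-intervals until the steady-state test passes.

    Returns ``(converged, n_used, last_raster, last_summary, est)``.
    ``est``, when given, is advanced by the exact slow rate filter over
    every interval.
    """
    T = conv.T
    N = net.state.N
    stdp = config.stdp if (
        config.stdp_active if stdp_override is None else stdp_override
    ) else None
    Ws: list[float] = []
    fs: list[float] = []
    last_raster = None
    last_summary = None
    converged = False
    n_used = 0
    for k in range(1, conv.n_max + 1):
        t_start = net.state.time
        raster = integrate_interval(
            net.state,
            net.conn,
            config.neuron,
            stdp=stdp,
            stimulus=stimulus,
            duration=T,
            dt=config.dt,
            rng_seed=_seed_int(noise_stream, k - 1),
        )
        mean_rate, cv, rates = rate_and_cv(raster, T, N)
        mW, _ = mean_weights(net.conn)
        R = order_parameter(
            raster, N, t=net.state.time, window=min(config.order_window, T)
        )
        summary = NetworkSummary(
            R=R,
            mean_rate=mean_rate,
            cv_rate=cv,
            mean_weight=mW if np.isfinite(mW) else 0.0,
            beta=net.conn.density,
            window=T,
        )
        record.summaries.append(summary)
        if est is not None:
            est = update_rate_estimate(
                est, [tr - t_start for tr in raster.per_neuron(N)], T
            )
        Ws.append(summary.mean_weight)
        fs.append(mean_rate)
        last_raster, last_summary = raster, summary
        n_used = k
        if k >= max(conv.n_min + 1, 2):
            if (
                relative_change(Ws[-2], Ws[-1]) < conv.upsilon
                and relative_change(fs[-2], fs[-1]) < conv.upsilon
            ):
                converged = True
                break
    return converged, n_used, last_raster, last_summary, est


def run_steady_state(
    config: ExperimentConfig, calib: CalibrationResult
) -> ExperimentRecord:
    """Relax a frozen-structure network (STDP weights only) to steady state."""
    record = ExperimentRecord(config=config)
    net = build_network(config, calib)
    record.natural_rates = net.natural_rates
    streams = seed_streams(config.master_seed)
    converged, n_used, raster, _, _ = _relax(
        config, net, streams["noise"], config.convergence, record, est=None
    )
    record.converged = converged
    record.n_intervals = n_used
    record.final_raster = raster
    record.network = net  # attached for downstream analysis
    return record


def run_adiabatic_sp(
    config: ExperimentConfig,
    calib: CalibrationResult,
    beta_tol: float | None = None,
) -> ExperimentRecord:
    """Adiabatic structural loop: relax, measure, one structural update.

    Each iteration relaxes the fast dynamics with the inner convergence
    window (``n_min=2``, ``n_max=31`` by default via ``config``), records
    the meta-steady summary, then applies one synchronous birth-death
    update using the slow-filtered rates.  Stops after
    ``config.max_sp_iterations`` updates, or earlier once the density has
    converged to relative accuracy ``beta_tol`` (when given).
    """
    if config.sp_regime is None:
        raise ValueError("run_adiabatic_sp needs a regime with structural plasticity")
    record = ExperimentRecord(config=config)
    net = build_network(config, calib)
    record.natural_rates = net.natural_rates
    streams = seed_streams(config.master_seed)
    noise = streams["noise"]
    sp_stream = streams["sp"]
    est: RateEstimator | None = None
    prev_beta = None
    for it in range(config.max_sp_iterations):
        sub_noise = noise.spawn(1)[0]
        converged, n_used, raster, summary, est = _relax(
            config, net, sub_noise, config.convergence, record, est=est
        )
        if est is None:
            # warm start the slow filter at the empirical rates of the
            # final relaxation interval of the first iteration
            _, _, rates = rate_and_cv(raster, config.convergence.T, net.state.N)
            est = RateEstimator.from_rates(rates, config.sp.tau_slow)
        record.sp_summaries.append(summary)
        record.sp_intervals.append(n_used)
        record.final_raster = raster
        sp_update(
            net.conn,
            net.geometry,
            est,
            config.sp,
            regime=config.sp_regime,
            rng_seed=np.random.default_rng(sp_stream.spawn(1)[0]),
            iteration=it,
            event_log=record.events,
        )
        beta = net.conn.density
        if beta_tol is not None and prev_beta is not None and (
            relative_change(prev_beta, beta) < beta_tol
        ):
            record.converged = True
            break
        prev_beta = beta
    record.n_intervals = len(record.summaries)
    record.network = net
    return record


def run_stimulation_protocol(
    config: ExperimentConfig,
    net: BuiltNetwork,
    a_s: float,
    F_s: float,
    stim_duration: float = 120_000.0,
    post_duration: float = 600_000.0,
    pre_duration: float = 60_000.0,
    stimulus_params: StimulusParams | None = None,
    desync_threshold: float = 0.3,
) -> dict:
    """Stimulate a prepared network and classify the long-term outcome.

    The protocol is pre / stimulation / post with STDP active throughout
    and the structure frozen.  The outcome is classified by the order
    parameter averaged over the final post-epoch interval:
    ``R < desync_threshold`` counts as long-term desynchronization.
    Returns a dict with the R time course per epoch and the verdict.
    """
    streams = seed_streams(config.master_seed)
    noise = streams["noise"].spawn(3)
    stim_ss = streams["stimulus"]
    sp = stimulus_params or StimulusParams(a_s=a_s, F_s=F_s)
    if sp.a_s != a_s or sp.F_s != F_s:
        sp = replace(sp, a_s=a_s, F_s=F_s)
    N = net.state.N
    T = 60_000.0
    out = {"pre_R": [], "stim_R": [], "post_R": []}

    def _epoch(duration, stimulus, key, stream):
        n_chunks = max(1, int(round(duration / T)))
        chunk = duration / n_chunks
        for k in range(n_chunks):
            raster = integrate_interval(
                net.state,
                net.conn,
                config.neuron,
                stdp=config.stdp if config.stdp_active else None,
                stimulus=stimulus,
                duration=chunk,
                dt=config.dt,
                rng_seed=_seed_int(stream, k),
            )
            R = order_parameter(
                raster, N, t=net.state.time,
                window=min(config.order_window, chunk),
            )
            out[key].append(R)
        return raster

    if pre_duration > 0:
        _epoch(pre_duration, None, "pre_R", noise[0])
    if stim_duration > 0 and a_s > 0:
        field_ = build_stimulus(
            net.geometry,
            sp,
            t_start=net.state.time,
            duration=stim_duration,
            neuron_params=config.neuron,
            rng_seed=np.random.default_rng(stim_ss),
        )
        _epoch(stim_duration, field_, "stim_R", noise[1])
    elif stim_duration > 0:
        _epoch(stim_duration, None, "stim_R", noise[1])
    if post_duration > 0:
        _epoch(post_duration, None, "post_R", noise[2])

    final_R = out["post_R"][-1] if out["post_R"] else float("nan")
    out["final_R"] = final_R
    out["desynchronized"] = bool(final_R < desync_threshold)
    return out


def fixture_network(preset: str, rng_seed: int = 0) -> BuiltNetwork:
    """Deterministic miniature networks for tests and worked examples.

    Presets: ``two_neuron`` (one directed contact), ``ring_16`` (a
    directed ring), ``lattice_36`` (6 x 6 lattice, random wiring),
    ``paper_400`` (full-size 20 x 20 lattice, default parameters).
    Leak conductances are fixed near the middle of the calibrated range
    (natural rate about 3 Hz) rather than drawn from a calibration run.
    """
    g3 = 0.0165  # mS/cm^2, natural rate ~3 Hz under default noise
    if preset == "two_neuron":
        positions = np.array([[0.25, 0.5], [0.75, 0.5]])
        diff = positions[:, None, :] - positions[None, :, :]
        geometry = NetworkGeometry(
            m=2, L=1.0, h=0.5, jitter_scale=0.0, positions=positions,
            distance=np.sqrt((diff**2).sum(axis=2)),
        )
        conn = empty_connectivity(2)
        conn.adjacency[1, 0] = 1      # contact 0 -> 1
        conn.weights[1, 0] = 1.0
        conn.birth_time[1, 0] = 0
        g_leak = np.array([g3, g3])
    elif preset == "ring_16":
        geometry = place_neurons(4, 1.0, jitter_scale=0.0)
        conn = empty_connectivity(16)
        for j in range(16):
            conn.adjacency[(j + 1) % 16, j] = 1
            conn.weights[(j + 1) % 16, j] = 1.0
            conn.birth_time[(j + 1) % 16, j] = 0
        g_leak = np.full(16, g3)
    elif preset == "lattice_36":
        geometry = place_neurons(6, 1.0, rng_seed=rng_seed)
        conn = random_connectivity(geometry, 0.1, l0=0.5, rng_seed=rng_seed)
        init_weights(conn, 0.8, rng_seed=rng_seed + 1)
        g_leak = np.full(36, g3)
    elif preset == "paper_400":
        geometry = place_neurons(20, 1.0, rng_seed=rng_seed)
        conn = random_connectivity(geometry, 0.075, l0=0.5, rng_seed=rng_seed)
        init_weights(conn, 0.8, rng_seed=rng_seed + 1)
        g_leak = np.full(400, g3)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    state = init_state(g_leak, rng_seed=rng_seed + 2)
    natural = np.full(geometry.N, 3.0)
    return BuiltNetwork(geometry, conn, state, g_leak, natural)
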