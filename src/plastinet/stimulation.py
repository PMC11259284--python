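"""Uncorrelated multichannel random stimulation (UMRS).

Each of ``N_s`` electrodes (quadrant centers of the network plane)
delivers charge-balanced pulse pairs at independent random times: onsets
form a renewal process whose intervals are a hard floor ``TAU_LAMBDA``
plus an exponential excess, giving a mean event rate ``F_s``.  A neuron
at distance ``l`` from an electrode receives the electrode's waveform
scaled by a Gaussian spatial profile ``D(l) = exp(-l^2 / 2 sigma_s^2)``,
and contributions from all electrodes sum linearly:

``I_stim,i(t) = a_s * I0 * sum_r X_r(t) * D(l_ir)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import NetworkGeometry
from .params import (
    TAU_LAMBDA,
    NeuronParameters,
    StimulusParams,
    sigma_from_gamma,
    stimulus_amplitude,
)


def electrode_positions(L: float, N_s: int = 4, offset: float = 0.0) -> np.ndarray:
    """Electrode coordinates: quadrant centers of the network plane.

    The lattice cloud occupies ``[offset, offset + L]`` per axis (the
    ideal lattice starts at half a spacing), so the quadrant centers sit
    at ``offset + L/4`` and ``offset + 3L/4``.
    """
    if N_s != 4:
        raise ValueError("only the 4-electrode quadrant layout is supported")
    q = L / 4.0
    return offset + np.array(
        [[q, q], [3 * q, q], [q, 3 * q], [3 * q, 3 * q]], dtype=float
    )


def umrs_event_times(
    F_s: float,
    duration: float,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Event onset times (ms) of one electrode over ``[0, duration]``.

    Inter-onset intervals are ``TAU_LAMBDA + Exp(tau_umrs)`` with
    ``tau_umrs = 1000 / F_s - TAU_LAMBDA``; at the 130 Hz ceiling the
    exponential part vanishes and the train is strictly periodic.
    """
    if F_s <= 0:
        raise ValueError("F_s must be positive")
    tau_umrs = 1000.0 / F_s - TAU_LAMBDA
    if tau_umrs < -1e-9:
        raise ValueError("F_s exceeds the 130 Hz event-rate ceiling")
    tau_umrs = max(tau_umrs, 0.0)
    rng = np.random.default_rng(rng_seed)
    mean_gap = TAU_LAMBDA + tau_umrs
    out = []
    t = 0.0
    n_guess = max(16, int(duration / mean_gap * 1.2) + 8)
    while t < duration:
        gaps = TAU_LAMBDA + (
            rng.exponential(tau_umrs, size=n_guess) if tau_umrs > 0
            else np.zeros(n_guess)
        )
        times = t + np.cumsum(gaps)
        out.append(times)
        t = times[-1]
    times = np.concatenate(out)
    return times[times < duration]


@dataclass
class StimulusField:
    """Realized stimulation: per-electrode event times plus spatial gains.

    ``t_start``/``t_stop`` delimit the active window in absolute
    simulation time; outside it the field contributes nothing.
    """

    params: StimulusParams
    event_times: list[np.ndarray]   # absolute onset times per electrode, ms
    gains: np.ndarray               # (N, N_s): a_s * I0 * D(l_ir), uA/cm^2
    sigma_s: float
    t_start: float
    t_stop: float

    def waveform(self, times_rel: np.ndarray) -> np.ndarray:
        """Pulse-pair amplitude at times (ms) relative to an event onset.

        1 during the positive phase, 0 in the gap, ``-tau_sp / tau_sn``
        during the negative phase; the time integral over one event is
        zero (charge balance).
        """
        p = self.params
        t = np.asarray(times_rel, dtype=float)
        out = np.zeros_like(t)
        out[(t >= 0) & (t < p.tau_sp)] = 1.0
        neg = (t >= p.tau_sp + p.tau_sg) & (t < p.event_width)
        out[neg] = p.neg_amplitude
        return out

    def electrode_amplitude(self, r: int, t: float) -> float:
        """Waveform value of electrode ``r`` at absolute time ``t``."""
        if not (self.t_start <= t < self.t_stop):
            return 0.0
        ev = self.event_times[r]
        k = np.searchsorted(ev, t, side="right") - 1
        if k < 0:
            return 0.0
        return float(self.waveform(np.array([t - ev[k]]))[0])

    def stim_current(self, t: float) -> np.ndarray:
        """Per-neuron stimulation current (uA/cm^2) at absolute time ``t``."""
        amps = np.array(
            [self.electrode_amplitude(r, t) for r in range(len(self.event_times))]
        )
        return self.gains @ amps

    def step_amplitudes(self, t0: float, n_steps: int, dt: float):
        """Per-step electrode amplitudes for the integrator.

        Returns ``(X, gains)`` where ``X[s, r]`` is electrode ``r``'s
        waveform sampled at the step start ``t0 + s * dt``; pulse phases
        are thereby snapped to the dt grid.
        """
        n_elec = len(self.event_times)
        X = np.zeros((n_steps, n_elec))
        lo = max(t0, self.t_start)
        hi = min(t0 + n_steps * dt, self.t_stop)
        if hi <= lo:
            return X, self.gains
        width = self.params.event_width
        for r, ev in enumerate(self.event_times):
            sel = ev[(ev > lo - width) & (ev < hi)]
            for onset in sel:
                s0 = int(np.ceil((max(onset, lo) - t0) / dt - 1e-9))
                s1 = int(np.ceil((min(onset + width, hi) - t0) / dt - 1e-9))
                s0 = max(s0, 0)
                s1 = min(s1, n_steps)
                if s1 > s0:
                    steps = np.arange(s0, s1)
                    X[steps, r] = self.waveform(t0 + steps * dt - onset)
        return X, self.gains


def build_stimulus(
    geometry: NetworkGeometry,
    params: StimulusParams,
    t_start: float,
    duration: float,
    neuron_params: NeuronParameters = NeuronParameters(),
    rng_seed: int | np.random.Generator = 0,
) -> StimulusField:
    """Draw the per-electrode event trains and precompute spatial gains."""
    rng = np.random.default_rng(rng_seed)
    sigma_s = sigma_from_gamma(params.gamma, geometry.L)
    I0 = stimulus_amplitude(neuron_params, params.tau_sp)
    pos_e = electrode_positions(geometry.L, params.N_s, offset=geometry.h / 2.0)
    d = np.sqrt(
        ((geometry.positions[:, None, :] - pos_e[None, :, :]) ** 2).sum(axis=2)
    )
    gains = params.a_s * I0 * np.exp(-(d**2) / (2.0 * sigma_s**2))
    events = [
        t_start + umrs_event_times(params.F_s, duration, rng)
        for _ in range(params.N_s)
    ]
    return StimulusField(
        params=params,
        event_times=events,
        gains=gains,
        sigma_s=sigma_s,
        t_start=t_start,
        t_stop=t_start + duration,
    )


def export_schedule(field: StimulusField, path) -> None:
    """TSV export of the event schedule: (electrode, onset_ms)."""
    with open(path, "w") as fh:
        fh.write("electrode\tonset_ms\n")
        for r, ev in enumerate(field.event_times):
            for t in ev:
                fh.write(f"{r}\t{t!r}\n")
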