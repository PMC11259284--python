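"""Additive spike-timing-dependent plasticity.

Two equivalent views of the rule live here.  :func:`stdp_delta` is the
pairwise window: the weight change caused by a single (pre, post) spike
pair at lag ``q = t_post - t_pre - t_d`` (positive lag: the presynaptic
spike *arrived* before the postsynaptic one fired, causing potentiation).
:class:`STDPEngine` is the online trace formulation used during
integration: each presynaptic arrival increments a presynaptic trace
``chi_j`` (decay ``tau_plus``) and each postsynaptic spike increments a
postsynaptic trace ``psi_i`` (decay ``tau_R * tau_plus``); weight
updates read the opposite-side trace, which implements all-to-all
pairing of the accumulated spike history.  Summed over isolated spike
pairs the two views agree exactly.
"""

from __future__ import annotations

import math

import numpy as np

from .connectivity import ConnectivityState
from .params import STDPParams


def stdp_delta(q: float, params: STDPParams) -> float:
    """Pairwise weight change for a single spike pair at lag ``q`` (ms).

    ``q > 0`` (pre arrival before post spike) potentiates by
    ``eta * exp(-|q| / tau_plus)``; ``q <= 0`` depresses by
    ``eta * (b / tau_R) * exp(-|q| / (tau_R * tau_plus))`` — the
    depression window is ``tau_R`` times longer and ``b / tau_R`` times
    the potentiation amplitude, so the rule integrates to
    ``eta * tau_plus * (1 - b)`` over all lags.
    """
    if q > 0:
        return params.eta * math.exp(-abs(q) / params.tau_plus)
    return -params.eta * (params.b / params.tau_R) * math.exp(
        -abs(q) / (params.tau_R * params.tau_plus)
    )


class STDPEngine:
    """Online all-to-all STDP via exponentially decaying spike traces.

    Traces decay lazily: each per-neuron trace stores its value at the
    time of its last event, and any read at a later time applies the
    exact exponential decay for the elapsed interval.  Weight updates
    therefore match the continuous-time trace dynamics to machine
    precision regardless of the integrator step.

    Event hooks
    -----------
    ``on_presynaptic_delivery(conn, j, t)``
        Called at the *arrival* time ``t = t_j + t_d`` of each spike of
        ``j``.  Depresses every live contact ``j -> i`` by
        ``eta * (b / tau_R) * psi_i(t)``, then increments ``chi_j``.
    ``on_postsynaptic_spike(conn, i, t)``
        Called at each spike time of ``i``.  Potentiates every live
        contact ``j -> i`` by ``eta * chi_j(t)``, then increments
        ``psi_i``.

    The opposite-side trace is read *before* the same-side increment, so
    a spike never pairs with itself.  Weights are hard-clipped to
    ``[0, 1]`` after every update.
    """

    def __init__(self, params: STDPParams, N: int):
        self.params = params
        self.N = N
        self.chi = np.zeros(N)       # presynaptic traces at their last event
        self.psi = np.zeros(N)       # postsynaptic traces at their last event
        self._t_chi = np.zeros(N)    # last event time per presynaptic trace
        self._t_psi = np.zeros(N)    # last event time per postsynaptic trace

    def chi_at(self, j: int, t: float) -> float:
        return self.chi[j] * math.exp(-(t - self._t_chi[j]) / self.params.tau_plus)

    def psi_at(self, i: int, t: float) -> float:
        return self.psi[i] * math.exp(
            -(t - self._t_psi[i]) / (self.params.tau_R * self.params.tau_plus)
        )

    def on_presynaptic_delivery(
        self, conn: ConnectivityState, j: int, t: float
    ) -> None:
        p = self.params
        live = conn.adjacency[:, j] == 1
        if live.any():
            idx = np.nonzero(live)[0]
            decay = np.exp(-(t - self._t_psi[idx]) / (p.tau_R * p.tau_plus))
            dw = p.eta * (p.b / p.tau_R) * self.psi[idx] * decay
            conn.weights[idx, j] = np.clip(conn.weights[idx, j] - dw, 0.0, 1.0)
        self.chi[j] = self.chi_at(j, t) + 1.0
        self._t_chi[j] = t

    def on_postsynaptic_spike(
        self, conn: ConnectivityState, i: int, t: float
    ) -> None:
        p = self.params
        live = conn.adjacency[i, :] == 1
        if live.any():
            idx = np.nonzero(live)[0]
            decay = np.exp(-(t - self._t_chi[idx]) / p.tau_plus)
            dw = p.eta * self.chi[idx] * decay
            conn.weights[i, idx] = np.clip(conn.weights[i, idx] + dw, 0.0, 1.0)
        self.psi[i] = self.psi_at(i, t) + 1.0
        self._t_psi[i] = t
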