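"""Model parameter containers and their default values.

The defaults describe an excitatory population of conductance-based
leaky integrate-and-fire (LIF) neurons placed on a square lattice,
coupled through delayed exponential synapses, driven by Poisson
background noise, and subject to two adaptation mechanisms acting on
well-separated timescales:

* additive spike-timing-dependent plasticity (STDP) acting on the
  weights of existing contacts, and
* a stochastic structural-plasticity (SP) birth-death process acting on
  the contacts themselves.

Units are millivolts, milliseconds, Hz, mS/cm^2, uF/cm^2 and uA/cm^2
throughout unless a field says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class NeuronParameters:
    """Membrane, threshold, synapse and noise constants of the LIF model.

    The resting potential sits *above* the resting threshold, so an
    isolated neuron is intrinsically tonic: after each reset the membrane
    relaxes toward ``V_rest`` and crosses ``V_th_rest`` on the way,
    producing periodic firing whose rate is set by the leak conductance.
    """

    C: float = 3.0              # membrane capacitance, uF/cm^2
    V_rest: float = -38.0       # resting membrane potential, mV
    V_reset: float = -67.0      # post-spike reset potential, mV
    V_th_rest: float = -40.0    # resting threshold, mV
    V_syn: float = 0.0          # synaptic reversal potential, mV
    V_spike: float = 20.0       # membrane value during the spike clamp, mV
    V_th_spike: float = 0.0     # threshold value during the spike clamp, mV
    t_d: float = 3.0            # synaptic transmission delay, ms
    tau_th: float = 5.0         # threshold relaxation time constant, ms
    tau_syn: float = 1.0        # synaptic conductance time constant, ms
    tau_spike: float = 1.0      # spike clamp duration, ms
    kappa: float = 8.0          # maximal coupling strength, mS/cm^2
    f_noise: float = 20.0       # Poisson background rate per neuron, Hz
    kappa_noise: float = 0.06   # conductance jump per noise event, mS/cm^2

    def __post_init__(self) -> None:
        if self.tau_spike <= 0:
            raise ValueError("tau_spike must be positive")
        if self.tau_syn <= 0 or self.tau_th <= 0:
            raise ValueError("time constants must be positive")
        if self.t_d < 0:
            raise ValueError("synaptic delay must be non-negative")


@dataclass(frozen=True)
class STDPParams:
    """Constants of the additive STDP rule.

    Potentiation of a contact follows a pre-before-post spike pair with
    amplitude ``eta`` and time constant ``tau_plus``.  Depression follows
    post-before-pre-arrival pairs with amplitude ``eta * b / tau_R`` and
    time constant ``tau_R * tau_plus``.  ``b`` sets the asymmetry: the
    pairwise rule integrates to ``eta * tau_plus * (1 - b)`` over all
    lags, so ``b > 1`` is depression-dominant.  ``tau_R`` is
    dimensionless; it stretches the depression window relative to the
    potentiation window while shrinking its amplitude by the same factor.
    """

    eta: float = 0.02       # learning rate (maximal weight change per pair)
    tau_plus: float = 10.0  # LTP time constant, ms
    tau_R: float = 4.0      # dimensionless LTD scaling factor
    b: float = 1.4          # asymmetry; b > 1 => depression dominant

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_R <= 0:
            raise ValueError("tau_plus and tau_R must be positive")

    @property
    def tau_minus(self) -> float:
        """Decay time constant of the post-synaptic trace, ms."""
        return self.tau_R * self.tau_plus

    @property
    def net_area(self) -> float:
        """Integral of the pairwise weight change over all lags."""
        return self.eta * self.tau_plus * (1.0 - self.b)


@dataclass(frozen=True)
class SPParams:
    """Constants of the stochastic structural-plasticity birth-death rule.

    A missing contact onto neuron ``i`` is created with probability
    ``P_h * G(f_i, f_minus, -nu) * exp(-l / l0)`` per structural update,
    and a live contact is removed with probability
    ``P_w * exp(-w / w_min) + P_h * G(f_i, f_plus, nu)``, where ``G`` is
    a logistic function of the postsynaptic low-pass-filtered rate.  The
    homeostatic midpoints straddle the target rate ``f_T`` and the slope
    ``nu`` is fixed by requiring ``G`` to equal the floor probability
    ``p_tilde_T`` when the neuron sits exactly at the target.
    """

    P_h: float = 0.01           # maximal homeostatic add/prune probability
    P_w: float = 0.0            # maximal weight-dependent pruning probability
    l0: float = 0.5             # distance decay constant (same units as L)
    f_T: float = 4.5            # homeostatic target rate, Hz
    delta_f: float = 1.0        # logistic steepness scale, Hz
    p_tilde_T: float = 0.01     # floor probability at the target rate
    w_min: float = 0.001        # weight scale of the pruning exponential
    tau_slow: float = 30.0 * 60.0 * 1000.0  # rate filter constant, ms (30 min)

    def __post_init__(self) -> None:
        if not 0.0 <= self.P_h <= 1.0:
            raise ValueError("P_h must lie in [0, 1]")
        if not 0.0 <= self.P_w <= 1.0:
            raise ValueError("P_w must lie in [0, 1]")
        if self.l0 <= 0 or self.w_min <= 0 or self.tau_slow <= 0:
            raise ValueError("l0, w_min and tau_slow must be positive")
        if not 0.0 < self.p_tilde_T < 0.5:
            raise ValueError("p_tilde_T must lie in (0, 0.5)")

    @property
    def f_minus(self) -> float:
        """Midpoint of the addition logistic, Hz (f_T - delta_f / 2)."""
        return self.f_T - self.delta_f / 2.0

    @property
    def f_plus(self) -> float:
        """Midpoint of the homeostatic pruning logistic, Hz."""
        return self.f_T + self.delta_f / 2.0

    @property
    def nu(self) -> float:
        """Logistic slope, Hz, from the floor-probability condition."""
        return self.delta_f / (2.0 * math.log((1.0 - self.p_tilde_T) / self.p_tilde_T))


def stimulus_amplitude(neuron: NeuronParameters, tau_sp: float) -> float:
    """Maximal stimulation intensity I0 from the charge-balance design.

    A positive pulse of width ``tau_sp`` at intensity ``I0`` moves the
    membrane by one full reset-to-spike-threshold excursion:
    ``I0 = (V_th_spike - V_reset) * C / tau_sp``  (uA/cm^2).
    """
    return (neuron.V_th_spike - neuron.V_reset) * neuron.C / tau_sp


def sigma_from_gamma(gamma: float, L: float) -> float:
    """Spatial SD of the Gaussian electrode profile for target coverage.

    The profile drops to ~1% of its peak at three SDs, so requiring the
    effective footprint ``pi * (3 sigma)^2`` to equal a fraction ``gamma``
    of the ``L x L`` plane gives ``sigma = (1/3) sqrt(gamma / pi) L``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return math.sqrt(gamma / math.pi) * L / 3.0


#: Hard minimum interval between stimulus events on one electrode, ms
#: (corresponds to a 130 Hz ceiling on the per-electrode event rate).
TAU_LAMBDA = 1000.0 / 130.0


@dataclass(frozen=True)
class StimulusParams:
    """Uncorrelated multichannel random stimulation (UMRS) constants.

    ``N_s`` electrodes sit at the quadrant centers of the network plane
    and fire independently.  Each event is a charge-balanced pulse pair:
    a positive rectangle of width ``tau_sp`` and unit amplitude, a gap
    ``tau_sg``, then a negative rectangle of width ``tau_sn`` and
    amplitude ``-tau_sp / tau_sn``.  Event onsets on one electrode are a
    renewal process with interval ``TAU_LAMBDA + Exp(tau_umrs)`` so the
    mean event rate is ``F_s = 1 / (tau_umrs + TAU_LAMBDA)``.
    """

    a_s: float = 1.0        # dimensionless amplitude scale in [0, 1]
    F_s: float = 130.0      # mean per-electrode event rate, Hz
    N_s: int = 4            # electrode count
    tau_sp: float = 0.5     # positive pulse width, ms
    tau_sg: float = 0.2     # gap width, ms
    tau_sn: float = 1.5     # negative pulse width, ms
    gamma: float = 0.2      # target stimulated fraction per electrode

    def __post_init__(self) -> None:
        if not 0.0 <= self.a_s <= 1.0:
            raise ValueError("a_s must lie in [0, 1]")
        if self.F_s <= 0 or self.F_s > 1000.0 / TAU_LAMBDA + 1e-9:
            raise ValueError("F_s must lie in (0, 130] Hz")
        if self.N_s < 1:
            raise ValueError("need at least one electrode")

    @property
    def tau_umrs(self) -> float:
        """Mean of the exponential extra inter-event interval, ms."""
        return max(1000.0 / self.F_s - TAU_LAMBDA, 0.0)

    @property
    def event_width(self) -> float:
        """Total width of one pulse pair, ms."""
        return self.tau_sp + self.tau_sg + self.tau_sn

    @property
    def neg_amplitude(self) -> float:
        """Amplitude of the negative phase enforcing zero net charge."""
        return -self.tau_sp / self.tau_sn
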