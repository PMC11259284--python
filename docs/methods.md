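# Methods

This note records the model as implemented, the numerical choices behind
the integrator, the conventions adopted where the design was genuinely
open, and what the desk-scale test runs do and do not demonstrate.

## Model summary and timescale architecture

Three processes are composed adiabatically:

1. **Spiking** (ms). Conductance-based LIF neurons with a dynamic
   threshold, delayed exponential synapses and Poisson background noise.
   Because the resting potential (−38 mV) lies above the resting
   threshold (−40 mV), an isolated neuron fires tonically; its rate is a
   nearly linear function of the leak conductance under the standing
   noise, which is what makes the calibration regression work.
2. **Weights** (seconds–minutes). Additive STDP with hard bounds
   [0, 1], applied on spike events through accumulating pre- and
   post-synaptic traces (all-to-all pairing). With asymmetry `b = 1.4`
   the rule is depression-dominant in uncorrelated firing, which
   stabilizes a desynchronized attractor; near-coincident volleys in a
   synchronized state potentiate, which stabilizes the synchronized
   attractor. This is the origin of the bistability.
3. **Structure** (hours). A birth–death process applied as discrete
   synchronous updates only once the fast dynamics have converged
   (relative change of ⟨W⟩ and ⟨f⟩ below Υ = 10⁻³ across consecutive
   60 s intervals). Addition is homeostatic (logistic in the slow
   low-pass rate, midpoint f_T − Δf/2) and local (exponential distance
   kernel, scale l₀ = 0.5 L); removal is homeostatic (midpoint
   f_T + Δf/2) plus weight-dependent with hazard `P_w e^{−w/w_min}`,
   which effectively removes only contacts whose weight STDP has driven
   below a few multiples of w_min = 0.001.

## Key parameters

Membrane and synapse constants are the package defaults in
`plastinet.params` (C = 3 µF/cm², V_rest = −38 mV, V_reset = −67 mV,
V_th,rest = −40 mV, V_syn = 0 mV, t_d = 3 ms, τ_th = 5 ms,
τ_syn = τ_spike = 1 ms, κ = 8 mS/cm², f_noise = 20 Hz,
κ_noise = 0.06 mS/cm²). STDP: η = 0.02, τ₊ = 10 ms, τ_R = 4
(dimensionless), b = 1.4. SP: P_h = 0.01, P_w ∈ [0, 1] (regime
dependent), f_T = 4.5 Hz, Δf = 1 Hz, p̃_T = 0.01, w_min = 0.001,
τ_slow = 30 min. Stimulation: pulse widths 0.5 / 0.2 / 1.5 ms,
I₀ = (V_th,spike − V_reset)·C/τ_sp = 402 µA/cm², a hard 7.692 ms floor
between events (130 Hz ceiling), γ = 0.2 stimulated fraction giving
σ_s = (1/3)√(γ/π) L ≈ 0.084 L.

A deliberate reading choice: the depression branch of the pairwise STDP
window is `−η (b/τ_R) e^{−|q|/(τ_R τ₊)}` — amplitude b/τ_R of the
potentiation amplitude, window stretched by τ_R. This is the unique
reading consistent with the trace dynamics (post-synaptic trace decay
constant τ_R τ₊) and with the net area `η τ₊ (1 − b)`; the alternative
(amplitude b·τ_R, window τ₊/τ_R) shares the area but makes depression
~16× stronger at small lags, destroying the synchronized attractor
entirely.

## Integrator

Forward Euler with dt = 0.1 ms (divides τ_spike, t_d and all pulse
sub-durations; a convergence test halves dt and checks the long-run
single-neuron rate moves < 1%). Within a step: (1) deliveries scheduled
for the step's start time are applied — STDP depression using the
post-synaptic trace, then the trace increment, then the conductance kick
κ w/N; (2) Poisson noise events (per-step Bernoulli, realized by
geometric gap sampling, exactly equivalent and much cheaper than one RNG
draw per neuron-step); (3) traces decay to the step end; (4) membranes
and thresholds take an Euler step, crossings fire in neuron-index order
with the spike stamped at the step's end time. Conductances and traces
decay by exact per-step exponential factors, so event-to-event decays
compound as exact powers and the engine's weight updates match the
continuous-time trace solution to rounding error. A spike stamped at t
has its deliveries processed at exactly t + t_d. During the spike clamp
the membrane and threshold are pinned; afterwards the membrane resets to
V_reset while the threshold relaxes from V_th,spike under its own
dynamics (rather than resetting), which is what keeps the threshold
equation dynamical. Stimulation current is not injected into clamped
neurons (their membrane is pinned regardless).

The inner loop is JIT-compiled (numba); a 60 s interval of the
400-neuron network with STDP takes roughly a second on one core. The
delay ring buffer, refractory clocks and traces live on the state object
so consecutive intervals chain bit-exactly.

## Initial conditions and calibration

Membrane potentials start uniform in [V_reset, V_rest], thresholds at
rest, conductances at zero. Initial wiring connects each ordered pair
with probability `c·e^{−l/l₀}` where `c` normalizes the *expected*
density to β₀ (reconciling a prescribed global density with the distance
kernel); initial weights are uniform on the widest mean-preserving
support inside [0, 1]. Lattice jitter is uniform within ±0.05 h per
coordinate (the magnitude and distribution are free choices; "small"
relative to the spacing is the only constraint honored). The ideal
lattice occupies [h/2, L + h/2] per axis and the four electrodes sit at
the quadrant centers of that frame.

Calibration simulates one noise-driven neuron for 500 s at each of 10
equally spaced g_leak values in [0.005, 0.05] mS/cm² and fits an
ordinary least-squares line (the curve is linear to R² > 0.99 on this
grid). Grid size and per-point duration are package choices; the
regression coefficients are then used to draw Gaussian leak conductances
realizing a requested natural-rate mean and SD, clipped to the grid
range with a warning.

## Slow rate filter and structural updates

The SP hazards use the low-pass filtered rate (τ_slow = 30 min), not the
instantaneous rate. Since a relaxation block (2–31 convergence
intervals) is shorter than τ_slow, the filter cannot equilibrate within
one block; it is therefore warm-started at each neuron's empirical rate
over the final relaxation interval of the first structural iteration and
advanced by the exact piecewise-exponential solution thereafter. Pruning
reads the weight at the moment of the structural update. Updates are
synchronous from the pre-update snapshot: a contact born in update n is
first exposed to pruning in update n + 1, and an ordered pair changes by
at most one contact per update. New contacts receive uniform weights on
[0, 0.2] when STDP is active (they must earn strength) and on [0, 1]
under homeostatic-only evolution. `P_w` acts only in the full
STDP+SP regime; the prune probability is capped at 1.

## Measures

Spike phases interpolate linearly by 2π between consecutive spikes; the
order parameter time-averages the modulus of the population mean phase
factor over a trailing 2 s window sampled at 1 ms (the window length is
a package default — the measure is insensitive to it in steady states,
and halving the sampling step moves R by < 10⁻³). Neurons without a
defined phase at an instant are excluded from that instant's mean.
Population rates for convergence and summaries are spike counts over the
measurement interval (the slow filter serves only the SP hazards).
Neurons with no incoming contacts are excluded from the mean-weight
average. The network density is reported as E/(N(N−1)) so an all-to-all
graph has density 1; per-neuron degree densities are degree/N.
Assortativity is the edge-wise Pearson correlation of endpoint degrees
(population normalization), reported as missing when an endpoint degree
sequence is constant; it cross-checks against networkx's degree Pearson
coefficient.

## Stimulation

UMRS delivers independent per-electrode trains of charge-balanced pulse
pairs (positive 0.5 ms at amplitude 1, 0.2 ms gap, negative 1.5 ms at
−1/3), onsets a renewal process with a 7.692 ms floor plus exponential
excess, mean rate F_s. Pulse phases snap to the dt grid, so the
discretized event integrates to exactly zero charge for grid-aligned
onsets. "Interval" means onset-to-onset; an event (2.2 ms) always ends
before the floor elapses. The spatial profile is a Gaussian of SD σ_s
around each electrode and electrode currents add linearly. The
stimulation protocol runs pre/stimulus/post epochs with STDP active and
structure frozen; the outcome is classified by the final post-epoch
order parameter against a 0.3 threshold (the synchronized and
desynchronized outcomes are strongly bimodal, so the exact cutoff is not
delicate). The post epoch defaults to a scaled 5–10 minutes of simulated
time, long enough for the weight dynamics to commit to an attractor.

## Desk-scale conventions in the tests

Test and acceptance runs shrink the problem, never the model: reduced
convergence patience (n_min = 10 instead of 60 for frozen-structure
steady states; 2–4 intervals of 10–15 s inside structural loops),
10 × 10 networks for structural-equilibrium direction checks, and 1–2
realizations instead of 10. Consequences to keep in mind:

* Scaled structural runs reproduce *directions* (density falls
  monotonically with P_w; synchronized networks out-dense desynchronized
  ones under strong pruning; faster-onto-slower contacts outlive the
  reverse) but not the published equilibrium densities, which require
  hundreds of full-length iterations at N = 400 — and at N = 100 the
  per-contact coupling κ/N is 4× stronger, shifting equilibria.
* Contact-lifetime statements are made as per-iteration pruning hazards
  split by the sign of the natural-rate mismatch, computed by replaying
  the structural event log; raw mean lifetimes of pruned contacts in a
  short window are censoring-biased (long-lived contacts rarely die
  inside the window) and can invert the comparison.
* The synthetic inputs are the model's own: there is no external data.
  Passing tests show the implementation realizes this model's
  phenomenology at desk scale, not that the model describes any
  particular biological recording.

## Known limitations

One contact at most per ordered pair (the data model reserves a
multi-contact extension; no dynamics are implemented for it). No
inhibition, no periodic boundaries, no event-driven integration, no
multiplicative or triplet STDP. The two-neuron toy with full-strength
mutual excitation locks anti-phase (delayed excitatory reverberation),
so in-phase synchrony should be studied at network scale. Long-run
structural equilibria at published scale are reachable with this code
but need hours of compute; the shipped tests check their direction at
reduced scale instead.
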