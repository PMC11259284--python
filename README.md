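# plastinet

Desk-scale simulation of **adaptive spiking neuronal networks** in which
three processes co-evolve on separated timescales: sub-second spiking of
excitatory conductance-based leaky integrate-and-fire (LIF) neurons,
minutes-scale synaptic weight changes under additive spike-timing-dependent
plasticity (STDP), and hours-scale rewiring under a stochastic
structural-plasticity (SP) birth–death process. The package is aimed at
computational neuroscientists studying pathological neural synchrony — of
the kind implicated in Parkinson's disease — and the design of
desynchronizing stimulation: it reproduces the bistability of synchronized
and desynchronized attractors, the structural reorganization that makes
synchrony cheaper in contacts, and the long-term desynchronization induced
by charge-balanced multichannel random stimulation (UMRS).

## Model

`N = m × m` neurons sit on a jittered square lattice with spacing
`h = L/(m−1)`. Each membrane obeys

```
C dV_i/dt = g_leak,i (V_rest − V_i) + g_syn,i (V_syn − V_i) + I_stim,i + I_noise,i
```

with a dynamic threshold `τ_th dV_th,i/dt = V_th,rest − V_th,i`. A
threshold crossing clamps `V = V_spike`, `V_th = V_th,spike` for
`τ_spike`, then resets the membrane to `V_reset`; because
`V_rest > V_th,rest`, every neuron is intrinsically tonic and its *natural
rate* is set by `g_leak,i` (calibrated by simulation and a linear fit
`f = α₁ g_leak + α₂`). Each spike of presynaptic neuron `j` increments
`g_syn,i` of its targets by `κ A_ij w_ij / N` after a delay `t_d`, and the
conductance decays with `τ_syn`; independent 20 Hz Poisson trains provide
background noise.

Weights of existing contacts follow additive STDP with all-to-all spike
pairing via traces: a pre-before-post pair at lag `q` potentiates by
`η e^{−q/τ₊}`, a post-before-pre pair depresses by
`η (b/τ_R) e^{−|q|/(τ_R τ₊)}`, so the rule integrates to
`η τ₊ (1 − b)` (depression-dominant for `b = 1.4`). Structure evolves by
discrete birth–death updates applied only after the fast dynamics reach a
meta-steady state (the adiabatic approximation): a missing contact onto
neuron `i` appears with probability
`P_h G(f_i, f_−, −ν) e^{−l_ij/l₀}` and a live contact dies with
probability `P_w e^{−w_ij/w_min} + P_h G(f_i, f₊, ν)`, where `G` is a
logistic function of the slowly filtered postsynaptic rate and
`f_± = f_T ± Δf/2` straddle the homeostatic target rate.

Observables include the Kuramoto order parameter `R` from interpolated
spike phases, population rate statistics and their CV, mean synaptic
weight `⟨W⟩`, node-degree densities, the four directed degree
assortativity coefficients, degree–frequency correlations, and contact
lifetime statistics.

## Worked example

`examples/02_stdp_synchronization.py` relaxes the same 400-neuron wiring
(`β₀ = 0.105`, `σ_f = 0.5 Hz`) from strong and from weak initial weights:

```
<W>0=0.80: R=0.91  rate=4.58 Hz  CV=0.032  <W>=0.58
<W>0=0.05: R=0.13  rate=3.06 Hz  CV=0.163  <W>=0.02
-> same wiring, two attractors: R ~ 0.9 is the synchronized (pathological)
   state, R < 0.3 the desynchronized one
```

STDP amplifies whichever state it starts near: strong initial coupling
locks the population into synchronized ~4.5 Hz firing (order parameter
0.91), weak initial coupling collapses the weights and leaves incoherent
~3 Hz firing at each neuron's natural rate.

The other examples calibrate the leak-conductance/rate map
(`01_calibrate_leak_conductance.py`), grow a network from unconnected
neurons by homeostatic SP (`03_structural_growth.py`), reorganize a
synchronized network with weight-dependent pruning and measure the
emerging degree–frequency correlations (`04_pruning_reorganization.py`),
and desynchronize a synchronized network long-term with a two-minute UMRS
stimulus (`05_desynchronizing_stimulation.py`).

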