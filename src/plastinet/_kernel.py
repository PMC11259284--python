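"""Numba inner loop of the network integrator.

One call advances the coupled membrane/threshold/conductance equations
by ``n_steps`` forward-Euler steps of size ``dt``.  All mutable state
(membrane variables, STDP traces, the synaptic delay ring buffer and the
weight matrix) is passed in as arrays and updated in place so that
consecutive calls chain seamlessly across measurement intervals.

Time convention: the state arrays hold values at the *start* of a step.
A threshold crossing detected while integrating step ``s`` is stamped at
the step's end time ``t0 + (s + 1) dt``; its deliveries are scheduled
``delay_steps`` later, which lands them exactly ``t_d`` after the stamp.
Traces and conductances decay once per step, so event-to-event decay
factors compound exactly as powers of ``exp(-dt / tau)``.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_network(
    # mutable state (updated in place)
    V, Vth, gsyn, gnoise, refr,
    A, W, chi, psi,
    ring, ring_count,
    # static per-neuron
    gleak,
    # integration plan
    n_steps, dt, t0, ring_pos,
    # neuron constants
    C, V_rest, V_reset, V_th_rest, V_syn, V_spike, V_th_spike,
    tau_th, spike_steps, delay_steps,
    kappa, dec_syn, p_noise, kappa_noise,
    # stdp constants
    stdp_on, eta, etabR, dec_chi, dec_psi,
    # stimulation (per-step electrode amplitudes and per-neuron gains)
    stim_on, stim_x, stim_gain,
    # forced spikes (sorted by step index, end-of-step convention)
    forced_step, forced_neuron,
    # rng
    seed,
    # outputs
    spike_neuron, spike_time,
):
    np.random.seed(seed)
    N = V.shape[0]
    slots = ring.shape[0]
    kappa_over_N = kappa / N
    n_spikes = 0
    cap = spike_neuron.shape[0]
    overflow = 0
    n_forced = forced_step.shape[0]
    fptr = 0

    # geometric gap sampling replicates an independent per-step Bernoulli
    # noise event of probability p_noise without one RNG draw per step
    next_noise = np.empty(N, dtype=np.int64)
    if p_noise > 0.0:
        lg = np.log(1.0 - p_noise)
        for i in range(N):
            u = np.random.random()
            next_noise[i] = int(np.log(u) / lg)
    else:
        for i in range(N):
            next_noise[i] = n_steps + 1

    istim = np.zeros(N)

    for s in range(n_steps):
        # 1) synaptic deliveries scheduled for this step (time t0 + s*dt)
        cur = (ring_pos + s) % slots
        cnt = ring_count[cur]
        for idx in range(cnt):
            j = ring[cur, idx]
            if stdp_on:
                for i in range(N):
                    if A[i, j] == 1:
                        w = W[i, j] - etabR * psi[i]
                        if w < 0.0:
                            w = 0.0
                        W[i, j] = w
                chi[j] += 1.0
            for i in range(N):
                if A[i, j] == 1:
                    gsyn[i] += kappa_over_N * W[i, j]
        ring_count[cur] = 0

        # 2) Poisson background noise events at the step start
        if p_noise > 0.0:
            lg = np.log(1.0 - p_noise)
            for i in range(N):
                while next_noise[i] == s:
                    gnoise[i] += kappa_noise
                    u = np.random.random()
                    next_noise[i] += 1 + int(np.log(u) / lg)

        # 3) stimulation current for this step
        if stim_on:
            for i in range(N):
                istim[i] = 0.0
            for r in range(stim_x.shape[1]):
                x = stim_x[s, r]
                if x != 0.0:
                    for i in range(N):
                        istim[i] += x * stim_gain[i, r]

        # traces advance to the step end before spike detection
        if stdp_on:
            for i in range(N):
                chi[i] *= dec_chi
                psi[i] *= dec_psi

        # 4) Euler step and threshold crossings (end-of-step spike times)
        for i in range(N):
            if refr[i] > 0:
                refr[i] -= 1
                if refr[i] == 0:
                    V[i] = V_reset
            else:
                g_exc = gsyn[i] + gnoise[i]
                I = gleak[i] * (V_rest - V[i]) + g_exc * (V_syn - V[i])
                if stim_on:
                    I += istim[i]
                V[i] += dt / C * I
                Vth[i] += dt / tau_th * (V_th_rest - Vth[i])
                fire = V[i] >= Vth[i]
                if not fire and fptr < n_forced and forced_step[fptr] == s:
                    # forced spikes are sorted; scan entries for this step
                    k = fptr
                    while k < n_forced and forced_step[k] == s:
                        if forced_neuron[k] == i:
                            fire = True
                            break
                        k += 1
                if fire:
                    if n_spikes < cap:
                        spike_neuron[n_spikes] = i
                        spike_time[n_spikes] = t0 + (s + 1) * dt
                        n_spikes += 1
                    else:
                        overflow = 1
                    if stdp_on:
                        for j in range(N):
                            if A[i, j] == 1:
                                w = W[i, j] + eta * chi[j]
                                if w > 1.0:
                                    w = 1.0
                                W[i, j] = w
                        psi[i] += 1.0
                    V[i] = V_spike
                    Vth[i] = V_th_spike
                    refr[i] = spike_steps
                    slot = (ring_pos + s + 1 + delay_steps) % slots
                    c = ring_count[slot]
                    if c < N:
                        ring[slot, c] = i
                        ring_count[slot] = c + 1
            # conductances decay over the step after entering the derivative
            gsyn[i] *= dec_syn
            gnoise[i] *= dec_syn

        while fptr < n_forced and forced_step[fptr] == s:
            fptr += 1

    return n_spikes, overflow, (ring_pos + n_steps) % slots
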