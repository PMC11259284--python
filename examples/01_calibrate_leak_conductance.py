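"""Calibrate the map from leak conductance to natural firing rate.

An unconnected neuron fires tonically at a rate set by its leak
conductance g_leak (under 20 Hz Poisson background noise of intensity
0.06 mS/cm^2).  We tabulate the rate on a grid, fit a straight line
f = alpha1 * g_leak + alpha2, and invert it to draw per-neuron leak
conductances that realize a requested rate distribution.
"""

import numpy as np

import plastinet as pn

calib = pn.fit_rate_curve(duration=200_000.0, rng_seed=1)
print("g_leak grid (mS/cm^2):", np.round(calib.grid, 4))
print("simulated rates (Hz): ", np.round(calib.rates, 2))
print(f"fit: f = {calib.alpha1:.2f} * g_leak + {calib.alpha2:.2f}")

# draw leaks for a population with mean 3 Hz and SD 0.5 Hz
g = pn.sample_gleak(3.0, 0.5, calib, N=400, rng_seed=2)
print(f"sampled g_leak: mean {g.mean():.5f}, SD {g.std():.5f} mS/cm^2")
print("-> the slope says each 0.01 mS/cm^2 of leak adds about "
      f"{calib.alpha1 * 0.01:.2f} Hz of natural firing rate")
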