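"""Mapping natural firing rates to leak conductances.

An unconnected neuron fires tonically at a rate set by its leak
conductance (under the standing Poisson background noise).  To build a
network whose unconnected ("natural") rates are Gaussian with mean
``f0`` and SD ``sigma_f``, the single-neuron rate curve ``f(g_leak)`` is
simulated on a grid, fitted by a straight line
``f = alpha1 * g_leak + alpha2``, and inverted: ``g_leak`` is drawn
Gaussian with mean ``(f0 - alpha2) / alpha1`` and SD
``sigma_f / alpha1``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectivity import empty_connectivity
from .dynamics import init_state, integrate_interval
from .params import NeuronParameters

#: calibrated leak-conductance grid range, mS/cm^2
GRID_LO, GRID_HI = 0.005, 0.05


@dataclass
class CalibrationResult:
    alpha1: float               # slope, Hz per mS/cm^2
    alpha2: float               # intercept, Hz
    grid: np.ndarray            # tabulated g_leak values
    rates: np.ndarray           # simulated long-time rates, Hz
    kappa_noise: float
    f_noise: float
    seed: int | None = None

    def g_leak_for_rate(self, f: float) -> float:
        return (f - self.alpha2) / self.alpha1

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "alpha1": self.alpha1,
                    "alpha2": self.alpha2,
                    "grid": list(map(float, self.grid)),
                    "rates": list(map(float, self.rates)),
                    "kappa_noise": self.kappa_noise,
                    "f_noise": self.f_noise,
                    "seed": self.seed,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            alpha1=d["alpha1"],
            alpha2=d["alpha2"],
            grid=np.asarray(d["grid"]),
            rates=np.asarray(d["rates"]),
            kappa_noise=d["kappa_noise"],
            f_noise=d["f_noise"],
            seed=d.get("seed"),
        )


def single_neuron_rate(
    g_leak: float,
    duration: float = 500_000.0,
    rng_seed: int = 0,
    params: NeuronParameters = NeuronParameters(),
    dt: float = 0.1,
) -> float:
    """Long-time firing rate (Hz) of one isolated noise-driven neuron."""
    state = init_state(np.array([g_leak]), params, rng_seed=rng_seed)
    conn = empty_connectivity(1)
    raster = integrate_interval(
        state,
        conn,
        params,
        duration=duration,
        dt=dt,
        rng_seed=rng_seed,
        spike_capacity_hz=200.0,
    )
    n = raster.n_spikes
    if n < 100:
        warnings.warn(
            f"only {n} spikes at g_leak={g_leak}; rate estimate is unstable",
            stacklevel=2,
        )
    return n / (duration / 1000.0)


def fit_rate_curve(
    grid: np.ndarray | None = None,
    duration: float = 500_000.0,
    rng_seed: int = 0,
    params: NeuronParameters = NeuronParameters(),
    dt: float = 0.1,
) -> CalibrationResult:
    """Simulate the rate curve on a g_leak grid and fit it by OLS.

    The default grid is 10 equally spaced points spanning the calibrated
    range [0.005, 0.05] mS/cm^2 with 500 s simulated per point.
    """
    if grid is None:
        grid = np.linspace(GRID_LO, GRID_HI, 10)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.ptp(grid) == 0:
        raise ValueError("need at least two distinct grid points")
    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(grid.size)
    rates = np.array(
        [
            single_neuron_rate(
                g, duration=duration, rng_seed=int(s) % (2**31 - 1),
                params=params, dt=dt,
            )
            for g, s in zip(grid, seeds)
        ]
    )
    alpha1, alpha2 = np.polyfit(grid, rates, 1)
    return CalibrationResult(
        alpha1=float(alpha1),
        alpha2=float(alpha2),
        grid=grid,
        rates=rates,
        kappa_noise=params.kappa_noise,
        f_noise=params.f_noise,
        seed=rng_seed,
    )


def sample_gleak(
    f0: float,
    sigma_f: float,
    calib: CalibrationResult,
    N: int,
    rng_seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-neuron leak conductances for target rate statistics.

    Draws are i.i.d. Gaussian with mean ``(f0 - alpha2) / alpha1`` and SD
    ``sigma_f / alpha1``, clipped to the calibrated grid range (with a
    warning if any draw clips).  ``sigma_f = 0`` yields identical
    neurons.
    """
    if sigma_f < 0:
        raise ValueError("sigma_f must be non-negative")
    mean = calib.g_leak_for_rate(f0)
    lo, hi = calib.grid.min(), calib.grid.max()
    if not lo <= mean <= hi:
        raise ValueError(
            f"target mean rate {f0} Hz maps to g_leak={mean:.4g} outside "
            f"the calibrated range [{lo}, {hi}]"
        )
    rng = np.random.default_rng(rng_seed)
    g = np.full(N, mean) if sigma_f == 0 else rng.normal(
        mean, sigma_f / calib.alpha1, size=N
    )
    clipped = (g < lo) | (g > hi)
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} of {N} leak draws clipped to the "
            "calibrated range",
            stacklevel=2,
        )
        g = np.clip(g, lo, hi)
    return g
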