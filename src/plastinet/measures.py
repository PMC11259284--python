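"""Dynamical and structural observables of the network.

Synchrony is quantified by the Kuramoto order parameter computed from
spike-phase interpolation: between consecutive spikes of a neuron its
phase advances linearly by 2 pi, the population's mean unit phase vector
is averaged over a trailing window, and the modulus is time-averaged.
Structure is summarized by node degree densities (degree / N), the four
directed degree-assortativity coefficients (edge-wise Pearson
correlations of endpoint degrees), and degree-frequency correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityState
from .dynamics import SpikeRaster


@dataclass
class NetworkSummary:
    R: float            # order parameter in [0, 1]
    mean_rate: float    # network-averaged firing rate, Hz
    cv_rate: float      # population CV of rates (NaN if mean rate is 0)
    mean_weight: float  # network-averaged incoming weight
    beta: float         # network-averaged node degree density
    window: float       # measurement window, ms


def phase_interpolation(
    spike_times: np.ndarray, sample_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear spike phase and its validity mask.

    The phase advances by exactly 2 pi between consecutive spikes.  It is
    undefined before the first and after the last spike; those samples
    are masked out.
    """
    t = np.asarray(spike_times, dtype=float)
    phases = np.zeros_like(sample_times, dtype=float)
    if t.size < 2:
        return phases, np.zeros_like(sample_times, dtype=bool)
    valid = (sample_times >= t[0]) & (sample_times <= t[-1])
    phases[valid] = np.interp(
        sample_times[valid], t, 2.0 * np.pi * np.arange(t.size)
    )
    return phases, valid


def order_parameter(
    raster: SpikeRaster,
    N: int,
    t: float,
    window: float = 2000.0,
    sample_step: float = 1.0,
) -> float:
    """Time-averaged modulus of the population mean phase factor.

    Averages ``|mean_i exp(i phi_i(t'))|`` over ``t' in [t - window, t]``
    on a grid of ``sample_step`` ms.  Neurons whose phase is undefined at
    an instant (no bracketing spikes) are excluded from the population
    mean at that instant; instants where no neuron has a defined phase
    contribute zero.  Returns a value in [0, 1]: identical spike trains
    give 1, a splay state gives ~0.
    """
    samples = np.arange(t - window, t + sample_step / 2, sample_step)
    acc = np.zeros(samples.shape, dtype=complex)
    count = np.zeros(samples.shape, dtype=int)
    trains = raster.per_neuron(N)
    for times in trains:
        ph, valid = phase_interpolation(times, samples)
        acc[valid] += np.exp(1j * ph[valid])
        count[valid] += 1
    mod = np.zeros(samples.shape)
    nz = count > 0
    mod[nz] = np.abs(acc[nz]) / count[nz]
    return float(mod.mean())


def rate_and_cv(
    raster: SpikeRaster, interval: float, N: int
) -> tuple[float, float, np.ndarray]:
    """Per-neuron empirical rates over the interval, their mean and CV.

    Rates are spike counts divided by ``interval`` (ms), in Hz.  The CV
    is the population standard deviation over the population mean; it is
    NaN when the mean rate is zero.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    rates = raster.counts(N) / (interval / 1000.0)
    mean = float(rates.mean())
    cv = float(rates.std() / mean) if mean > 0 else float("nan")
    return mean, cv, rates


def mean_weights(conn: ConnectivityState) -> tuple[float, np.ndarray]:
    """Network-averaged and per-neuron average incoming synaptic weight.

    ``W_i`` is the mean weight over neuron i's live incoming contacts,
    NaN for neurons with no incoming contact; such neurons are excluded
    from the network average.
    """
    live = conn.adjacency == 1
    indeg = live.sum(axis=1)
    wsum = np.where(live, conn.weights, 0.0).sum(axis=1)
    W_i = np.full(conn.N, np.nan)
    nz = indeg > 0
    W_i[nz] = wsum[nz] / indeg[nz]
    mean = float(np.nanmean(W_i)) if nz.any() else float("nan")
    return mean, W_i


def node_degree_densities(
    conn: ConnectivityState,
) -> tuple[np.ndarray, np.ndarray, float]:
    """In- and out-degree densities (degree / N) and the mean density.

    The network average ``beta`` is reported as ``E / (N (N - 1))`` so
    that an all-to-all graph has beta = 1.
    """
    live = conn.adjacency == 1
    beta_in = live.sum(axis=1) / conn.N
    beta_out = live.sum(axis=0) / conn.N
    return beta_in, beta_out, conn.density


@dataclass
class AssortativityResult:
    """Four edge-wise Pearson coefficients indexed (pre-type, post-type)."""

    rho: dict  # keys ("in"|"out", "in"|"out") -> float or NaN
    E: int


def degree_assortativity(conn: ConnectivityState) -> AssortativityResult:
    """Directed degree assortativity via edge-wise Pearson correlation.

    For each directed contact ``e`` from ``j`` (pre) to ``i`` (post) and
    each pair of degree types, correlate the pre-endpoint degree with the
    post-endpoint degree over all contacts, normalizing by ``E`` (the
    population convention).  A coefficient is NaN when either endpoint
    degree sequence is constant over the edges.
    """
    post, pre = np.nonzero(conn.adjacency)
    E = post.size
    if E < 2:
        raise ValueError("need at least 2 contacts for assortativity")
    indeg = (conn.adjacency == 1).sum(axis=1)
    outdeg = (conn.adjacency == 1).sum(axis=0)
    deg = {"in": indeg, "out": outdeg}
    rho = {}
    for eps in ("in", "out"):
        for ups in ("in", "out"):
            U = deg[eps][pre].astype(float)
            V = deg[ups][post].astype(float)
            sU = U.std()
            sV = V.std()
            if sU == 0 or sV == 0:
                rho[(eps, ups)] = float("nan")
            else:
                rho[(eps, ups)] = float(
                    ((U - U.mean()) * (V - V.mean())).mean() / (sU * sV)
                )
    return AssortativityResult(rho=rho, E=int(E))


def degree_frequency_correlation(
    conn: ConnectivityState, natural_rates: np.ndarray
) -> tuple[float, float]:
    """Pearson correlations of (in-NDD, f_nat) and (out-NDD, f_nat)."""
    beta_in, beta_out, _ = node_degree_densities(conn)
    f = np.asarray(natural_rates, dtype=float)

    def _corr(a, b):
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    return _corr(beta_in, f), _corr(beta_out, f)


def relative_change(a: float, b: float) -> float:
    """Symmetric relative difference ``2 |a - b| / (a + b)``; 0 if both 0."""
    if a == 0.0 and b == 0.0:
        return 0.0
    return 2.0 * abs(a - b) / (a + b)


def convergence_test(
    series_W,
    series_f,
    upsilon: float = 1e-3,
    n_min: int = 2,
    n_max: int = 31,
) -> tuple[bool, int]:
    """Steady-state test on consecutive-interval averages.

    Scans interval pairs ``(n, n + 1)`` (1-based) and declares
    convergence at the first ``n >= n_min`` where the symmetric relative
    differences of both the mean weight and the mean rate fall below
    ``upsilon``.  Returns ``(converged, n)``; ``n`` is ``n_max`` when the
    scan exhausts the series without converging.
    """
    W = list(series_W)
    f = list(series_f)
    last = min(len(W), len(f)) - 1
    for n in range(n_min, min(last, n_max - 1) + 1):
        dW = relative_change(W[n - 1], W[n])
        df = relative_change(f[n - 1], f[n])
        if dW < upsilon and df < upsilon:
            return True, n
    return False, n_max


def weight_fraction_below(conn: ConnectivityState, threshold: float = 0.1) -> float:
    """Fraction of live contact weights below ``threshold``.

    Used to compare weight-distribution shapes across plasticity regimes
    (weight-dependent pruning depletes the near-zero mode).
    """
    live = conn.adjacency == 1
    w = conn.weights[live]
    if w.size == 0:
        return float("nan")
    return float((w < threshold).mean())
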