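"""Directed connectivity state and its construction and serialization.

The connectivity of the network is a dense ``N x N`` adjacency matrix
``A`` (``A[i, j] = 1`` for a contact from presynaptic ``j`` onto
postsynaptic ``i``) together with a weight matrix ``W`` whose entries
are meaningful only where ``A`` is 1, and a birth-time table recording
the structural-update iteration at which each live contact appeared.
One contact at most is allowed per ordered pair; dense storage is the
natural choice at the few-hundred-neuron scale this model targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import NetworkGeometry


@dataclass
class ConnectivityState:
    adjacency: np.ndarray   # (N, N) uint8, A[i, j]: contact j -> i
    weights: np.ndarray     # (N, N) float64 in [0, 1] where adjacency == 1
    birth_time: np.ndarray  # (N, N) int64, SP iteration of creation (-1 dead)
    max_contacts: int = 1

    @property
    def N(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_contacts(self) -> int:
        return int(self.adjacency.sum())

    @property
    def density(self) -> float:
        """Network-averaged node degree density beta = E / (N (N - 1))."""
        n = self.N
        return self.n_contacts / (n * (n - 1))

    def validate(self) -> None:
        a = self.adjacency
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        live = a == 1
        w = self.weights[live]
        if w.size and (w.min() < 0 or w.max() > 1):
            raise ValueError("live weights must lie in [0, 1]")

    def copy(self) -> "ConnectivityState":
        return ConnectivityState(
            adjacency=self.adjacency.copy(),
            weights=self.weights.copy(),
            birth_time=self.birth_time.copy(),
            max_contacts=self.max_contacts,
        )


def empty_connectivity(N: int) -> ConnectivityState:
    return ConnectivityState(
        adjacency=np.zeros((N, N), dtype=np.uint8),
        weights=np.zeros((N, N), dtype=np.float64),
        birth_time=np.full((N, N), -1, dtype=np.int64),
    )


def random_connectivity(
    geometry: NetworkGeometry,
    beta0: float,
    l0: float | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> ConnectivityState:
    """Wire a distance-modulated random graph at a prescribed density.

    Each ordered pair ``(i, j)``, ``i != j``, is connected independently
    with probability ``c * exp(-l_ij / l0)``.  The constant ``c`` is set
    so the *expected* density equals ``beta0``, reconciling the desired
    global density with the exponential distance falloff.  With
    ``l0 = None`` the kernel is flat and every pair connects with
    probability ``beta0`` exactly.
    """
    if not 0.0 <= beta0 <= 1.0:
        raise ValueError("beta0 must lie in [0, 1]")
    N = geometry.N
    rng = np.random.default_rng(rng_seed)
    off = ~np.eye(N, dtype=bool)

    if l0 is None:
        p = np.full((N, N), beta0)
    else:
        if l0 <= 0:
            raise ValueError("l0 must be positive")
        kernel = np.exp(-geometry.distance / l0)
        mean_kernel = kernel[off].mean()
        c = beta0 / mean_kernel
        p = c * kernel
        if beta0 > 0 and p[off].max() > 1.0 + 1e-12:
            raise ValueError(
                "requested density beta0=%g not achievable with the "
                "exponential distance kernel (some pair probabilities "
                "exceed 1); increase l0 or lower beta0" % beta0
            )
    p = np.clip(p, 0.0, 1.0)
    adjacency = (rng.random((N, N)) < p) & off
    conn = empty_connectivity(N)
    conn.adjacency = adjacency.astype(np.uint8)
    conn.birth_time[adjacency] = 0
    return conn


def init_weights(
    conn: ConnectivityState,
    mean_weight: float,
    rng_seed: int | np.random.Generator = 0,
) -> ConnectivityState:
    """Assign initial weights to live contacts with the requested mean.

    Weights are drawn uniform on ``[max(0, 2 m - 1), min(1, 2 m)]`` for a
    mean ``m`` — the widest mean-preserving uniform support inside
    ``[0, 1]``.  Dead entries are untouched.
    """
    if not 0.0 <= mean_weight <= 1.0:
        raise ValueError("mean_weight must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    lo = max(0.0, 2.0 * mean_weight - 1.0)
    hi = min(1.0, 2.0 * mean_weight)
    live = conn.adjacency == 1
    n_live = int(live.sum())
    conn.weights[live] = rng.uniform(lo, hi, size=n_live)
    return conn


def save_snapshot(
    conn: ConnectivityState,
    geometry: NetworkGeometry,
    path: str | Path,
    g_leak: np.ndarray | None = None,
    parameters: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a network snapshot: TSV edge list plus a JSON sidecar.

    The edge list has columns (pre_index, post_index, weight,
    birth_iteration) with weights at full float precision so a
    round-trip is lossless.  Positions, per-neuron leak conductances and
    free-form parameters go into ``<path>.json``.
    """
    path = Path(path)
    post, pre = np.nonzero(conn.adjacency)
    with open(path, "w") as fh:
        fh.write("pre_index\tpost_index\tweight\tbirth_iteration\n")
        for i, j in zip(post, pre):
            fh.write(
                f"{j}\t{i}\t{float(conn.weights[i, j])!r}\t"
                f"{int(conn.birth_time[i, j])}\n"
            )
    sidecar = {
        "m": geometry.m,
        "L": geometry.L,
        "jitter_scale": geometry.jitter_scale,
        "positions": geometry.positions.tolist(),
        "g_leak": None if g_leak is None else list(map(float, g_leak)),
        "parameters": parameters or {},
        "seed": seed,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def load_snapshot(path: str | Path):
    """Read a snapshot written by :func:`save_snapshot`.

    Returns ``(geometry, connectivity, sidecar_dict)``; ``sidecar_dict``
    retains ``g_leak``, ``parameters`` and ``seed`` as stored.
    """
    from .geometry import NetworkGeometry

    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    positions = np.asarray(sidecar["positions"], dtype=np.float64)
    m = int(sidecar["m"])
    L = float(sidecar["L"])
    diff = positions[:, None, :] - positions[None, :, :]
    geometry = NetworkGeometry(
        m=m,
        L=L,
        h=L / (m - 1),
        jitter_scale=float(sidecar["jitter_scale"]),
        positions=positions,
        distance=np.sqrt((diff**2).sum(axis=2)),
    )
    conn = empty_connectivity(m * m)
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("pre_index")
        for line in fh:
            pre_s, post_s, w_s, birth_s = line.split()
            i, j = int(post_s), int(pre_s)
            conn.adjacency[i, j] = 1
            conn.weights[i, j] = float(w_s)
            conn.birth_time[i, j] = int(birth_s)
    return geometry, conn, sidecar
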