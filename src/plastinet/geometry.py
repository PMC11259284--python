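"""Spatial layout of the network: a jittered square lattice.

Neurons are placed on an ``m x m`` lattice filling an ``L x L`` plane.
Lattice index ``(ix, iy)`` (1-based in the scientific notation, 0-based
in code) maps to flat index ``i = ix + iy * m`` and to coordinates
``(h/2) * (2 ix - 1) + jitter`` with spacing ``h = L / (m - 1)``.
Distances between neurons modulate both the initial wiring and the
structural-plasticity addition probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NetworkGeometry:
    m: int                  # lattice side count; N = m * m
    L: float                # physical side length
    h: float                # lattice spacing, L / (m - 1)
    jitter_scale: float     # bound of the uniform positional jitter
    positions: np.ndarray   # (N, 2) coordinates
    distance: np.ndarray    # (N, N) symmetric Euclidean distance table

    @property
    def N(self) -> int:
        return self.positions.shape[0]


def place_neurons(
    m: int,
    L: float = 1.0,
    jitter_scale: float | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> NetworkGeometry:
    """Place ``m * m`` neurons on a jittered square lattice.

    Parameters
    ----------
    m
        Lattice side count; must be at least 2 so the spacing is defined.
    L
        Side length of the square plane.
    jitter_scale
        Per-coordinate jitters are drawn i.i.d. uniform in
        ``[-jitter_scale, +jitter_scale]``.  Defaults to ``0.05 * h``,
        small relative to the spacing.  Pass 0 for the exact lattice.
    rng_seed
        Integer seed or a ``numpy`` Generator.
    """
    if m < 2:
        raise ValueError("m must be >= 2 (lattice spacing undefined for m < 2)")
    if L <= 0:
        raise ValueError("L must be positive")
    h = L / (m - 1)
    if jitter_scale is None:
        jitter_scale = 0.05 * h
    if jitter_scale < 0:
        raise ValueError("jitter_scale must be non-negative")

    rng = np.random.default_rng(rng_seed)
    ix, iy = np.meshgrid(np.arange(1, m + 1), np.arange(1, m + 1))
    # iy varies slowest: flat index i = ix + (iy - 1) * m in 1-based terms
    x = (h / 2.0) * (2.0 * ix.ravel() - 1.0)
    y = (h / 2.0) * (2.0 * iy.ravel() - 1.0)
    positions = np.column_stack([x, y])
    if jitter_scale > 0:
        positions = positions + rng.uniform(
            -jitter_scale, jitter_scale, size=positions.shape
        )

    diff = positions[:, None, :] - positions[None, :, :]
    distance = np.sqrt((diff**2).sum(axis=2))
    return NetworkGeometry(
        m=m,
        L=L,
        h=h,
        jitter_scale=jitter_scale,
        positions=positions,
        distance=distance,
    )
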