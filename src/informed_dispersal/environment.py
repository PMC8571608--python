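"""Temporally autocorrelated patch environment.

Each of the ``n_patches`` breeding patches carries an independent,
unitless environmental quality ``Q`` that follows a stationary AR(1)
process: at ``t = 0`` quality is drawn from ``N(0, sigma)``; afterwards

    Q_{t+1} = autocorr * Q_t + w_t * sqrt(1 - autocorr**2)

with a fresh innovation ``w_t ~ N(0, sigma)`` per patch and year.  The
``sqrt(1 - autocorr**2)`` scaling makes the marginal variance of ``Q``
equal to ``sigma**2`` at every time, so changing the autocorrelation
coefficient changes predictability without changing the amplitude of
fluctuations.

Quality drives the patch carrying capacity linearly,

    K = max(0, K0 + K0 * Q),

clamped at zero (a patch can be momentarily uninhabitable).  ``Q``
itself is never clamped.  ``K`` is kept real-valued; the demographic
density dependence divides by it directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EnvironmentGrid:
    """Per-patch environmental quality and carrying capacity.

    Parameters
    ----------
    n_patches
        Number of discrete breeding patches (flat index 0..n_patches-1;
        patch positions carry no spatial meaning, so no geometry is stored).
    sigma
        Standard deviation of the innovation distribution (and, by the
        stationary scaling, of quality itself). Must be >= 0.
    autocorr
        Temporal autocorrelation coefficient of quality, in [0, 1].
    k0
        Baseline carrying capacity at Q = 0, in individuals. Must be > 0.
    """

    n_patches: int = 25
    sigma: float = 1.0
    autocorr: float = 0.8
    k0: float = 100.0
    q: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not 0.0 <= self.autocorr <= 1.0:
            raise ValueError(f"autocorr must be in [0, 1], got {self.autocorr}")
        if self.k0 <= 0:
            raise ValueError(f"k0 must be > 0, got {self.k0}")

    @property
    def k(self) -> np.ndarray:
        """Current carrying capacities (requires initialized quality)."""
        if self.q is None:
            raise RuntimeError("environment not initialized; call init_quality")
        return carrying_capacity(self.q, self.k0)


def init_quality(grid: EnvironmentGrid, rng: np.random.Generator) -> np.ndarray:
    """Draw the year-0 qualities, one independent N(0, sigma) per patch."""
    grid.q = rng.normal(0.0, grid.sigma, size=grid.n_patches)
    return grid.q


def step_quality(grid: EnvironmentGrid, rng: np.random.Generator) -> np.ndarray:
    """Advance every patch's quality one year under the AR(1) recursion."""
    if grid.q is None:
        raise RuntimeError("environment not initialized; call init_quality")
    w = rng.normal(0.0, grid.sigma, size=grid.n_patches)
    grid.q = grid.autocorr * grid.q + w * np.sqrt(1.0 - grid.autocorr**2)
    return grid.q


def carrying_capacity(q, k0: float):
    """Carrying capacity ``max(0, k0 + k0*Q)``; elementwise on arrays."""
    return np.maximum(0.0, k0 + k0 * np.asarray(q, dtype=float))
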