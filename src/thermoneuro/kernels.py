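"""Time grids, spike rasters, lag functions and spike-timing kernels.

This module holds the shared currency of all the models in the package: binary
firing records ``phi_i(t)`` on a uniform time grid, real functions of the
post-minus-pre spike lag (STDP windows ``Omega(t)``, synaptic response kernels
``lambda_syn(t)``, cross-correlations ``C(t)``), and the even/odd window
decomposition that separates changes of the symmetric and antisymmetric parts
of reciprocal connections.

Conventions
-----------
Time bins are left-edge labelled and half-open, ``[t, t + dt)``; bin ``i``
maps to time ``t = i * dt``.  Lag grids are uniform, symmetric about zero and
contain the zero lag.  Lag integrals use the rectangle rule at grid
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "TimeGrid",
    "SpikeRaster",
    "LagFunction",
    "AlphaParams",
    "eval_alpha",
    "lif_lambda_syn",
    "even_odd_parts",
    "cross_correlation",
    "stdp_weight_change",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time discretization: ``n_steps`` bins of width ``dt`` (ms)."""

    dt: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def duration(self) -> float:
        return self.dt * self.n_steps

    @property
    def times(self) -> np.ndarray:
        """Left edges of the time bins."""
        return np.arange(self.n_steps) * self.dt


@dataclass
class SpikeRaster:
    """Binary neuron x time-bin firing record ``phi_i(t)``."""

    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster must be a 2-D neuron x bin array")
        if self.values.shape[1] != self.grid.n_steps:
            raise ValueError("raster width must equal grid.n_steps")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("raster entries must be exactly 0 or 1")
        self.values = self.values.astype(np.int8)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    def spike_times(self, i: int) -> np.ndarray:
        """Times (bin left edges) at which neuron ``i`` fires."""
        return np.flatnonzero(self.values[i]) * self.grid.dt


@dataclass
class LagFunction:
    """A real function sampled on a uniform symmetric lag grid ``-L..L``."""

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape or self.lags.ndim != 1:
            raise ValueError("lags and values must be matching 1-D arrays")
        if len(self.lags) > 1:
            d = np.diff(self.lags)
            if not np.allclose(d, d[0]):
                raise ValueError("lag grid must be uniform")

    @property
    def dlag(self) -> float:
        return float(self.lags[1] - self.lags[0]) if len(self.lags) > 1 else 1.0

    def is_symmetric_grid(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.lags, -self.lags[::-1], atol=tol))

    def require_symmetric_grid(self) -> None:
        if not self.is_symmetric_grid():
            raise ValueError("lag grid must be symmetric about zero")

    def same_grid(self, other: "LagFunction", tol: float = 1e-9) -> bool:
        return self.lags.shape == other.lags.shape and bool(
            np.allclose(self.lags, other.lags, atol=tol)
        )


def symmetric_lags(max_lag: float, dt: float) -> np.ndarray:
    """Uniform lag grid ``-L..L`` (inclusive) with spacing ``dt``."""
    m = int(round(max_lag / dt))
    return np.arange(-m, m + 1) * dt


@dataclass(frozen=True)
class AlphaParams:
    """Parameters of the synaptic alpha-function and leaky-integrator kernel.

    ``tau_d`` is the delay time (ms), ``tau_c`` the characteristic time (ms),
    ``c_mem`` the capacitance scale and ``gamma`` the membrane leak rate
    (1/ms) of the integrate-and-fire solution.
    """

    tau_d: float = 2.0
    tau_c: float = 1.0
    c_mem: float = 1.0
    gamma: float = 0.15

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.c_mem <= 0:
            raise ValueError("c_mem must be positive")


def eval_alpha(t, p: AlphaParams):
    """Synaptic conductance time course ``alpha(t) = g(t) exp(-g(t))``.

    with ``g(t) = max[(tau_d - t)/tau_c, 0]``; implemented verbatim, so the
    pulse sits *before* the delay time ``tau_d`` and vanishes for
    ``t >= tau_d``.  Total function: accepts scalars or arrays.
    """
    g = np.maximum((p.tau_d - np.asarray(t, dtype=float)) / p.tau_c, 0.0)
    out = g * np.exp(-g)
    return float(out) if np.isscalar(t) else out


def lif_lambda_syn(grid: TimeGrid, p: AlphaParams, normalize: bool = False) -> LagFunction:
    """Synaptic response kernel of a leaky integrate-and-fire membrane.

    ``lambda_syn(t) = C^-1 * int_0^t dt' exp(gamma (t' - t)) alpha(t')`` for
    ``t > 0`` and 0 for ``t <= 0`` (the kernel is causal).  Each positive grid
    point is evaluated by adaptive quadrature.  With ``normalize=True`` the
    kernel is rescaled to unit peak (the overall scale is a free calibration).
    """
    lags = symmetric_lags(grid.dt * (grid.n_steps - 1), grid.dt)
    vals = np.zeros_like(lags)
    pos = lags > 0

    def integrand(s: float, t: float) -> float:
        return math.exp(p.gamma * (s - t)) * eval_alpha(s, p)

    for k in np.flatnonzero(pos):
        t = lags[k]
        breaks = [b for b in (p.tau_d,) if 0 < b < t]
        val, _ = quad(integrand, 0.0, t, args=(t,), points=breaks or None, limit=200)
        vals[k] = val / p.c_mem
    if normalize:
        peak = vals.max()
        if peak > 0:
            vals = vals / peak
    return LagFunction(lags, vals)


def even_odd_parts(w: LagFunction) -> tuple[LagFunction, LagFunction]:
    """Split a window into its even and odd parts about zero lag.

    ``w_even(t) = [w(t) + w(-t)]/2`` and ``w_odd(t) = [w(t) - w(-t)]/2``; the
    two recombine to the original pointwise.
    """
    w.require_symmetric_grid()
    rev = w.values[::-1]
    even = 0.5 * (w.values + rev)
    odd = 0.5 * (w.values - rev)
    return LagFunction(w.lags.copy(), even), LagFunction(w.lags.copy(), odd)


def cross_correlation(r: SpikeRaster, i: int, j: int, max_lag: float) -> LagFunction:
    """Spike cross-correlation ``C_ij(l) = <phi_i(t) phi_j(t - l)>``.

    The average runs over all bins ``t`` for which both ``t`` and ``t - l``
    lie inside the raster; each lag is normalized by its own count of valid
    pairs, so ``C_ij(l) = C_ji(-l)`` holds exactly.
    """
    if r.values.size == 0 or r.grid.n_steps == 0:
        raise ValueError("empty raster")
    if max_lag > r.grid.duration:
        raise ValueError("max_lag exceeds raster duration")
    dt = r.grid.dt
    n = r.grid.n_steps
    m = int(round(max_lag / dt))
    if m >= n:
        raise ValueError("max_lag leaves no valid pairs at the extreme lag")
    lags = np.arange(-m, m + 1) * dt
    vals = np.empty_like(lags)
    a, b = r.values[i].astype(float), r.values[j].astype(float)
    for idx, k in enumerate(range(-m, m + 1)):
        if k >= 0:
            s = float(a[k:] @ b[: n - k])
        else:
            s = float(a[: n + k] @ b[-k:])
        vals[idx] = s / (n - abs(k))
    return LagFunction(lags, vals)


def stdp_weight_change(window: LagFunction, C: LagFunction) -> float:
    """Long-time connection change ``Delta W = int dt Omega(t) C(t)``.

    Rectangle rule on the shared lag grid.  Because the grid is symmetric,
    the decomposition identity holds exactly: integrating the full window
    against the even/odd part of ``C`` equals integrating the even/odd part
    of the window against the full ``C``.
    """
    if not window.same_grid(C):
        raise ValueError("window and correlation must share a lag grid")
    return float(np.sum(window.values * C.values) * window.dlag)
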