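"""Path-integral spiking model ("Feynman machine").

Firing states live on a spatiotemporal grid of (neuron, time-bin) sites.
Pairwise causal interaction kernels ``D+_ij(t) ~ -lambda_syn(t) W_ij``
(zero for ``t <= 0``) and time-dependent biases ``B_i(t) = h_i(t) - Vth``
define an action

    A[phi] = -1/2 sum_ij sum_tt' D_ij(t - t') phi_i(t) phi_j(t')
             + sum_i sum_t B_i(t) phi_i(t),

with ``D_ij(t) = D+_ij(t) + D+_ji(-t)``, and the firing statistics follow
from the free energy ``F = -T log Tr exp(A/T)``.  Small grids are traced
exactly; larger ones are handled by the truncated fugacity/Mayer cluster
expansion of the one-point function, by a conditional-rate Monte Carlo, or
by the zero-temperature firing condition.  The same free energy yields the
learning rule and, through it, the spike-timing-dependent plasticity
window ``Omega(t) ~ lambda_syn(t) - int dt' Sigma(t,t') lambda_syn(t')``.

Binary ``phi`` is treated as a per-bin spike count, so kernel-spike sums
carry no extra ``dt`` factor; kernel-kernel integrals (the STDP window,
the frequency sum of the spatiotemporal rule) are Riemann sums at grid
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from ._rng import child_rng
from .kernels import LagFunction, SpikeRaster, TimeGrid

__all__ = [
    "SynapseParams",
    "FeynmanNetwork",
    "ExpansionState",
    "SigmaModel",
    "series_potential",
    "conditional_firing_rate",
    "zero_T_firing_condition",
    "spiking_monte_carlo",
    "exact_trace_one_point",
    "ExactTraceResult",
    "site_action",
    "mayer_one_point",
    "mayer_series_all",
    "stdp_window_theory",
    "free_energy_gradient_learning",
    "exact_free_energy_of_weights",
    "stdp_route_weight_gradient",
    "spatiotemporal_learning_step",
]


@dataclass(frozen=True)
class SynapseParams:
    """Biophysical synapse parameters.

    The effective connection strength is ``W = g_syn (V_syn - V_eq)``; only
    the conductance ``g_syn >= 0`` is plastic, so the sign of ``W`` never
    changes during learning.  ``Vth_bar = V_th - V_eq`` is the firing
    threshold measured from rest.
    """

    g_syn: float
    V_syn: float
    V_eq: float = 0.0
    V_th: float = 1.0

    def __post_init__(self) -> None:
        if self.g_syn < 0:
            raise ValueError("g_syn must be non-negative")

    @property
    def W(self) -> float:
        return self.g_syn * (self.V_syn - self.V_eq)

    @property
    def Vth_bar(self) -> float:
        return self.V_th - self.V_eq


@dataclass
class FeynmanNetwork:
    """Signed (possibly asymmetric) weights with a shared causal kernel.

    ``D+_ij(t) = -lambda_syn(t) W_ij`` for ``t > 0`` and 0 otherwise; the
    refractory term is realized as a hard veto of duration ``tau_r`` rather
    than a finite penalty.  ``B`` is the (neuron, bin) bias array
    ``B_i(t) = h_i(t) - Vth_bar``; ``T`` is the noise temperature.
    """

    W: np.ndarray
    lambda_syn: LagFunction
    grid: TimeGrid
    B: np.ndarray
    T: float = 1.0
    tau_r: float = 0.0
    rate_const: float = 1.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("W must be square")
        self.B = np.asarray(self.B, dtype=float)
        if self.B.shape != (n, self.grid.n_steps):
            raise ValueError("B must be (n_neurons, n_steps)")
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def kernel_on_bins(self) -> np.ndarray:
        """``lambda_syn`` sampled at non-negative bin lags 0..n_steps-1."""
        lam = np.zeros(self.grid.n_steps)
        lags = self.lambda_syn.lags
        vals = self.lambda_syn.values
        for k in range(self.grid.n_steps):
            t = k * self.grid.dt
            idx = np.argmin(np.abs(lags - t))
            if abs(lags[idx] - t) < 1e-9 and lags[idx] > 0:
                lam[k] = vals[idx]
        return lam

    def dplus(self, i: int, j: int, lag_bins: int) -> float:
        """``D+_ij`` at a (signed) bin lag; zero for non-positive lags."""
        if lag_bins <= 0:
            return 0.0
        lam = self.kernel_on_bins()
        if lag_bins >= len(lam):
            return 0.0
        return -lam[lag_bins] * self.W[i, j]


def series_potential(
    net: FeynmanNetwork, raster: SpikeRaster, h: np.ndarray
) -> np.ndarray:
    """First-order membrane potential given the firing record.

    ``V_i(t) = h_i(t) + sum_j W_ij sum_{t'} lambda_syn(t - t') phi_j(t')``
    — the leaky-integrated external drive plus a superposition of causal
    synaptic responses, one per presynaptic spike.
    """
    if raster.grid.n_steps != net.grid.n_steps or raster.grid.dt != net.grid.dt:
        raise ValueError("raster grid does not match network grid")
    h = np.asarray(h, dtype=float)
    lam = net.kernel_on_bins()
    nb = net.grid.n_steps
    conv = np.zeros((raster.n_neurons, nb))
    for j in range(raster.n_neurons):
        c = np.convolve(raster.values[j].astype(float), lam)[:nb]
        conv[j] = c
    return h + net.W @ conv


def conditional_firing_rate(
    net: FeynmanNetwork, raster: SpikeRaster, t: int, i: int
) -> float:
    """Instantaneous firing rate of neuron ``i`` at bin ``t`` given history.

    ``rate = r exp[(drive + B_i(t))/T]`` with the synaptic drive summed over
    spikes strictly before ``t``; exactly zero inside the refractory period
    (the hard-veto realization of the diverging refractory kernel).
    """
    dt = net.grid.dt
    if net.tau_r > 0:
        r_bins = int(np.ceil(net.tau_r / dt))
        lo = max(0, t - r_bins)
        if raster.values[i, lo:t].any():
            return 0.0
    lam = net.kernel_on_bins()
    drive = 0.0
    for j in range(net.n):
        spikes = np.flatnonzero(raster.values[j, :t])
        for s in spikes:
            lag = t - s
            if lag < len(lam):
                drive += net.W[i, j] * lam[lag]
    return float(net.rate_const * np.exp((drive + net.B[i, t]) / net.T))


def zero_T_firing_condition(
    syn: SynapseParams | np.ndarray,
    spike_times: np.ndarray,
    lambda_syn: LagFunction,
    t_grid: np.ndarray | None = None,
) -> bool:
    """Zero-temperature firing condition of a single postsynaptic neuron.

    Fires iff ``max_t sum_j lambda_syn(t - t_j) W_j >= Vth_bar``: the peak
    summed synaptic drive reaches threshold.  ``syn`` may be a single
    parameter set (shared by all presynaptic spikes) or one per spike.
    """
    if isinstance(syn, SynapseParams):
        Ws = np.full(len(spike_times), syn.W)
        vth = syn.Vth_bar
    else:
        syn = list(syn)
        Ws = np.array([s.W for s in syn])
        vth = syn[0].Vth_bar
    spike_times = np.asarray(spike_times, dtype=float)
    if t_grid is None:
        dl = lambda_syn.dlag
        t_grid = np.arange(
            spike_times.min(), spike_times.max() + lambda_syn.lags.max() + dl, dl
        )
    lags, vals = lambda_syn.lags, lambda_syn.values
    drive = np.zeros_like(t_grid)
    for w, ts in zip(Ws, spike_times):
        drive += w * np.interp(t_grid - ts, lags, vals, left=0.0, right=0.0)
    return bool(drive.max() >= vth)


def spiking_monte_carlo(
    net: FeynmanNetwork,
    h: np.ndarray | None = None,
    n_trials: int = 100,
    seed: int = 0,
    drive_from: np.ndarray | None = None,
) -> list[SpikeRaster]:
    """Sample independent trial rasters bin-by-bin from the conditional rate.

    Per-bin spike probability is ``min(rate * dt, 1)``; a warning is issued
    if it exceeds 0.5 anywhere (the binning is then too coarse for the rate).
    ``drive_from`` optionally clamps some neurons to a fixed spike train
    (boolean mask of clamped neurons, whose rows of ``net.B`` are ignored
    and whose spikes are taken from ``h`` interpreted as a raster).
    """
    rng = child_rng(seed, "spiking-mc")
    dt = net.grid.dt
    nb = net.grid.n_steps
    n = net.n
    lam = net.kernel_on_bins()
    L = len(lam)
    r_bins = int(np.ceil(net.tau_r / dt)) if net.tau_r > 0 else 0
    clamped = (
        np.zeros(n, dtype=bool) if drive_from is None else np.asarray(drive_from, bool)
    )
    clamp_raster = None
    if clamped.any():
        clamp_raster = np.asarray(h)
    warned = False
    out = []
    for _ in range(n_trials):
        phi = np.zeros((n, nb), dtype=np.int8)
        drive = np.zeros((n, nb))
        last_spike = np.full(n, -(10**9))
        for t in range(nb):
            for i in range(n):
                if clamped[i]:
                    phi[i, t] = clamp_raster[i, t]
                else:
                    if r_bins and t - last_spike[i] <= r_bins:
                        continue
                    rate = net.rate_const * np.exp(
                        (drive[i, t] + net.B[i, t]) / net.T
                    )
                    p = rate * dt
                    if p > 0.5 and not warned:
                        warnings.warn(
                            "per-bin spike probability exceeds 0.5; "
                            "dt is too coarse for this rate",
                            stacklevel=2,
                        )
                        warned = True
                    if rng.random() < min(p, 1.0):
                        phi[i, t] = 1
                if phi[i, t]:
                    last_spike[i] = t
                    hi = min(nb, t + L)
                    if hi > t + 1:
                        drive[:, t + 1 : hi] += np.outer(
                            net.W[:, i], lam[1 : hi - t]
                        )
        out.append(SpikeRaster(phi, net.grid))
    return out


# ---------------------------------------------------------------------------
# exact spatiotemporal trace
# ---------------------------------------------------------------------------

_MAX_SITES = 20


@dataclass
class ExactTraceResult:
    means: np.ndarray          # <phi_a> per site
    two_point: np.ndarray      # <phi_a phi_b>
    connected: np.ndarray      # G_ab = <phi phi> - <phi><phi>
    free_energy: float         # F = -T log Z


def site_action(net: FeynmanNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the site-pair interaction matrix and bias vector.

    Sites are (neuron, bin) pairs in row-major order; the symmetric matrix
    holds ``D_ij(t_a - t_b) = D+_ij(t_a - t_b) + D+_ji(t_b - t_a)``.
    """
    Dplus = _dplus_sites(net)
    return Dplus + Dplus.T, net.B.reshape(-1)


def exact_trace_one_point(
    Dmat: np.ndarray, B: np.ndarray, T: float
) -> ExactTraceResult:
    """Exact firing statistics by enumeration of all site configurations.

    ``A(phi) = -1/2 phi' Dmat phi + B phi``; returns one- and two-point
    functions and the free energy ``F = -T log Z``.  Finite differences of
    ``F`` in the biases reproduce the one-point function and (scaled by
    ``-T``) the connected two-point function.
    """
    Dmat = np.asarray(Dmat, dtype=float)
    B = np.asarray(B, dtype=float)
    S = len(B)
    if S > _MAX_SITES:
        raise ValueError(f"exact trace limited to {_MAX_SITES} sites")
    idx = np.arange(2**S, dtype=np.int64)
    Phi = ((idx[:, None] >> np.arange(S)) & 1).astype(float)
    A = -0.5 * np.einsum("sa,ab,sb->s", Phi, Dmat, Phi) + Phi @ B
    logw = A / T
    logZ = logsumexp(logw)
    w = np.exp(logw - logZ)
    means = w @ Phi
    two = Phi.T @ (w[:, None] * Phi)
    G = two - np.outer(means, means)
    return ExactTraceResult(
        means=means, two_point=two, connected=G, free_energy=float(-T * logZ)
    )


# ---------------------------------------------------------------------------
# truncated fugacity / Mayer expansion
# ---------------------------------------------------------------------------


@dataclass
class ExpansionState:
    """Fugacities and Mayer functions on the site grid.

    ``z_a = exp(B_a / T)`` per (neuron, bin) site and
    ``f+_ab = exp(-D+_ab / T) - 1``, zero wherever the causal kernel
    vanishes.  ``order`` is the truncation order of the one-point series
    (1, 2 or 3).
    """

    z: np.ndarray
    fplus: np.ndarray
    order: int = 3
    n_neurons: int = 0
    n_bins: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.order <= 3:
            raise ValueError("expansion order must be 1, 2 or 3")

    @classmethod
    def from_network(cls, net: FeynmanNetwork, order: int = 3) -> "ExpansionState":
        Dmat_plus = _dplus_sites(net)
        z = np.exp(net.B.reshape(-1) / net.T)
        fplus = np.exp(-Dmat_plus / net.T) - 1.0
        return cls(
            z=z,
            fplus=fplus,
            order=order,
            n_neurons=net.n,
            n_bins=net.grid.n_steps,
        )

    @property
    def f(self) -> np.ndarray:
        """Full Mayer function ``f_ab = f+_ab + f+_ba``."""
        return self.fplus + self.fplus.T


def _dplus_sites(net: FeynmanNetwork) -> np.ndarray:
    n, nb = net.n, net.grid.n_steps
    lam = net.kernel_on_bins()
    lagmat = np.subtract.outer(np.arange(nb), np.arange(nb))
    lamlag = np.zeros_like(lagmat, dtype=float)
    pos = lagmat > 0
    lamlag[pos] = lam[lagmat[pos]]
    S = n * nb
    Dplus = np.zeros((S, S))
    for i in range(n):
        for j in range(n):
            Dplus[i * nb : (i + 1) * nb, j * nb : (j + 1) * nb] = (
                -lamlag * net.W[i, j]
            )
    return Dplus


def mayer_series_all(exp_state: ExpansionState, resummed: bool = True) -> np.ndarray:
    """Truncated cluster-expansion one-point function for every site.

    The series is the printed low-fugacity expansion: the fugacity term,
    the pair term ``sum_b z_a z_b f+_ab``, and the three third-order
    diagrams ``1/2 sum_bc z z z [2 f+_ab f_bc + f+_ab f+_ac
    + f+_ab f+_ac f_bc]`` (sites ``b, c`` distinct from each other and from
    ``a``; only causal ``f+`` legs attach to the observed site).

    With ``resummed=True`` (default) the bare fugacity is replaced by the
    self-excluded site activity ``zeta = z/(1+z)`` and the pair term carries
    the saturation factor ``(1 - zeta_a)``; this diagonal resummation
    restores the hard-core constraint ``phi^2 = phi`` exactly in the
    non-interacting limit and makes the truncation error scale as
    ``O(zeta^(order+1))``.  With ``resummed=False`` the series is evaluated
    verbatim (zeroth term exactly ``z``), which carries an ``O(z^2)``
    single-site error.
    """
    z = exp_state.z
    Fp = exp_state.fplus
    Ff = exp_state.f
    S = len(z)
    zeta = z / (1.0 + z) if resummed else z
    out = zeta.copy()
    if exp_state.order >= 2:
        pair = Fp @ zeta  # sum_b f+_ab zeta_b  (diagonal f+_aa is zero)
        sat = (1.0 - zeta) if resummed else 1.0
        out = out + zeta * sat * pair
    if exp_state.order >= 3:
        third = np.empty(S)
        for a in range(S):
            m = zeta.copy()
            m[a] = 0.0
            u = m * Fp[a]  # u_b = zeta_b f+_ab, b != a
            su = u.sum()
            # 2 f+_ab f_bc : sum_{b != c} u_b F_bc m_c
            t1 = 2.0 * (u @ Ff @ m - u @ (np.diag(Ff) * m))
            # f+_ab f+_ac : sum_{b != c} u_b u_c
            t2 = su * su - u @ u
            # f+_ab f+_ac f_bc : sum_{b != c} u_b F_bc u_c
            t3 = u @ Ff @ u - u @ (np.diag(Ff) * u)
            third[a] = 0.5 * zeta[a] * (t1 + t2 + t3)
        out = out + third
    return out


def mayer_one_point(
    exp_state: ExpansionState, i: int, t: int, resummed: bool = True
) -> float:
    """One-point function ``<phi_i(t)>`` from the truncated expansion."""
    vals = mayer_series_all(exp_state, resummed=resummed)
    return float(vals[i * exp_state.n_bins + t])


# ---------------------------------------------------------------------------
# STDP window and learning rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmaModel:
    """Gaussian model of the entropy curvature kernel.

    ``Sigma(t, t') = A exp[-(t + t')^2 / 2 sigma^2 - (t - t')^2 / 2 sigma^2]``,
    symmetric in its arguments and bounded by ``A``.
    """

    A: float = 0.02
    sigma: float = 30.0

    def __call__(self, t: np.ndarray, tp: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tp = np.asarray(tp, dtype=float)
        return self.A * np.exp(
            -((t + tp) ** 2) / (2 * self.sigma**2)
            - ((t - tp) ** 2) / (2 * self.sigma**2)
        )


def stdp_window_theory(
    lambda_syn: LagFunction, sigma: SigmaModel, scale: float = 1.0
) -> LagFunction:
    """STDP window from the free-energy gradient:

    ``Omega(t) = scale [lambda_syn(t) - int dt' Sigma(t, t') lambda_syn(t')]``.

    The first (internal-energy) term contributes only at positive lags
    (pre-before-post potentiation); the entropy term extends to negative
    lags and produces the depression lobe.
    """
    lambda_syn.require_symmetric_grid()
    if np.any(lambda_syn.values[lambda_syn.lags < 0] != 0):
        raise ValueError("lambda_syn must be causal (zero for t < 0)")
    lags = lambda_syn.lags
    lam = lambda_syn.values
    Smat = sigma(lags[:, None], lags[None, :])
    omega = scale * (lam - Smat @ lam * lambda_syn.dlag)
    return LagFunction(lags.copy(), omega)


def exact_free_energy_of_weights(
    template: FeynmanNetwork,
) -> "callable":
    """Factory: ``F(W)`` evaluated by exact trace on the template's grid.

    Usable only on small grids; intended as the differentiable free-energy
    estimator for gradient learning and its finite-difference checks.
    """

    def F_of_W(W: np.ndarray) -> float:
        net = FeynmanNetwork(
            W=np.asarray(W, dtype=float),
            lambda_syn=template.lambda_syn,
            grid=template.grid,
            B=template.B,
            T=template.T,
            tau_r=template.tau_r,
        )
        Dmat, Bvec = site_action(net)
        return exact_trace_one_point(Dmat, Bvec, net.T).free_energy

    return F_of_W


def free_energy_gradient_learning(
    W: np.ndarray,
    gradient_estimator,
    lr: float,
    eps: float = 1e-5,
) -> np.ndarray:
    """One gradient-flow step ``W -= lr * dF/dW`` with sign projection.

    ``gradient_estimator`` is either a callable returning ``dF/dW`` directly
    or a scalar function ``F(W)`` (detected by output shape), in which case
    a central finite difference is used.  Because only conductances are
    plastic, the sign of each weight is preserved: entries whose sign would
    flip are projected to zero.
    """
    W = np.asarray(W, dtype=float).copy()
    probe = gradient_estimator(W)
    if np.ndim(probe) == 0:
        grad = np.zeros_like(W)
        for idx in np.ndindex(W.shape):
            Wp = W.copy()
            Wp[idx] += eps
            Wm = W.copy()
            Wm[idx] -= eps
            grad[idx] = (gradient_estimator(Wp) - gradient_estimator(Wm)) / (2 * eps)
    else:
        grad = np.asarray(probe, dtype=float)
    new = W - lr * grad
    flip = (np.sign(new) != np.sign(W)) & (W != 0)
    new[flip] = 0.0
    return new


def stdp_route_weight_gradient(net: FeynmanNetwork, i: int, j: int) -> float:
    """``-dF/dW_ij`` via the correlation route.

    Differentiating the action in the weight gives
    ``-dF/dW_ij = sum_tt' lambda_syn(t - t') <phi_i(t) phi_j(t')>``: the
    window-weighted sum of the exact (unconnected) two-point function over
    all spatiotemporal lag pairs.  Valid on exact-enumerable grids only.
    """
    Dmat, Bvec = site_action(net)
    res = exact_trace_one_point(Dmat, Bvec, net.T)
    nb = net.grid.n_steps
    lam = net.kernel_on_bins()
    lagmat = np.subtract.outer(np.arange(nb), np.arange(nb))
    lamlag = np.zeros_like(lagmat, dtype=float)
    pos = lagmat > 0
    lamlag[pos] = lam[lagmat[pos]]
    block = res.two_point[i * nb : (i + 1) * nb, j * nb : (j + 1) * nb]
    return float(np.sum(lamlag * block))


def spatiotemporal_learning_step(
    K_omega: np.ndarray,
    Q_omega: np.ndarray,
    W: np.ndarray,
    beta: float,
    lr: float,
    d_omega: float = 1.0,
) -> np.ndarray:
    """Frequency-domain spatiotemporal learning step.

    ``dW ~ sum_omega K~(omega) W Q~(omega) d_omega - beta (W W')^-1 W``
    with ``K~`` and ``Q~`` the Fourier transforms of the output vertex
    two-point function and the input correlation function, supplied on a
    discrete frequency grid (leading axis) and Hermitian at every
    frequency.  The assembled update must be real to within 1e-10 (the
    frequency grid must pair conjugate frequencies); the real part is
    applied.  When ``Q~`` is concentrated at zero frequency the step
    reduces to the firing-rate (PSL-type) rule
    ``K~(0) W Q~(0) - beta (W W')^-1 W``.
    """
    K_omega = np.asarray(K_omega, dtype=complex)
    Q_omega = np.asarray(Q_omega, dtype=complex)
    W = np.asarray(W, dtype=float)
    if K_omega.ndim == 2:
        K_omega = K_omega[None]
    if Q_omega.ndim == 2:
        Q_omega = Q_omega[None]
    if K_omega.shape[0] != Q_omega.shape[0]:
        raise ValueError("K and Q must share the frequency grid")
    for name, arr in (("K", K_omega), ("Q", Q_omega)):
        herm = np.abs(arr - np.conj(np.swapaxes(arr, 1, 2))).max()
        if herm > 1e-8:
            raise ValueError(f"{name}~(omega) must be Hermitian at every frequency")
    upd = np.einsum("wij,jk,wkl->il", K_omega, W.astype(complex), Q_omega) * d_omega
    if np.abs(upd.imag).max() > 1e-10:
        raise ValueError("assembled update has a non-negligible imaginary part")
    comp = np.linalg.solve(W @ W.T, W)
    return W + lr * (upd.real - beta * comp)
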