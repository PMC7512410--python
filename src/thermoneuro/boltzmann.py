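"""Boltzmann machine: exact statistics, KL-gradient learning, and the
coupled firing/structural-plasticity Monte Carlo that grows heavy-tailed
connectivity.

Neurons are binary, ``phi_i in {0, 1}``, with energy
``E = -1/2 sum_ij J_ij phi_i phi_j - sum_i B_i phi_i`` and single-neuron
Metropolis flips.  Small networks (``N <= 20``) can be enumerated exactly,
which provides the oracle statistics used throughout the test suite.

The structural-plasticity model couples two Monte Carlo processes on
different time scales: neurons flip their firing states, and connections
toggle between a fixed quantum ``J`` and 0 with a Metropolis rule on the
wiring energy ``F = -1/2 sum_ij (C_ij - eta rho_i rho_j + mu) J_ij`` whose
window-estimated correlations feed back on the firing dynamics.  Run long
enough, the network settles into a degree distribution whose cumulative form
is close to a straight line on log-log axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp
from scipy.stats import linregress

from ._rng import child_rng

__all__ = [
    "BoltzmannNetwork",
    "StructuralConfig",
    "DegreeDistribution",
    "bm_energy",
    "metropolis_flip",
    "metropolis_sweep",
    "exact_expectation",
    "free_energy_exact",
    "visible_marginal",
    "kl_divergence",
    "clamped_expectation",
    "kl_gradient_learning_step",
    "structural_energy",
    "structural_flip",
    "run_coupled_dynamics",
    "cumulative_degree_distribution",
]

_MAX_ENUM = 20


@dataclass
class BoltzmannNetwork:
    """Symmetric couplings, biases ``B_i = h_i + theta_i`` and a 0/1 state."""

    J: np.ndarray
    B: np.ndarray
    phi: np.ndarray
    visible_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.phi = np.asarray(self.phi)
        n = self.J.shape[0]
        if self.J.shape != (n, n) or not np.allclose(self.J, self.J.T):
            raise ValueError("J must be square and symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("J must have zero diagonal")
        if self.B.shape != (n,):
            raise ValueError("B must have length N")
        if self.phi.shape != (n,) or not np.isin(self.phi, (0, 1)).all():
            raise ValueError("phi entries must be 0 or 1")
        self.phi = self.phi.astype(np.int8)
        if self.visible_mask is None:
            self.visible_mask = np.ones(n, dtype=bool)
        else:
            self.visible_mask = np.asarray(self.visible_mask, dtype=bool)
            if self.visible_mask.shape != (n,):
                raise ValueError("visible_mask must have length N")

    @property
    def n(self) -> int:
        return self.J.shape[0]


def bm_energy(net: BoltzmannNetwork, phi: np.ndarray | None = None) -> float:
    """``E = -1/2 sum_ij J_ij phi_i phi_j - sum_i B_i phi_i``."""
    p = (net.phi if phi is None else np.asarray(phi)).astype(float)
    return float(-0.5 * p @ net.J @ p - net.B @ p)


def metropolis_flip(
    net: BoltzmannNetwork, i: int, T: float, rng: np.random.Generator
) -> np.ndarray:
    """Attempt a 0<->1 flip of neuron ``i`` with ``min[exp(-dE/T), 1]``."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    dphi = 1 - 2 * int(net.phi[i])
    dE = -(net.J[i] @ net.phi + net.B[i]) * dphi
    if dE <= 0 or rng.random() < np.exp(-dE / T):
        net.phi[i] = 1 - net.phi[i]
    return net.phi


def metropolis_sweep(
    net: BoltzmannNetwork, T: float, rng: np.random.Generator
) -> np.ndarray:
    """One full sweep in a fresh random permutation order."""
    for i in rng.permutation(net.n):
        metropolis_flip(net, int(i), T, rng)
    return net.phi


@lru_cache(maxsize=8)
def _states(n: int) -> np.ndarray:
    """All 2^n binary configurations, LSB = neuron 0."""
    idx = np.arange(2**n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n)) & 1).astype(float)


def _boltzmann_weights(net: BoltzmannNetwork, T: float) -> tuple[np.ndarray, np.ndarray]:
    if net.n > _MAX_ENUM:
        raise ValueError(f"exact enumeration limited to N <= {_MAX_ENUM}")
    S = _states(net.n)
    E = -0.5 * np.einsum("si,ij,sj->s", S, net.J, S) - S @ net.B
    logw = -E / T
    logZ = logsumexp(logw)
    return S, np.exp(logw - logZ)


def exact_expectation(
    net: BoltzmannNetwork, T: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact ``<phi_i>`` and ``<phi_i phi_j>`` by full enumeration."""
    S, w = _boltzmann_weights(net, T)
    means = w @ S
    pair = S.T @ (w[:, None] * S)
    return means, pair


def free_energy_exact(net: BoltzmannNetwork, T: float) -> float:
    """``F = -T log Z`` by enumeration; ``-dF/dB_i`` recovers ``<phi_i>``."""
    if net.n > _MAX_ENUM:
        raise ValueError(f"exact enumeration limited to N <= {_MAX_ENUM}")
    S = _states(net.n)
    E = -0.5 * np.einsum("si,ij,sj->s", S, net.J, S) - S @ net.B
    return float(-T * logsumexp(-E / T))


def visible_marginal(net: BoltzmannNetwork, T: float) -> np.ndarray:
    """Model marginal over visible-unit configurations.

    Returns an array of length ``2^n_vis`` indexed by the visible bits (the
    k-th visible neuron, in index order, is bit k).
    """
    S, w = _boltzmann_weights(net, T)
    vis = np.flatnonzero(net.visible_mask)
    codes = (S[:, vis] @ (2 ** np.arange(len(vis)))).astype(np.int64)
    out = np.zeros(2 ** len(vis))
    np.add.at(out, codes, w)
    return out


def kl_divergence(net: BoltzmannNetwork, T: float, clamped_dist: np.ndarray) -> float:
    """Kullback-Leibler divergence of the clamped (data) distribution over
    visible states from the free-running model marginal.

    Terms with ``P(v) = 0`` are excluded; ``L >= 0`` with equality iff the
    distributions coincide.
    """
    P = np.asarray(clamped_dist, dtype=float)
    if not np.isclose(P.sum(), 1.0):
        raise ValueError("clamped distribution must sum to 1")
    P0 = visible_marginal(net, T)
    if P.shape != P0.shape:
        raise ValueError("clamped distribution has wrong size for visible set")
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / P0[mask])))


def clamped_expectation(
    net: BoltzmannNetwork, T: float, clamped_dist: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """``<phi_i>`` and ``<phi_i phi_j>`` with visible units clamped.

    Visible units are pinned to each configuration ``v`` (weighted by the
    data probability ``P(v)``) while hidden units equilibrate; expectations
    are computed by exact enumeration of the hidden units.
    """
    P = np.asarray(clamped_dist, dtype=float)
    vis = np.flatnonzero(net.visible_mask)
    hid = np.flatnonzero(~net.visible_mask)
    n = net.n
    means = np.zeros(n)
    pair = np.zeros((n, n))
    Sv = _states(len(vis))
    Sh = _states(len(hid)) if len(hid) else np.zeros((1, 0))
    for code, pv in enumerate(P):
        if pv == 0:
            continue
        full = np.zeros((Sh.shape[0], n))
        full[:, vis] = Sv[code]
        if len(hid):
            full[:, hid] = Sh
        E = -0.5 * np.einsum("si,ij,sj->s", full, net.J, full) - full @ net.B
        logw = -E / T
        w = np.exp(logw - logsumexp(logw))
        means += pv * (w @ full)
        pair += pv * (full.T @ (w[:, None] * full))
    return means, pair


def kl_gradient_learning_step(
    net: BoltzmannNetwork,
    T: float,
    clamped_stats: np.ndarray,
    free_stats: np.ndarray,
    lr: float,
) -> np.ndarray:
    """Gradient-descent step on the KL divergence:
    ``J_ij += lr * (C_ij - C0_ij)`` with ``C`` / ``C0`` the clamped / free
    pair correlations.  Off-diagonal only; the result stays symmetric.
    """
    C = np.asarray(clamped_stats, dtype=float)
    C0 = np.asarray(free_stats, dtype=float)
    if not (np.allclose(C, C.T) and np.allclose(C0, C0.T)):
        raise ValueError("correlation matrices must be symmetric")
    step = lr * (C - C0)
    np.fill_diagonal(step, 0.0)
    net.J = net.J + 0.5 * (step + step.T)
    return net.J


# ---------------------------------------------------------------------------
# structural plasticity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuralConfig:
    """Parameters of the coupled firing/wiring Monte Carlo.

    ``J_val`` is the connection quantum (each connection is either ``J_val``
    or 0), ``T`` the temperature shared by both processes, ``tau >= 1`` the
    firing-to-wiring time-scale ratio, ``eta`` the competition strength,
    ``mu`` the wiring propensity (the negative of a wiring cost), ``bias``
    the uniform neuron bias ``B_i``, and ``window_len`` the moving-window
    length (in firing sweeps) over which the firing probability ``rho_i``
    and the equal-time correlation ``C_ij`` are estimated.
    """

    J_val: float = 0.5
    T: float = 0.1
    tau: float = 2.0
    eta: float = 10.0
    mu: float = 1.9
    bias: float = -0.3
    window_len: int = 100

    def __post_init__(self) -> None:
        if self.J_val <= 0:
            raise ValueError("J_val must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")


def structural_energy(
    C: np.ndarray, rho: np.ndarray, Jbin: np.ndarray, cfg: StructuralConfig
) -> float:
    """Wiring energy ``F = -1/2 sum_{i != j} (C_ij - eta rho_i rho_j + mu) J_ij``."""
    C = np.asarray(C, dtype=float)
    Jbin = np.asarray(Jbin, dtype=float)
    if C.shape != Jbin.shape:
        raise ValueError("C and Jbin shapes must match")
    if not np.allclose(C, C.T):
        raise ValueError("C must be symmetric")
    coef = C - cfg.eta * np.outer(rho, rho) + cfg.mu
    np.fill_diagonal(coef, 0.0)
    return float(-0.5 * np.sum(coef * Jbin))


def _flip_dF(
    C: np.ndarray, rho: np.ndarray, Jbin: np.ndarray, cfg: StructuralConfig
) -> np.ndarray:
    """Energy change of toggling each (symmetric) pair between 0 and J_val."""
    coef = C - cfg.eta * np.outer(rho, rho) + cfg.mu
    delta = np.where(Jbin > 0, -cfg.J_val, cfg.J_val)  # J_new - J_old
    return -coef * delta


def structural_flip(
    Jbin: np.ndarray,
    ij: tuple[int, int],
    C: np.ndarray,
    rho: np.ndarray,
    cfg: StructuralConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Attempt one connection toggle with ``P = (1/tau) min[exp(-dF/T), 1]``.

    The pair ``(i, j)`` and its mirror are toggled together so that the
    coupling matrix stays symmetric.
    """
    i, j = ij
    if i == j:
        raise ValueError("self-connections are excluded")
    dF = _flip_dF(C, rho, Jbin, cfg)[i, j]
    p = min(np.exp(-dF / cfg.T), 1.0) / cfg.tau
    if rng.random() < p:
        new = 0.0 if Jbin[i, j] > 0 else cfg.J_val
        Jbin[i, j] = Jbin[j, i] = new
    return Jbin


def run_coupled_dynamics(
    cfg: StructuralConfig,
    N: int,
    steps: int,
    seed: int,
    record_every: int = 10,
    degree_sample_every: int | None = 20,
) -> tuple[dict, "DegreeDistribution"]:
    """Interleave firing sweeps and structural toggles.

    Each macro step runs one Metropolis firing sweep under the current
    couplings, refreshes the moving-window estimates of ``rho`` and ``C``,
    and then lets every neuron pair attempt a wiring toggle with the
    structural Metropolis rule (given the frozen window estimates the pair
    energies are independent, so the attempts are vectorized).  The window
    is seeded by ``window_len`` burn-in firing sweeps before the first
    structural attempt; while fewer sweeps than ``window_len`` have elapsed
    the available prefix is used.

    Returns a trajectory dict (edge counts, mean firing rate) and the
    cumulative degree distribution at equilibrium.  With
    ``degree_sample_every`` set (default: every 20 steps) the distribution
    pools degree snapshots over the second half of the run — the ergodic
    estimate of the stationary distribution, much less noisy than a single
    final snapshot; with ``None`` only the final graph is used.
    """
    if cfg.J_val < 5 * cfg.T:
        import warnings

        warnings.warn(
            "connection quantum J_val should be well above T "
            "(J_val >= 5T) for a crisp wired/unwired distinction",
            stacklevel=2,
        )
    rng = child_rng(seed, "bm-structure")
    A = np.zeros((N, N))  # binary adjacency; couplings are J_val * A
    phi = rng.integers(0, 2, size=N).astype(float)
    bias = np.full(N, cfg.bias)

    win = cfg.window_len
    hist = np.zeros((win, N))
    sum_phi = np.zeros(N)
    sum_outer = np.zeros((N, N))
    n_in_win = 0
    ptr = 0

    def fire_sweep() -> None:
        nonlocal phi
        order = rng.permutation(N)
        u = rng.random(N)
        Jw = cfg.J_val * A
        for k, i in enumerate(order):
            dphi = 1.0 - 2.0 * phi[i]
            dE = -(Jw[i] @ phi + bias[i]) * dphi
            if dE <= 0 or u[k] < np.exp(-dE / cfg.T):
                phi[i] = 1.0 - phi[i]

    def push_window() -> None:
        nonlocal n_in_win, ptr, sum_phi, sum_outer
        if n_in_win == win:
            old = hist[ptr]
            sum_phi -= old
            sum_outer -= np.outer(old, old)
        else:
            n_in_win += 1
        hist[ptr] = phi
        sum_phi += phi
        sum_outer += np.outer(phi, phi)
        ptr = (ptr + 1) % win

    # burn-in: fill the window before any wiring happens
    for _ in range(win):
        fire_sweep()
        push_window()

    iu = np.triu_indices(N, k=1)
    traj = {"step": [], "n_edges": [], "mean_rho": []}
    degree_pool: list[np.ndarray] = []
    for step in range(steps):
        fire_sweep()
        push_window()
        rho = sum_phi / n_in_win
        C = sum_outer / n_in_win
        dF = _flip_dF(C, rho, A * cfg.J_val, cfg)
        p = np.minimum(np.exp(np.minimum(-dF / cfg.T, 0.0)), 1.0) / cfg.tau
        toggle = rng.random(len(iu[0])) < p[iu]
        rows, cols = iu[0][toggle], iu[1][toggle]
        A[rows, cols] = 1.0 - A[rows, cols]
        A[cols, rows] = A[rows, cols]
        if step % record_every == 0 or step == steps - 1:
            traj["step"].append(step)
            traj["n_edges"].append(int(A[iu].sum()))
            traj["mean_rho"].append(float(rho.mean()))
        if (
            degree_sample_every
            and step >= steps // 2
            and step % degree_sample_every == 0
        ):
            degree_pool.append((A != 0).sum(axis=1))
    if degree_pool:
        return traj, cumulative_degree_distribution(np.concatenate(degree_pool))
    return traj, cumulative_degree_distribution(A)


@dataclass
class DegreeDistribution:
    """Cumulative degree distribution with a log-log least-squares line."""

    degrees: np.ndarray
    k: np.ndarray
    pcum: np.ndarray
    fit_slope: float
    fit_intercept: float
    fit_r2: float


def cumulative_degree_distribution(
    graph,
    fit_kmin: int = 1,
    fit_pmin: float = 0.02,
    fit_pmax: float = 0.8,
) -> DegreeDistribution:
    """Exact cumulative degree distribution ``Pcum(k) = P(degree >= k)``.

    ``graph`` may be an adjacency matrix (nonzero entries are edges), a
    ``networkx`` graph, or a 1-D array of degree samples (e.g. pooled over
    equilibrium snapshots).  ``Pcum`` is evaluated at the observed degrees;
    the least-squares line is fit on log-log axes over the central range
    ``k >= fit_kmin`` and ``fit_pmin <= Pcum <= fit_pmax``.  The defaults
    trim the saturated head (``Pcum -> 1`` at the minimum degree by
    construction) and the deep tail carried by a handful of nodes, where a
    finite network shows its size cutoff; if fewer than three points
    remain, the fit falls back to the full ``k >= fit_kmin`` support, and
    the fit fields are NaN when even that leaves fewer than three points.
    """
    import networkx as nx

    if isinstance(graph, nx.Graph):
        degrees = np.array([d for _, d in graph.degree()])
    else:
        arr = np.asarray(graph)
        if arr.ndim == 1:
            degrees = arr.astype(int)
        else:
            degrees = (arr != 0).sum(axis=1)
    if len(degrees) == 0 or degrees.max() == 0:
        raise ValueError("graph has no edges")
    ks = np.unique(degrees)
    ks = ks[ks >= 1]
    pcum = np.array([(degrees >= k).mean() for k in ks])
    sel = (ks >= fit_kmin) & (pcum >= fit_pmin) & (pcum <= fit_pmax)
    if sel.sum() < 3:
        sel = ks >= fit_kmin
    if sel.sum() >= 3:
        res = linregress(np.log10(ks[sel]), np.log10(pcum[sel]))
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    else:
        slope = intercept = r2 = float("nan")
    return DegreeDistribution(
        degrees=degrees,
        k=ks,
        pcum=pcum,
        fit_slope=slope,
        fit_intercept=intercept,
        fit_r2=r2,
    )
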