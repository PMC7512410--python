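"""Linear-network feature-map formation.

A two-layer linear network: output neurons receive feedforward weights ``W``
from input neurons and interact laterally through ``J`` (or directly through
the recursive interaction ``K = (I - J)^-1``).  The module implements

* the steady-state activity ``u = K W h``,
* correlation-based Hebbian learning ``dW ~ K W Q`` with the input
  correlation matrix ``Q_ij = <<h_i h_j>>``,
* the Gaussian free energy ``F = U - T S`` with ``U = -1/2 B' K B`` and
  ``S = 1/2 tr log(T K)`` whose derivatives recover the firing and learning
  rules,
* quenched-noise (pseudo-stochastic) Langevin sampling whose stationary
  output covariance has the closed form ``beta K K' + K W Q W' K'``,
* the entropy-driven competition term ``(W W')^-1 W`` and the PSL learning
  rule ``dW ~ K W Q + T (W W')^-1 W``,
* ocular-dominance and topographic-map development experiments with
  map-quality metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from ._rng import child_rng

__all__ = [
    "LayeredNetwork",
    "InputEnsemble",
    "FeatureMapResult",
    "steady_state_activity",
    "correlation_learning_step",
    "gaussian_free_energy",
    "langevin_simulate",
    "langevin_covariance_theory",
    "entropy_gradient_term",
    "psl_learning_step",
    "grid_positions",
    "mexican_hat_interaction",
    "develop_ocular_dominance",
    "develop_topographic_map",
    "map_metrics",
]


@dataclass
class LayeredNetwork:
    """Input/output layers with feedforward ``W`` and lateral ``J`` or ``K``.

    Exactly one of ``J`` (lateral couplings, spectral radius < 1) or ``K``
    (the recursive interaction, prescribed directly as in the map-formation
    experiments) must be given; when ``J`` is given, ``K = (I - J)^-1``.
    """

    n_in: int
    n_out: int
    W: np.ndarray
    J: np.ndarray | None = None
    K: np.ndarray | None = None
    positions_in: np.ndarray | None = None
    positions_out: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (self.n_out, self.n_in):
            raise ValueError("W must be n_out x n_in")
        if (self.J is None) == (self.K is None):
            raise ValueError("give exactly one of J or K")
        if self.J is not None:
            self.J = np.asarray(self.J, dtype=float)
            if self.J.shape != (self.n_out, self.n_out):
                raise ValueError("J must be n_out x n_out")
            rad = np.abs(np.linalg.eigvals(self.J)).max()
            if rad >= 1:
                raise ValueError("spectral radius of J must be < 1")
            self.K = np.linalg.inv(np.eye(self.n_out) - self.J)
        else:
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (self.n_out, self.n_out):
                raise ValueError("K must be n_out x n_out")

    @property
    def D(self) -> np.ndarray:
        """``D = I - J = K^-1`` (built from J when available)."""
        if self.J is not None:
            return np.eye(self.n_out) - self.J
        return np.linalg.inv(self.K)


@dataclass
class InputEnsemble:
    """Input correlation matrix ``Q`` with a zero-mean Gaussian sampler."""

    Q: np.ndarray
    _chol: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if not np.allclose(self.Q, self.Q.T):
            raise ValueError("Q must be symmetric")
        evals, evecs = np.linalg.eigh(self.Q)
        if evals.min() < -1e-10 * max(1.0, evals.max()):
            raise ValueError("Q must be positive semidefinite")
        self._chol = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    def sample(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """``n_draws`` rows of zero-mean Gaussian inputs with covariance Q."""
        z = rng.standard_normal((n_draws, self.Q.shape[0]))
        return z @ self._chol.T


def steady_state_activity(net: LayeredNetwork, h: np.ndarray) -> np.ndarray:
    """Fixed point of the linear rate dynamics: ``u_out = K W h``.

    Solved exactly (linear solve against ``I - J`` when J is given, direct
    product when K is prescribed).  Input neurons simply carry ``u = h``.
    """
    h = np.asarray(h, dtype=float)
    drive = net.W @ h
    if net.J is not None:
        return np.linalg.solve(np.eye(net.n_out) - net.J, drive)
    return net.K @ drive


def correlation_learning_step(
    net: LayeredNetwork, Q: np.ndarray, lr: float
) -> np.ndarray:
    """Hebbian step averaged over the input ensemble: ``W += lr K W Q``."""
    net.W = net.W + lr * net.K @ net.W @ np.asarray(Q, dtype=float)
    return net.W


def gaussian_free_energy(
    net: LayeredNetwork, h: np.ndarray, T: float
) -> tuple[float, float, float]:
    """Gaussian free energy ``F = U - T S`` of the linear network.

    ``U = -1/2 sum_ij K_ij B_i B_j`` with ``B = W h``, and
    ``S = 1/2 tr log(G)`` with ``G = T K``.  Requires ``D = I - J``
    symmetric positive definite so the Gaussian integral exists.
    ``-dF/dB_i = (K B)_i`` recovers the steady-state activity and
    ``-dF/dW_ij = (K W h)_i h_j`` the Hebbian learning rule.
    """
    D = net.D
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("I - J must be symmetric for the Gaussian integral")
    evals = np.linalg.eigvalsh(D)
    if evals.min() <= 0:
        raise ValueError("I - J must be positive definite")
    B = net.W @ np.asarray(h, dtype=float)
    K = net.K
    U = float(-0.5 * B @ K @ B)
    n = net.n_out
    # tr log(T K) = n log T - log det D
    S = float(0.5 * (n * np.log(T) - np.sum(np.log(evals))))
    return U - T * S, U, S


def langevin_covariance_theory(
    net: LayeredNetwork, Q: np.ndarray, beta: float
) -> np.ndarray:
    """Closed-form stationary output covariance ``beta K K' + K W Q W' K'``."""
    K, W = net.K, net.W
    return beta * K @ K.T + K @ W @ np.asarray(Q) @ W.T @ K.T


def langevin_simulate(
    net: LayeredNetwork,
    Q: np.ndarray,
    beta: float,
    n_steps: int,
    dt: float = 0.1,
    seed: int = 0,
    relax_steps: int | None = None,
    tau: float = 1.0,
) -> np.ndarray:
    """Sample the stationary output covariance of the noisy rate dynamics.

    The noise is quenched on the firing time scale (the "pseudo-stochastic"
    picture): each of the ``n_steps`` episodes draws an input vector ``h``
    with covariance ``Q`` and an endogenous noise vector ``xi`` with
    covariance ``beta I`` (both zero mean, mutually independent), lets the
    linear dynamics relax, and records the settled state
    ``u = K (W h + xi)``.  With ``relax_steps`` set, relaxation is done by
    explicit Euler integration of ``tau du/dt = -(I - J) u + W h + xi``
    instead of the exact solve.  Returns the empirical covariance, which
    converges to ``beta K K' + K W Q W' K'``.
    """
    if net.J is not None:
        rad = np.abs(np.linalg.eigvals(net.J)).max()
        if rad >= 1:
            raise ValueError("unstable lateral couplings")
    rng = child_rng(seed, "langevin")
    ens = InputEnsemble(np.asarray(Q, dtype=float))
    H = ens.sample(n_steps, rng)
    Xi = np.sqrt(beta) * rng.standard_normal((n_steps, net.n_out))
    drive = H @ net.W.T + Xi  # (n_steps, n_out)
    if relax_steps is None:
        U = drive @ net.K.T
    else:
        D = net.D
        U = np.zeros_like(drive)
        for _ in range(relax_steps):
            U = U + (dt / tau) * (-(U @ D.T) + drive)
    return (U.T @ U) / n_steps


def entropy_gradient_term(W: np.ndarray) -> np.ndarray:
    """Gradient of the output entropy with respect to the weights.

    For square ``W`` this is the gradient of ``tr log W = log|det W|``,
    i.e. ``(W^-1)'``; for rectangular ``W`` the Gram form
    ``1/2 tr log(W W')`` is used, giving ``(W W')^-1 W``.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] == W.shape[1]:
        return np.linalg.inv(W).T
    return np.linalg.solve(W @ W.T, W)


def psl_learning_step(
    net: LayeredNetwork,
    Q: np.ndarray,
    T: float,
    lr: float,
    approx: bool = False,
    normalize: bool = True,
) -> np.ndarray:
    """Entropy-regularized (pseudo-stochastic) learning step.

    ``W += lr [K W Q + T (W W')^-1 W]``; with ``approx=True`` the
    competition term uses ``(W W')^-1 ~= I - W W'`` (valid near the
    normalized manifold ``(W W')_ii = 1``).  With ``normalize=True`` rows
    are rescaled afterwards so that ``(W W')_ii = 1`` exactly.  At ``T = 0``
    (and without normalization) the step reduces to plain correlation-based
    learning.
    """
    W = net.W
    Q = np.asarray(Q, dtype=float)
    if T == 0.0:
        comp = np.zeros_like(W)
    elif approx:
        comp = (np.eye(net.n_out) - W @ W.T) @ W
    else:
        comp = np.linalg.solve(W @ W.T, W)
    W = W + lr * (net.K @ W @ Q + T * comp)
    if normalize:
        norms = np.linalg.norm(W, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise FloatingPointError("weight row collapsed to zero")
        W = W / norms
    net.W = W
    return W


# ---------------------------------------------------------------------------
# map-formation experiments
# ---------------------------------------------------------------------------


def grid_positions(n: int, spacing: float = 1.0) -> np.ndarray:
    """Coordinates of an n x n square lattice, row-major."""
    xs, ys = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return spacing * np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def mexican_hat_interaction(
    positions: np.ndarray, k: float, sigma: float
) -> np.ndarray:
    """Recursive lateral interaction ``K_ij = (1 - k r^2/sigma^2) exp(-r^2/2 sigma^2)``.

    ``k`` sets the strength of the inhibitory surround (``k = 0`` is purely
    excitatory); distances are Euclidean on the neuron grid.
    """
    r2 = _sq_dists(positions, positions)
    return (1.0 - k * r2 / sigma**2) * np.exp(-r2 / (2.0 * sigma**2))


@dataclass
class FeatureMapResult:
    """Outcome of a map-development run."""

    od: np.ndarray | None = None
    rf_centers: np.ndarray | None = None
    positions_out: np.ndarray | None = None
    positions_in: np.ndarray | None = None
    grid_n: int = 0
    W: np.ndarray | None = None


def develop_ocular_dominance(
    grid_n: int = 40,
    k: float = 0.5,
    sigma: float = 2.0,
    eta: float = 0.3,
    steps: int = 200,
    lr: float = 0.02,
    seed: int = 0,
    w_max: float = 1.0,
    w_init: np.ndarray | None = None,
) -> FeatureMapResult:
    """Ocular-dominance development with correlation-based learning.

    Two input neurons (left/right eye) feed an ``grid_n x grid_n`` output
    sheet with Mexican-hat recursive interaction
    ``K_ij = (1 - k r^2/sigma^2) exp(-r^2/2 sigma^2)`` and input correlation
    ``Q = [[1, eta], [eta, 1]]``.  Weights start small random positive and
    are clipped to ``[0, w_max]`` after every Hebbian step (pure linear
    Hebbian growth is unbounded; the clip is the saturating nonlinearity).
    The ocular dominance of an output neuron is the difference of its two
    feedforward weights.

    With sufficient surround inhibition (``k`` large enough) the dominance
    map segregates into alternating stripes — a dominant nonzero spatial
    frequency; with ``k = 0`` the map stays single-signed.
    """
    rng = child_rng(seed, "od-map")
    pos = grid_positions(grid_n)
    K = mexican_hat_interaction(pos, k, sigma)
    # scale the learning rate by the spectral norm so the growth rate per
    # step is comparable across grid sizes and k values
    knorm = np.linalg.norm(K, 2)
    Q = np.array([[1.0, eta], [eta, 1.0]])
    if w_init is None:
        W = rng.uniform(0.4, 0.6, size=(grid_n * grid_n, 2)) * w_max
    else:
        W = np.array(w_init, dtype=float)
    for _ in range(steps):
        W = W + (lr / knorm) * K @ W @ Q
        np.clip(W, 0.0, w_max, out=W)
    od = W[:, 0] - W[:, 1]
    return FeatureMapResult(
        od=od, positions_out=pos, grid_n=grid_n, W=W
    )


def develop_topographic_map(
    grid_n: int = 10,
    T: float = 0.1,
    steps: int = 2000,
    lr: float = 0.05,
    seed: int = 0,
    kernel_scale: float = 0.7,
) -> FeatureMapResult:
    """Topographic-map development with the entropy-driven (PSL) rule.

    Input and output layers are ``grid_n x grid_n`` sheets with
    ``K_ij = exp(-r_ij^2)`` on the output grid and ``Q_ab = exp(-r_ab^2)``
    on the input grid; ``kernel_scale`` is the lattice spacing entering the
    distances (the kernels' length unit is a free choice; the default 0.7
    makes them smooth enough for global ordering while keeping the
    competition selective).  The weights evolve by the approximate PSL rule
    ``dW ~ K W Q + T (I - W W') W`` with the row normalization
    ``(W W')_ii = 1`` after every step.  Receptive-field centers are the
    centroids of the (rectified, squared) weight mass on the input grid; at
    the stated temperature the centers spread into a grid that mirrors the
    output lattice, while a ``T = 0`` control collapses all centers onto a
    common centroid.
    """
    rng = child_rng(seed, "topo-map")
    pos_out = grid_positions(grid_n, spacing=kernel_scale)
    pos_in = grid_positions(grid_n, spacing=kernel_scale)
    K = np.exp(-_sq_dists(pos_out, pos_out))
    Q = np.exp(-_sq_dists(pos_in, pos_in))
    n = grid_n * grid_n
    W = rng.uniform(0.0, 1.0, size=(n, n))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    net = LayeredNetwork(n_in=n, n_out=n, W=W, K=K,
                         positions_in=pos_in, positions_out=pos_out)
    for _ in range(steps):
        psl_learning_step(net, Q, T=T, lr=lr, approx=True, normalize=True)
    rf = rf_centers(net.W, pos_in)
    return FeatureMapResult(
        rf_centers=rf,
        positions_out=pos_out,
        positions_in=pos_in,
        grid_n=grid_n,
        W=net.W,
    )


def rf_centers(W: np.ndarray, positions_in: np.ndarray) -> np.ndarray:
    """Weight-mass centroids on the input grid (rectified-squared mass)."""
    mass = np.clip(W, 0.0, None) ** 2
    tot = mass.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return (mass @ positions_in) / tot


def map_metrics(result: FeatureMapResult) -> dict:
    """Quality metrics of a developed map.

    Returns the dominant spatial frequency of the ocular-dominance map (via
    the 2-D power spectrum; radial index 0 means the mean dominates), the
    topographic order (Spearman rank correlation between output-grid
    pairwise distances and RF-center pairwise distances) and the dominance
    balance (mean OD).
    """
    out: dict = {}
    if result.od is not None:
        g = result.grid_n
        od_map = result.od.reshape(g, g)
        spec = np.abs(np.fft.fft2(od_map)) ** 2
        fx = np.fft.fftfreq(g)
        fy = np.fft.fftfreq(g)
        idx = np.unravel_index(np.argmax(spec), spec.shape)
        out["dominant_frequency"] = float(np.hypot(fx[idx[0]], fy[idx[1]]))
        out["od_balance"] = float(result.od.mean())
    if result.rf_centers is not None:
        out["topographic_order"] = topographic_order(
            result.positions_out, result.rf_centers
        )
    return out


def topographic_order(positions_out: np.ndarray, rf_centers: np.ndarray) -> float:
    """Spearman correlation of output-grid vs RF-center pairwise distances."""
    from scipy.spatial.distance import pdist

    rho, _ = spearmanr(pdist(positions_out), pdist(rf_centers))
    return float(rho)
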