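"""Hopfield associative memory.

Outer-product pattern storage, deterministic zero-temperature dynamics,
finite-temperature single-spin Metropolis dynamics, and the Ising energy whose
local minima are the stored patterns.  States are spin-valued,
``sigma_i in {-1, +1}``; updates are asynchronous (one neuron at a time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import child_rng

__all__ = [
    "HopfieldNetwork",
    "PatternSet",
    "store_patterns",
    "zero_T_update",
    "energy",
    "metropolis_update",
    "sweep",
    "run_to_fixed_point",
    "recall_experiment",
]


@dataclass
class PatternSet:
    """A set of ``p`` binary patterns with overall storage strength ``eta``."""

    patterns: np.ndarray
    eta: float = 1.0

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be a p x N array")
        if not np.isin(self.patterns, (-1, 1)).all():
            raise ValueError("pattern entries must be -1 or +1")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        self.patterns = self.patterns.astype(np.int8)


@dataclass
class HopfieldNetwork:
    """Symmetric couplings ``J`` (zero diagonal), biases ``B``, spin state."""

    J: np.ndarray
    B: np.ndarray
    state: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.state = np.asarray(self.state)
        n = self.J.shape[0]
        if self.J.shape != (n, n):
            raise ValueError("J must be square")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("J must have zero diagonal (no self-connection)")
        if self.B.shape != (n,):
            raise ValueError("B must have length N")
        if self.state.shape != (n,) or not np.isin(self.state, (-1, 1)).all():
            raise ValueError("state entries must be -1 or +1")
        self.state = self.state.astype(np.int8)

    @property
    def n(self) -> int:
        return self.J.shape[0]


def store_patterns(ps: PatternSet, state: np.ndarray | None = None) -> HopfieldNetwork:
    """Build the network with the outer-product (Hebbian) coupling matrix.

    ``J_ij = eta * sum_n sigma_i^(n) sigma_j^(n)`` off the diagonal and
    ``J_ii = 0``.
    """
    S = ps.patterns.astype(float)
    J = ps.eta * (S.T @ S)
    np.fill_diagonal(J, 0.0)
    n = J.shape[0]
    if state is None:
        state = np.ones(n, dtype=np.int8)
    return HopfieldNetwork(J=J, B=np.zeros(n), state=np.asarray(state))


def local_field(net: HopfieldNetwork, i: int) -> float:
    return float(net.J[i] @ net.state + net.B[i])


def energy(net: HopfieldNetwork, state: np.ndarray | None = None) -> float:
    """Ising energy ``E = -1/2 sum_ij J_ij s_i s_j - sum_i B_i s_i``."""
    s = net.state if state is None else np.asarray(state)
    s = s.astype(float)
    return float(-0.5 * s @ net.J @ s - net.B @ s)


def zero_T_update(net: HopfieldNetwork, order: np.ndarray) -> np.ndarray:
    """Apply the deterministic threshold rule sequentially along ``order``.

    ``sigma_i <- +1`` iff the local field ``sum_j J_ij sigma_j + B_i >= 0``
    (ties resolve to +1), else -1.  Mutates and returns ``net.state``.  The
    energy is non-increasing along the trajectory (Lyapunov property of
    asynchronous dynamics with symmetric couplings).
    """
    order = np.asarray(order)
    if sorted(order.tolist()) != list(range(net.n)):
        raise ValueError("order must be a permutation of all neurons")
    s = net.state
    for i in order:
        s[i] = 1 if net.J[i] @ s + net.B[i] >= 0 else -1
    return s


def metropolis_update(
    net: HopfieldNetwork,
    T: float,
    rng_seed: int | np.random.Generator,
    order: np.ndarray | None = None,
) -> np.ndarray:
    """One asynchronous Metropolis sweep at temperature ``T``.

    Each neuron in ``order`` (a fresh random permutation when omitted)
    attempts a spin flip accepted with probability ``min[1, exp(-dE/T)]``.
    ``T = 0`` is taken as a strict limit with no division: flip iff
    ``dE < 0``, and at exact ties (``dE = 0``, i.e. zero local field) the
    spin is set to +1, reproducing the deterministic rule.
    """
    if T < 0:
        raise ValueError("temperature must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    if order is None:
        order = rng.permutation(net.n)
    s = net.state
    for i in order:
        h = net.J[i] @ s + net.B[i]
        dE = 2.0 * s[i] * h
        if T == 0.0:
            if dE < 0:
                s[i] = -s[i]
            elif dE == 0:
                s[i] = 1
        else:
            if dE <= 0 or rng.random() < np.exp(-dE / T):
                s[i] = -s[i]
    return s


def sweep(
    net: HopfieldNetwork, T: float, rng: np.random.Generator
) -> np.ndarray:
    """Convenience: one Metropolis sweep with a fresh random permutation."""
    return metropolis_update(net, T, rng, order=rng.permutation(net.n))


def run_to_fixed_point(
    net: HopfieldNetwork,
    rng: np.random.Generator,
    max_sweeps: int = 100,
    assert_lyapunov: bool = False,
) -> tuple[np.ndarray, int]:
    """Iterate zero-temperature sweeps until no spin flips.

    Returns the fixed-point state and the number of sweeps used.  With
    ``assert_lyapunov`` the energy is checked to be non-increasing after
    every single-neuron update.
    """
    for k in range(max_sweeps):
        before = net.state.copy()
        order = rng.permutation(net.n)
        if assert_lyapunov:
            e = energy(net)
            for i in order:
                h = net.J[i] @ net.state + net.B[i]
                net.state[i] = 1 if h >= 0 else -1
                e_new = energy(net)
                if e_new > e + 1e-9:
                    raise AssertionError("energy increased during zero-T update")
                e = e_new
        else:
            zero_T_update(net, order)
        if np.array_equal(net.state, before):
            return net.state, k + 1
    return net.state, max_sweeps


def recall_experiment(
    n: int = 100,
    p: int = 5,
    flip_frac: float = 0.10,
    n_trials: int = 100,
    eta: float = 1.0,
    seed: int = 0,
    max_sweeps: int = 100,
    assert_lyapunov: bool = False,
) -> dict:
    """Pattern-completion experiment in the low-load regime.

    Stores ``p`` random patterns in an ``n``-neuron network, corrupts a
    stored pattern by flipping a fraction ``flip_frac`` of its bits, runs
    zero-temperature dynamics to a fixed point and scores exact recovery of
    the stored pattern.  Returns the success rate over ``n_trials`` trials
    together with per-trial overlaps.
    """
    rng = child_rng(seed, "hopfield-recall")
    successes = 0
    overlaps = []
    for _ in range(n_trials):
        patterns = rng.choice([-1, 1], size=(p, n))
        net = store_patterns(PatternSet(patterns, eta=eta))
        target = patterns[rng.integers(p)]
        corrupted = target.copy()
        flip_idx = rng.choice(n, size=int(round(flip_frac * n)), replace=False)
        corrupted[flip_idx] *= -1
        net.state = corrupted.astype(np.int8)
        final, _ = run_to_fixed_point(
            net, rng, max_sweeps=max_sweeps, assert_lyapunov=assert_lyapunov
        )
        overlap = float(final @ target) / n
        overlaps.append(abs(overlap))
        if overlap == 1.0:
            successes += 1
    return {
        "n": n,
        "p": p,
        "flip_frac": flip_frac,
        "n_trials": n_trials,
        "success_rate": successes / n_trials,
        "mean_abs_overlap": float(np.mean(overlaps)),
    }
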