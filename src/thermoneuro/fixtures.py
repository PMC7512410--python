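"""Seeded generators for synthetic inputs and run configuration.

Every stochastic object in the package is produced from an integer seed
through named child streams (see ``_rng``), so runs are byte-reproducible
and adding a generator never perturbs existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._rng import child_rng
from .feature_map import InputEnsemble
from .hopfield import PatternSet
from .kernels import SpikeRaster, TimeGrid

__all__ = [
    "RunConfig",
    "gen_patterns",
    "gen_poisson_raster",
    "gen_input_ensemble",
]


@dataclass
class RunConfig:
    """A reproducible run: model name, flat parameter map, seed, output dir."""

    model: str
    params: dict
    seed: int
    output_dir: Path

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.params,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
        }


def gen_patterns(n: int, p: int, seed: int, eta: float = 1.0) -> PatternSet:
    """``p`` i.i.d. uniform +-1 patterns of length ``n``."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    rng = child_rng(seed, "patterns")
    return PatternSet(rng.choice([-1, 1], size=(p, n)), eta=eta)


def gen_poisson_raster(
    n_neurons: int, grid: TimeGrid, rate: float, seed: int
) -> SpikeRaster:
    """Independent Bernoulli(rate * dt) spiking in every bin."""
    p = rate * grid.dt
    if p > 1:
        raise ValueError("rate * dt must not exceed 1")
    rng = child_rng(seed, "poisson-raster")
    values = (rng.random((n_neurons, grid.n_steps)) < p).astype(np.int8)
    return SpikeRaster(values, grid)


def gen_input_ensemble(Q: np.ndarray, seed: int) -> tuple[InputEnsemble, np.random.Generator]:
    """An input ensemble with covariance ``Q`` plus its seeded sampler rng."""
    ens = InputEnsemble(np.asarray(Q, dtype=float))
    return ens, child_rng(seed, "input-ensemble")
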