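"""Seed fan-out for reproducible simulations.

A single user-facing integer seed is expanded into independent per-purpose
streams keyed by a stable string, so adding a new consumer never perturbs the
streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, stream: str) -> np.random.SeedSequence:
    """Derive a named child seed sequence from a global integer seed."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """A fresh Generator for the named stream under the global seed."""
    return np.random.default_rng(child_seed(seed, stream))
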