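"""Seed-derivation helpers.

Every stochastic component takes either an integer seed or a
``numpy.random.Generator``.  Independent substreams are derived through
``SeedSequence`` spawn keys built from string tokens, so a master seed plus a
run's coordinates (condition, scheme, replicate index) always map to the same
stream regardless of execution order.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["as_generator", "child_rng", "spawn"]


def as_generator(random_state: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(random_state, np.random.Generator):
        return random_state
    return np.random.default_rng(random_state)


def _token_key(token: str | int) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    digest = hashlib.sha256(str(token).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def spawn(seed: int, *tokens: str | int) -> np.random.SeedSequence:
    """Deterministic SeedSequence for (seed, tokens), stable across sessions."""
    return np.random.SeedSequence(int(seed), spawn_key=tuple(_token_key(t) for t in tokens))


def child_rng(seed: int, *tokens: str | int) -> np.random.Generator:
    """Generator on the independent substream keyed by ``tokens``."""
    return np.random.default_rng(spawn(seed, *tokens))
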