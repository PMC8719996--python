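"""Shared helpers: validation error type and seeded RNG plumbing."""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


class ValidationError(ValueError):
    """Raised when an operation's preconditions are violated."""


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    """Derive ``n`` independent child seed sequences from a master seed."""
    return np.random.SeedSequence(seed).spawn(n)
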