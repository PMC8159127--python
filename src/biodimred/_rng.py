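"""Seed plumbing: all randomness flows from one explicit integer seed.

Stages derive child seeds with :func:`child_seeds` so that, e.g., adding a
classifier to an experiment never perturbs data generation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_seeds", "rng_from"]

_MOD = 2**31


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from ``seed``."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint64)
    return [int(s % _MOD) for s in state]


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))
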