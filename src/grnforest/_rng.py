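"""Seed plumbing: every source of randomness derives from one master seed.

A master integer seed is expanded through :class:`numpy.random.SeedSequence`
into per-gene, per-stage and per-tree streams, so that serial and parallel
runs, and repeated runs with the same seed, are identical.
"""

from __future__ import annotations

import numpy as np


def as_seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if seed is None:
        seed = 0
    return np.random.SeedSequence(int(seed))


def tree_seeds(seed, n: int) -> np.ndarray:
    """Derive ``n`` per-tree seeds (int64, < 2**31) from a seed/SeedSequence."""
    ss = as_seed_sequence(seed)
    return (ss.generate_state(n) & 0x7FFFFFFF).astype(np.int64)


def generator(seed) -> np.random.Generator:
    return np.random.default_rng(as_seed_sequence(seed))
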