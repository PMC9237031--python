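"""Seed handling shared across the package.

Every stochastic entry point takes a ``seed`` argument that may be an int,
a ``numpy.random.SeedSequence``, an existing ``numpy.random.Generator`` or
``None``.  Long-running permutation loops spawn one child ``SeedSequence``
per iteration so results do not depend on evaluation order.
"""

from __future__ import annotations

import numpy as np

SeedLike = "int | np.random.SeedSequence | np.random.Generator | None"


def as_rng(seed=None) -> np.random.Generator:
    """Coerce ``seed`` into a ``numpy.random.Generator``."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    """Spawn ``n`` independent child seed sequences from ``seed``."""
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        raise TypeError("cannot spawn substreams from a Generator; pass an int or SeedSequence")
    else:
        ss = np.random.SeedSequence(seed)
    return ss.spawn(n)


def seed_int(seed) -> int:
    """Derive a plain non-negative int (< 2**31) from any seed-like value.

    Needed for libraries that only accept integer seeds.
    """
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1, dtype=np.uint32)[0]) % (2**31)
    if seed is None:
        seed = np.random.SeedSequence().entropy
    return int(np.random.SeedSequence(int(seed)).generate_state(1, dtype=np.uint32)[0]) % (2**31)
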