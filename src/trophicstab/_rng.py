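"""Deterministic seed derivation.

All randomness in the package flows from a single root seed. Child
generators are derived through ``numpy.random.SeedSequence`` spawn keys so
that any community, grid cell or replicate can be re-generated in
isolation, independent of execution order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def child_seed_sequence(root_seed: int, *key: int) -> np.random.SeedSequence:
    """Seed sequence for the child stream identified by ``key``."""
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=tuple(int(k) for k in key))


def child_rng(root_seed: int, *key: int) -> np.random.Generator:
    """Generator for the child stream identified by ``key``.

    Identical (root_seed, key) pairs always yield identical streams.
    """
    return np.random.default_rng(child_seed_sequence(root_seed, *key))
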