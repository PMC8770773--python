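"""Deterministic seed derivation.

All randomness in the package flows from a single master seed.  Substreams
are derived per (participant, phase, purpose, ...) by hashing the string
form of each key into a :class:`numpy.random.SeedSequence`, so any single
participant or resampling iteration can be replayed in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed_sequence"]


def derive_seed_sequence(master_seed: int, *keys: object) -> np.random.SeedSequence:
    entropy = [int(master_seed) & 0xFFFFFFFF]
    entropy += [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.SeedSequence(entropy)


def derive_rng(master_seed: int, *keys: object) -> np.random.Generator:
    """Generator for the substream identified by ``keys`` under ``master_seed``."""
    return np.random.default_rng(derive_seed_sequence(master_seed, *keys))
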