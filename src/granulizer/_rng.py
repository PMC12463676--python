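"""Seeded random-stream derivation shared by all generators.

Each synthetic-data generator draws from an independent stream derived from
(seed, generator-name), so adding or reordering generators never perturbs
another generator's output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng"]


def derive_rng(seed: int, name: str) -> np.random.Generator:
    """Return a Generator on an independent stream keyed by ``(seed, name)``."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), tag)))
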