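"""Deterministic derivation of named random streams from one master seed.

Every source of randomness in the package (connectivity wiring, STN
spike generation, conductance heterogeneity, synaptic conductance draws)
draws from its own stream, derived from the master seed and a stable
stream name.  This makes trial batteries reproducible while keeping the
streams statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_seed", "stream_rng"]


def stream_seed(master_seed: int, *names) -> int:
    """A 31-bit child seed derived from the master seed and stream names."""
    key = ":".join(str(n) for n in names).encode()
    return (int(master_seed) ^ zlib.crc32(key)) & 0x7FFFFFFF


def stream_rng(master_seed: int, *names) -> np.random.Generator:
    """Generator for the named stream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF,
                               spawn_key=tuple(zlib.crc32(str(n).encode()) for n in names))
    )
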