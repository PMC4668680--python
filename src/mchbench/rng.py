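"""Deterministic per-operation random streams.

Every simulator and sampler in the package draws from its own named
substream of a single master seed, so that reordering, adding or removing
one simulation never perturbs another.  The splitting rule is: each string
key is hashed with CRC-32 and the resulting tuple is used as the
``spawn_key`` of a :class:`numpy.random.SeedSequence` rooted at the master
seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_rng", "substream_seed"]


def _key_ints(keys: tuple) -> tuple[int, ...]:
    return tuple(zlib.crc32(str(k).encode("utf8")) for k in keys)


def stream_rng(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``."""
    ss = np.random.SeedSequence(int(master_seed) % (2**31), spawn_key=_key_ints(keys))
    return np.random.default_rng(ss)


def substream_seed(master_seed: int, *keys) -> int:
    """A 31-bit integer seed derived from the named substream (for APIs
    that take a plain seed rather than a Generator)."""
    ss = np.random.SeedSequence(int(master_seed) % (2**31), spawn_key=_key_ints(keys))
    return int(ss.generate_state(1)[0] % (2**31))
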