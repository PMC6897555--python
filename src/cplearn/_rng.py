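"""Deterministic random-stream fan-out.

A single master seed is expanded into independent named substreams so any
generated object (one stimulus, one schedule, one subject) is reproducible in
isolation without replaying everything generated before it.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("substream keys must be non-negative")
        return int(key)
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"unsupported substream key type: {type(key)!r}")


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream identified by ``(seed, *keys)``.

    Keys may be non-negative integers or short strings (hashed with CRC32).
    Distinct key tuples yield statistically independent streams via
    ``numpy.random.SeedSequence``.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    entropy = [int(seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
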