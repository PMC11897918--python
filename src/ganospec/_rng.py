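"""Seeded random-stream management.

Every stochastic stage of the pipeline draws from a named substream derived
from one master seed, so a single integer reproduces every artifact while
stages stay statistically independent of each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _tag_entropy(tag) -> int:
    if isinstance(tag, (bytes, bytearray)):
        return zlib.crc32(bytes(tag))
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def child_seed(seed: int, *tags) -> list[int]:
    """Entropy sequence for a named substream of ``seed``."""
    return [int(seed) & 0x7FFFFFFF] + [_tag_entropy(t) for t in tags]


def substream(seed: int, *tags) -> np.random.Generator:
    """Generator for the substream of ``seed`` identified by ``tags``.

    Identical (seed, tags) always yield an identical stream; distinct tags
    yield streams seeded from distinct entropy.
    """
    return np.random.default_rng(child_seed(seed, *tags))
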