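"""Seeding utilities: one global seed, named per-stage substreams."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_rng"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of a global seed.

    Distinct names yield statistically independent streams; the mapping is
    stable across processes, so any stage can be re-run in isolation.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept either a seed or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
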