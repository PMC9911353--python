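"""Named RNG substreams: one global seed, independently reproducible stages."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for stage ``name`` derived from the global ``seed``.

    The same (seed, name) pair always yields the same stream, and distinct
    names yield statistically independent streams, so each pipeline stage
    is reproducible in isolation.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
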