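"""Deterministic per-stream random generators derived from one root seed.

Every stochastic stage derives its generator from the root seed plus a
tuple of string labels (element, scenario, quantity), so the full study is
reproducible and individual streams can be re-created in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and a label path.

    Labels are hashed with CRC32 into the SeedSequence spawn key; distinct
    label paths give statistically independent streams.
    """
    key = tuple(zlib.crc32(str(label).encode("utf-8")) for label in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
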