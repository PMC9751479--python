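"""Named seed fan-out: every stage draws from its own substream."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic child generator for (seed, stage-name).

    Stable under stage reordering because the child key depends only on
    the stage name, not on call order.
    """
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
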