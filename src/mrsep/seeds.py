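"""Named random substreams.

Every stochastic stage (parameter sampling, measurement noise, network
initialization, batch shuffling, ...) draws from its own substream derived
from one master seed and a stage name, so regenerating any single artifact is
reproducible without replaying the whole pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "rng_for"]


def substream(master_seed: int, *names: str) -> np.random.SeedSequence:
    """SeedSequence for the substream ``names`` under ``master_seed``."""
    keys = [zlib.crc32(n.encode()) & 0x7FFFFFFF for n in names]
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *keys])


def rng_for(master_seed: int, *names: str) -> np.random.Generator:
    """Generator seeded on the named substream."""
    return np.random.default_rng(substream(master_seed, *names))
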