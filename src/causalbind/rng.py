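"""Named random substreams derived from a single master seed.

Every source of randomness in the package draws from a substream keyed by
what it is for (e.g. ``("s03", "pre", "latents")``), so any piece of a run
can be reproduced in isolation and the keys can be recorded in outputs.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(master_seed: int, *keys) -> np.random.Generator:
    """A generator for the substream named by ``keys`` under ``master_seed``."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def substream_seed(master_seed: int, *keys) -> int:
    """A stable 31-bit integer seed for the substream named by ``keys``."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] & 0x7FFFFFFF)
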