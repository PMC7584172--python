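"""Named random substreams derived from one global seed.

Each generation stage (geography, community, hospitals, discharges, ...)
draws from its own substream, so regenerating one stage never perturbs the
others.  Substreams are derived deterministically from (seed, stage name).
"""

from __future__ import annotations

import zlib

import numpy as np

_STREAM_KEYS = {}


def substream(seed: int, stage: str) -> np.random.Generator:
    """Return the generator for ``stage`` under global ``seed``.

    The stage name is hashed (CRC-32) into the spawn key of a
    ``SeedSequence``, which guarantees independent, reproducible streams.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)
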