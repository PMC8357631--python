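"""Named, reproducible random streams.

All randomness in the package flows from one integer seed. Each consumer
asks for a stream by name; the (seed, name) pair maps deterministically to
an independent :class:`numpy.random.Generator`, so regenerating one table
never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """Generator for the named stream derived from ``seed``."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
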