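"""Deterministic fan-out of one master seed into named substreams.

Every stochastic component (enhancer, loaders, k-means, classifiers,
generators) draws its seed from ``derive_seed(master, *names)`` so a single
integer reproduces an entire experiment.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *names: object) -> int:
    """A stable sub-seed (< 2**31) for the named substream of ``master``."""
    keys = [int(master) & 0x7FFFFFFF]
    for name in names:
        keys.append(zlib.crc32(str(name).encode()) & 0x7FFFFFFF)
    seq = np.random.SeedSequence(keys)
    return int(seq.generate_state(1)[0] % (2**31))


def rng_for(master: int, *names: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *names))
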