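"""Seeded random-number substreams.

Every stochastic component draws from a named substream derived from a single
run seed, so that adding draws to one component never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is a CRC32 of the name, so streams are stable across
    sessions and independent of call order.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
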