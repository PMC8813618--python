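"""Shared helpers: seeded random substreams and small validation utilities."""

from __future__ import annotations

import zlib

import numpy as np

KINGDOMS = ("bacteria", "fungi", "archaea", "viruses")


def substream_seed(master_seed: int, name: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a master seed and a label.

    Every stochastic stage draws its seed through this function so that
    changing one stage's label never perturbs another stage's stream.
    """
    h = zlib.crc32(name.encode("utf-8"))
    return int((int(master_seed) * 0x9E3779B1 + h) % (2**31 - 1))


def rng_for(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(master_seed, name))
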