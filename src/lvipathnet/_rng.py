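"""Seeded random-number substreams.

All randomness in the pipeline flows from a single integer seed. Each
consumer (synthesis, augmentation, splitting, weight init, ...) draws from a
named substream so that adding a stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return an independent ``Generator`` for ``name`` derived from ``seed``.

    The substream key is a CRC32 of the name, so the mapping is stable
    across processes and Python versions.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
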