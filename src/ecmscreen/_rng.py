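"""Seed-substream derivation.

All randomness in the package flows from one top-level integer seed.
Independent substreams are derived with :class:`numpy.random.SeedSequence`
using a ``spawn_key`` built from CRC32 hashes of string labels, so a
pipeline stage gets the same stream regardless of the order stages run in.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels`` under ``seed``.

    ``substream(7, "scene", 3)`` is independent of ``substream(7, "counts")``
    and reproducible across processes and platforms.
    """
    key = tuple(
        zlib.crc32(str(lab).encode()) if isinstance(lab, str) else int(lab) & 0xFFFFFFFF
        for lab in labels
    )
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
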