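"""Deterministic sub-seed derivation.

Every stochastic routine in the package draws from a Generator derived from
a single integer seed plus a tuple of string/integer tags.  Tags are hashed
with CRC-32 so that e.g. adding a subject to a simulation does not reshuffle
the streams of existing subjects.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seedseq"]


def _tag_to_int(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def derive_seedseq(seed: int, *tags: object) -> np.random.SeedSequence:
    """SeedSequence for ``(seed, *tags)``, stable across runs and platforms."""
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(_tag_to_int, tags)])


def derive_rng(seed: int, *tags: object) -> np.random.Generator:
    """Independent Generator keyed by an integer seed and entity tags."""
    return np.random.default_rng(derive_seedseq(seed, *tags))
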