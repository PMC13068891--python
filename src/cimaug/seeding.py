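"""Deterministic seed substreams.

All randomness in the package flows from one integer seed through named,
ordered substreams, so that adding or reordering one consumer (e.g. a new
augmentation variant) never perturbs the draws of another.  Substream
identity is the tuple of labels, hashed with CRC-32 so results are stable
across processes and platforms (unlike Python's randomised ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_for", "substream"]


def seed_for(seed: int, *labels: object) -> int:
    """Derive a child integer seed (< 2**31) from ``seed`` and a label path."""
    entropy = [int(seed)] + [zlib.crc32(str(lab).encode("utf-8")) for lab in labels]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, *labels: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded from a named substream of ``seed``."""
    return np.random.default_rng(seed_for(seed, *labels))
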