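"""Deterministic RNG spawning.

Randomized stages derive independent child generators from a single global
seed plus string keys (e.g. a stratum code), so adding or removing one
stratum never perturbs the random streams of the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, *keys: str) -> int:
    """A stable 31-bit seed derived from a global seed and string keys."""
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for k in keys:
        h.update(b"\x00")
        h.update(str(k).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def child_rng(seed: int, *keys: str) -> np.random.Generator:
    """Independent generator for (seed, keys); stable across runs."""
    return np.random.default_rng(child_seed(seed, *keys))
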