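"""Seed plumbing.

A single user-facing seed fans out to independent child seeds, one per named
stage or sample, via stable hashing. Child seeds are therefore reproducible
independently of the order in which stages execute.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, name: str) -> int:
    """Derive a deterministic child seed (< 2**31) from ``seed`` and a label."""
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def child_rng(seed: int, name: str) -> np.random.Generator:
    """A ``numpy`` Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(seed, name))
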