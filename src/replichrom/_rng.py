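"""Seed-substream plumbing.

Every source of randomness in the package flows from a single integer seed
via named substreams, so any stage can be re-run in isolation and reproduce
its output exactly.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "subseed"]


def _name_key(name: str) -> int:
    digest = hashlib.blake2b(name.encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def subseed(seed: int, *names: str) -> int:
    """Derive a deterministic child seed (< 2**31) for a named substream."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_name_key(n) for n in names))
    return int(ss.generate_state(1)[0] % (2**31))


def substream(seed: int, *names: str) -> np.random.Generator:
    """Generator for the (seed, names...) substream."""
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=tuple(_name_key(n) for n in names))
    )
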