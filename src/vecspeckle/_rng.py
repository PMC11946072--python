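"""Deterministic child-seed derivation.

Every stochastic component in the package draws from a child generator
derived from one root seed plus a symbolic path, e.g.
``rng_for(seed, "medium", 3)``.  The path is hashed into a
``numpy.random.SeedSequence`` spawn key, so any single sample, medium or
glyph can be re-created in isolation without replaying the whole run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "child_seed"]


def _key(parts: tuple) -> tuple[int, ...]:
    out = []
    for p in parts:
        if isinstance(p, (int, np.integer)):
            out.append(int(p) & 0xFFFFFFFF)
        else:
            out.append(zlib.crc32(str(p).encode()))
    return tuple(out)


def rng_for(root_seed: int, *path) -> np.random.Generator:
    """Child generator for (root_seed, path); pure function of its arguments."""
    return np.random.default_rng(
        np.random.SeedSequence(int(root_seed) & 0x7FFFFFFF, spawn_key=_key(path))
    )


def child_seed(root_seed: int, *path) -> int:
    """A 31-bit integer seed derived from (root_seed, path)."""
    return int(rng_for(root_seed, *path).integers(0, 2**31 - 1))
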