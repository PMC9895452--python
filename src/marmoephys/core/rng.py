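"""Deterministic, named random streams."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["seeded_rng"]


def seeded_rng(seed: int, stream: str = "") -> np.random.Generator:
    """Return a Generator determined by ``(seed, stream)``.

    Identical pairs give identical draws; distinct stream names give
    statistically independent streams for the same seed. Platform-independent
    (the stream name is folded in via SHA-256).
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    digest = hashlib.sha256(stream.encode("utf-8")).digest()
    words = np.frombuffer(digest[:16], dtype="<u4").tolist()
    return np.random.default_rng(np.random.SeedSequence([int(seed), *words]))
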