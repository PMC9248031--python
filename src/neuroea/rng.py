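"""Seeded random-number streams.

All randomness in a run flows from one root seed; independent consumers
(initialisation, variation, target noise, stimulus shuffling...) each get a
named child stream so that adding a draw in one place never perturbs
another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["named_stream"]


def named_stream(seed: int, name: str) -> np.random.Generator:
    """A generator derived from ``(seed, name)``, stable across runs."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
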