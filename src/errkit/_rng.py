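"""Named random streams derived from a single user seed.

Every stochastic component of the package draws from its own named stream
so that, e.g., the outcome draws are unchanged when the error model changes.
Streams are derived deterministically from (seed, name) via SeedSequence.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """A reproducible 31-bit integer seed for the stream `name`."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def stream(seed: int, name: str) -> np.random.Generator:
    """Generator for the independent stream `name` under master `seed`."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    return np.random.default_rng(ss)
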