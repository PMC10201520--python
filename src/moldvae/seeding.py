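"""Deterministic fan-out of one global seed into named per-component streams.

Each subsystem (dataset split, PCD chains, spike-and-exponential draws,
decoding, ...) gets its own independent `numpy.random.Generator`, so runs are
reproducible component-by-component: changing how often one subsystem draws
never perturbs another.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stream(seed: int, name: str) -> np.random.Generator:
    """A named random stream derived deterministically from the global seed."""
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
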