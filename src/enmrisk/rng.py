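"""Seed derivation for per-stage reproducibility.

One pipeline-level seed is supplied in the configuration; each stage
derives its own sub-seed by stable hashing of ``(seed, stage_name)`` so
that rerunning a single stage reproduces its stream regardless of what
ran before it.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(seed: int, stage: str) -> int:
    """Stable sub-seed in [0, 2**31) from a base seed and a stage name."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Generator seeded with :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(seed, stage))
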