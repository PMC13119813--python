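"""Small shared helpers: seed derivation and validation."""

from __future__ import annotations

import zlib

import numpy as np

_SEED_MOD = 2**31


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific seed from a master seed.

    Uses a CRC32 of the stage name so every pipeline stage gets an
    independent, reproducible stream; the result is kept below 2**31 so
    it is valid for every RNG consumer (numpy, scikit-learn, xgboost).
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return int((int(master_seed) * 1000003 + tag) % _SEED_MOD)


def rng_from(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def check_positive_int(value: int, name: str) -> int:
    if not isinstance(value, (int, np.integer)) or value <= 0:
        raise ValueError(f"{name} must be a positive integer, got {value!r}")
    return int(value)
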