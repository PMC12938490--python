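"""Internal helpers: seed derivation and array coercion."""

from __future__ import annotations

import hashlib

import numpy as np

# Derived seeds must stay below 2**31 so they are valid for every RNG backend.
_SEED_MOD = 2**31


def derive_seed(master_seed: int, *names: object) -> int:
    """Derive a stage seed from a master seed and a stage path.

    Hash-based fan-out: adding a new stage never perturbs the stream of an
    existing one. Deterministic across processes and platforms.
    """
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(master_seed)).encode())
    for name in names:
        h.update(b"/")
        h.update(str(name).encode())
    return int.from_bytes(h.digest(), "little") % _SEED_MOD


def as_1d_float(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def as_2d_float(values, name: str = "matrix") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be two-dimensional, got shape {arr.shape}")
    return arr
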