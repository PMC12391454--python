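"""Deterministic seed derivation.

Every stochastic stage derives its own 31-bit seed from the experiment master
seed plus a stage-specific label, so stages can be re-run independently and the
whole study is reproducible from a single integer.
"""
from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master: int, *labels: object) -> int:
    """Derive a stable 31-bit child seed from ``master`` and string labels."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for lab in labels:
        h.update(b"\x00")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(master: int, *labels: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *labels))
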