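"""Deterministic sub-seed derivation.

A single master seed drives every stochastic stage.  Sub-seeds are derived by
hashing the master seed together with string labels (mouse id, receptor type,
stage name), so adding or removing one mouse never perturbs the draws of the
others, and parallel stage execution cannot change results.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(master_seed: int, *labels: object) -> int:
    """Derive a 32-bit sub-seed from a master seed and a label path."""
    token = ":".join([str(int(master_seed))] + [str(l) for l in labels])
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def derive_rng(master_seed: int, *labels: object) -> np.random.Generator:
    """A fresh generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *labels))
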