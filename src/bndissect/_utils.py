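"""Small shared helpers: seed derivation and column checks."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(master_seed: int, *tokens) -> int:
    """Derive a stable child seed from a master seed and a list of tokens.

    Tokens (stage names, replicate indices) are hashed with CRC32 so the same
    (master_seed, tokens) pair always yields the same child seed, independent
    of Python's per-process hash randomization.  The result fits in 31 bits.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(str(t).encode("utf8")) & 0x7FFFFFFF for t in tokens)
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_for(master_seed: int, *tokens) -> np.random.Generator:
    """A Generator seeded via :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *tokens))
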