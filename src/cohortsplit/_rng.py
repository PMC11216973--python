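"""Deterministic seed derivation.

All randomness in the package flows from a single user seed. Each stage
(embedding, each k-means replicate, each permutation replicate, ...) gets its
own derived seed so stages are independently reproducible and nested seed
sequences stay stable when replicate counts grow.
"""

from __future__ import annotations

import zlib

_MODULUS = 2**31 - 1  # keep derived seeds valid for every RNG API


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a child seed from ``seed`` and a stage path of tokens.

    Deterministic, order-sensitive, and stable across processes (crc32, not
    ``hash``). The result is in ``[0, 2**31 - 1)``.
    """
    label = ":".join(str(t) for t in tokens)
    return (int(seed) * 0x9E3779B1 + zlib.crc32(label.encode("utf-8"))) % _MODULUS
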