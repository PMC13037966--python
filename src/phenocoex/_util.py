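"""Small shared helpers."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, digits: int = 1) -> float:
    """Round with ties away from zero (the convention used for printed percentages).

    Python's built-in round() is banker's rounding, which would turn 57.05 into 57.0;
    reported shares instead follow the half-up convention.
    """
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def stable_seed(*parts: object) -> int:
    """Derive a reproducible sub-seed (< 2**31) from arbitrary labelled parts.

    Independent of Python's hash randomization and of platform word size, so
    per-pair permutation draws are identical across runs and machines.
    """
    key = "\x1f".join(str(p) for p in parts).encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)
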