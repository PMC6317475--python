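"""Small shared helpers: sequence ops, rounding, deterministic hashing."""

from __future__ import annotations

import hashlib
from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def percent_half_up(numerator: float, denominator: float, digits: int = 2) -> float:
    """Percentage rounded half-up (bankers' rounding would turn 20.565 into 20.56)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) / Decimal(denominator) * 100
    q = Decimal(1).scaleb(-digits)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def stable_hash(obj: object, length: int = 8) -> str:
    """Deterministic short hex digest of repr(obj); stable across processes."""
    return hashlib.md5(repr(obj).encode()).hexdigest()[:length]
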