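"""Small shared helpers: percentage rounding and chromosome collation."""

from __future__ import annotations

import re
from decimal import Decimal, ROUND_HALF_UP


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention used in report tables.

    Python's built-in round() is banker's rounding; table percentages are
    conventionally rounded half-up (93.65 -> 93.7).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up; 0.0 on empty denominator."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


_CHUNK = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural collation key for chromosome names: Chr2 sorts before Chr10.

    Names are split into digit and non-digit runs; digit runs compare
    numerically. This is the documented chromosome ordering used when sites
    are sorted after loading.
    """
    parts = _CHUNK.split(chrom)
    key = []
    for p in parts:
        if p == "":
            continue
        if p.isdigit():
            key.append((0, int(p), ""))
        else:
            key.append((1, 0, p))
    return tuple(key)
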