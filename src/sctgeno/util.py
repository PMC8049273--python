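"""Small shared helpers: sequence arithmetic and the rounding conventions
used in printed reports."""

from __future__ import annotations

import math

BASES = ("A", "C", "G", "T")

_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def revcomp(seq: str) -> str:
    """Reverse complement; N and '-' are self-complementary."""
    return seq.translate(_COMP)[::-1]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (105/152 -> 69.1-style table rounding).

    Python's built-in round() is banker's rounding, which disagrees with
    how clinical tables are conventionally printed.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def trunc_decimal(x: float, ndigits: int = 1) -> float:
    """Truncate toward zero at ndigits decimals."""
    factor = 10.0**ndigits
    return math.trunc(x * factor) / factor


def pct(numerator: int, denominator: int) -> float:
    """Plain percentage, no rounding. Returns nan for an empty denominator."""
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator
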