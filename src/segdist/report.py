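"""Report-layer formatting: printed-precision rounding and significance stars.

The estimation and testing engines always carry full precision; this
layer reproduces the printed-table conventions (half-up decimal
rounding, star annotations) for human-readable output.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "significance_stars", "format_p"]

#: Default star thresholds (p < threshold -> stars).
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def round_half_up(x: float, decimals: int) -> float:
    """Decimal half-up rounding (so 0.1064 -> 0.11 and 0.125 -> 0.13 at 2 dp)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def significance_stars(p: float, thresholds=STAR_THRESHOLDS) -> str:
    for cutoff, stars in sorted(thresholds):
        if p < cutoff:
            return stars
    return ""


def format_p(p: float, sigfigs: int = 2) -> str:
    """p-value at a printed precision (2 significant figures by default).

    Uses positional notation down to 1e-4 (so 0.00016679 prints as
    0.00017, matching table conventions) and scientific below that.
    """
    if p != 0 and p < 1e-4:
        return f"{p:.{sigfigs - 1}e}"
    return f"{p:.{sigfigs}g}"
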