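"""Small reporting arithmetic shared by tables and summaries."""

from __future__ import annotations

import math


def percent_ratio(
    numerator: float, denominator: float, decimals: int = 2, mode: str = "round"
) -> float:
    """100 * numerator / denominator, rounded or truncated to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    value = 100.0 * numerator / denominator
    factor = 10.0**decimals
    if mode == "round":
        return round(value * factor) / factor
    if mode == "truncate":
        return math.floor(value * factor) / factor
    raise ValueError(f"unknown mode {mode!r}; use 'round' or 'truncate'")


def region_length(start: int, end: int) -> int:
    """Length of a half-open interval (end - start), as printed in region tables."""
    if end <= start:
        raise ValueError("end must exceed start")
    return end - start
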