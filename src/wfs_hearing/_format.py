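"""Centralized rounding/formatting so tables and JSON cannot diverge.

Reported dB values carry one decimal; the SII is reported as an integer
percentage; p-values keep three significant figures.
"""

from __future__ import annotations

import math


def round_db(x: float) -> float:
    """dB values are reported to one decimal."""
    return round(float(x), 1)


def sii_percent(x: float) -> int:
    """SII proportions are reported as integer percent."""
    return int(round(100.0 * float(x)))


def round_stat(x: float, digits: int = 2) -> float:
    return round(float(x), digits)


def format_p(p: float) -> str:
    if math.isnan(p):
        return "NA"
    return f"{p:.3g}"
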