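"""Small shared helpers: published-table rounding and logging setup."""

from __future__ import annotations

import logging
import math

log = logging.getLogger("eamkit")


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round to `ndigits` decimals with ties going away from zero.

    Published agronomy tables round 0.0005 up to 0.001 (and -0.0005 down to
    -0.001); Python's built-in banker's rounding does not.
    """
    if not math.isfinite(x):
        return x
    factor = 10.0 ** ndigits
    scaled = x * factor
    # nudge by half an ulp-scale epsilon to defeat representation error on
    # exact decimal ties such as 0.0495
    eps = 1e-9
    if scaled >= 0:
        return math.floor(scaled + 0.5 + eps) / factor
    return math.ceil(scaled - 0.5 - eps) / factor
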