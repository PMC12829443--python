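"""Auditory-stimulus safety limit.

The maximal safe headphone volume for a brief aversive noise follows an
equal-energy trading rule relative to an 8-hour (28 800 s) occupational
exposure limit of 80 dB, with a 3 dB exchange rate per halving of duration:

    max dB = | 3 * log2(duration / 28800) | + 80
"""

from __future__ import annotations

import math

OCCUPATIONAL_LIMIT_DB = 80.0
REFERENCE_EXPOSURE_SECONDS = 28_800.0
EXCHANGE_RATE_DB = 3.0


def max_safe_noise_db(
    duration_seconds: float = 4.5,
    reference_seconds: float = REFERENCE_EXPOSURE_SECONDS,
    base_db: float = OCCUPATIONAL_LIMIT_DB,
    exchange_rate_db: float = EXCHANGE_RATE_DB,
) -> float:
    """Maximum safe noise level (dB) for a total exposure duration."""
    if duration_seconds <= 0 or reference_seconds <= 0:
        raise ValueError("durations must be positive")
    return abs(exchange_rate_db * math.log2(duration_seconds / reference_seconds)) + base_db
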