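"""Plaque-screening sample-size statistics.

If a fraction p of the phages in a plaque belong to the minority type, the
probability of seeing at least one among n screened plaques is 1 - (1-p)^n
(geometric detection). The design question inverts this: the smallest n whose
detection probability reaches a target confidence c is ceil(ln(1-c)/ln(1-p)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def detection_probability(p: float, n: int) -> float:
    """Probability of detecting >=1 minority-type phage among n plaques."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"minority fraction p={p} outside [0, 1]")
    if n < 0 or int(n) != n:
        raise ValueError(f"sample size n={n} must be a non-negative integer")
    return 1.0 - (1.0 - p) ** n


@dataclass(frozen=True)
class ScreeningDesign:
    """Solution of the screening sample-size equation 1 - (1-p)^n = c."""

    p: float
    confidence: float
    n_real: float  # exact real-valued root
    n_int: int  # smallest integer n achieving the confidence

    @property
    def achieved_probability(self) -> float:
        return detection_probability(self.p, self.n_int)


def required_sample_size(p: float, confidence: float) -> ScreeningDesign:
    """Smallest number of plaques to screen to detect the minority type.

    ``n_real`` is the exact root ln(1-c)/ln(1-p); ``n_int`` is the smallest
    integer whose detection probability reaches the confidence (verified
    directly, not just by rounding the root).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"minority fraction p={p} must be in (0, 1)")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence {confidence} must be in (0, 1)")
    n_real = math.log(1.0 - confidence) / math.log(1.0 - p)
    n_int = max(1, math.ceil(n_real))
    # guard against floating-point edge cases on exact boundaries
    while detection_probability(p, n_int) < confidence:
        n_int += 1
    while n_int > 1 and detection_probability(p, n_int - 1) >= confidence:
        n_int -= 1
    return ScreeningDesign(p=p, confidence=confidence, n_real=n_real, n_int=n_int)
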