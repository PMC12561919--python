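"""Classical equal-variance signal detection measures.

Sensitivity d' = z(Hit) - z(FA) and criterion c = -(z(Hit) + z(FA))/2,
with z the standard normal quantile function.  Positive c means a
conservative observer (reluctant to report "present").
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import norm

__all__ = ["SDTMeasures", "sdt_measures", "sdt_from_rates"]


@dataclasses.dataclass
class SDTMeasures:
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float


def sdt_from_rates(hit_rate: float, fa_rate: float) -> SDTMeasures:
    """d' and c from (already corrected) hit and false-alarm rates."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError("rates must lie strictly inside (0, 1)")
    zh, zf = norm.ppf(hit_rate), norm.ppf(fa_rate)
    return SDTMeasures(hit_rate, fa_rate, zh - zf, -0.5 * (zh + zf))


def sdt_measures(
    n_hit: int, n_miss: int, n_fa: int, n_cr: int, correction: str = "loglinear"
) -> SDTMeasures:
    """SDT measures from trial counts.

    When any empirical rate is exactly 0 or 1 the ``loglinear``
    correction adds 0.5 to every cell before computing rates (the
    quantile function is unbounded at the extremes).  ``correction=
    "none"`` raises on extreme rates instead.
    """
    counts = np.array([n_hit, n_miss, n_fa, n_cr], float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    n_sig, n_noise = n_hit + n_miss, n_fa + n_cr
    if n_sig == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    h = n_hit / n_sig
    f = n_fa / n_noise
    if h in (0.0, 1.0) or f in (0.0, 1.0):
        if correction == "loglinear":
            h = (n_hit + 0.5) / (n_sig + 1.0)
            f = (n_fa + 0.5) / (n_noise + 1.0)
        else:
            raise ValueError("extreme rate with correction disabled")
    return sdt_from_rates(h, f)
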