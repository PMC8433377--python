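"""Standard-addition quantification of one sample's metabolite concentration.

Combines the test rate, negative-control rate and the two positive-control
(spiked) rates into an in-matrix sensitivity estimate and a concentration
estimate ``[T] = r_t*/S``, with a full intermediate audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StandardAddition",
    "background_correct",
    "sensitivities",
    "quantify",
    "replicate_summary",
]


@dataclass
class StandardAddition:
    """One sample's standard-addition record.

    Rates in mV s⁻¹ (``r_n`` negative control, ``r_t`` test, ``r_a``/``r_b``
    positive controls), spike levels in µM. The derived fields hold the
    background-corrected test rate, the three sensitivity variants and
    their mean (mV s⁻¹ µM⁻¹), the clipped concentration estimate ``t_est``
    and the unclipped ``t_est_raw``.
    """

    r_n: float
    r_t: float
    r_a: float
    r_b: float
    conc_a: float
    conc_b: float
    r_t_star: float | None = None
    s1: float | None = None
    s2: float | None = None
    s3: float | None = None
    s_avg: float | None = None
    t_est: float | None = None
    t_est_raw: float | None = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.conc_b > self.conc_a > 0):
            raise ValueError("spike levels must satisfy conc_b > conc_a > 0")
        for name in ("r_n", "r_t", "r_a", "r_b"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def background_correct(r_t: float, r_n: float) -> float:
    """Adjusted test rate ``r_t* = r_t - r_n`` (may be negative)."""
    return r_t - r_n


def sensitivities(
    r_t: float, r_a: float, r_b: float, conc_a: float, conc_b: float
) -> tuple[float, float, float, float]:
    """Three in-matrix sensitivity estimates and their mean.

    ``s1 = (r_b - r_a)/(conc_b - conc_a)``, ``s2 = (r_b - r_t)/conc_b``,
    ``s3 = (r_a - r_t)/conc_a``. Because spikes are added on top of the
    same sample, the unknown endogenous concentration (and any shared
    background) cancels in each difference, so the negative-control rate
    never enters here.
    """
    if not (conc_b > conc_a > 0):
        raise ValueError("spike levels must satisfy conc_b > conc_a > 0")
    s1 = (r_b - r_a) / (conc_b - conc_a)
    s2 = (r_b - r_t) / conc_b
    s3 = (r_a - r_t) / conc_a
    return s1, s2, s3, (s1 + s2 + s3) / 3.0


def quantify(
    r_n: float,
    r_t: float,
    r_a: float,
    r_b: float,
    conc_a: float,
    conc_b: float,
) -> StandardAddition:
    """Complete a standard-addition record: ``t_est = r_t*/s_avg``.

    A non-positive sensitivity flags ``failed_standard_addition`` (the
    estimate is left unset); a negative corrected rate is reported as 0
    with a ``below_background`` flag, the raw value retained.
    """
    sa = StandardAddition(r_n=r_n, r_t=r_t, r_a=r_a, r_b=r_b, conc_a=conc_a, conc_b=conc_b)
    sa.r_t_star = background_correct(r_t, r_n)
    sa.s1, sa.s2, sa.s3, sa.s_avg = sensitivities(r_t, r_a, r_b, conc_a, conc_b)
    if min(sa.s1, sa.s2, sa.s3) <= 0:
        sa.flags.append("failed_standard_addition")
        return sa
    if sa.r_b <= sa.r_a:
        sa.flags.append("failed_standard_addition")
        return sa
    sa.t_est_raw = sa.r_t_star / sa.s_avg
    if sa.t_est_raw < 0:
        sa.flags.append("below_background")
        sa.t_est = 0.0
    else:
        sa.t_est = sa.t_est_raw
    return sa


def replicate_summary(
    replicates: Sequence[StandardAddition],
) -> tuple[float, float, int]:
    """Mean, sample SD and count over unflagged replicate estimates."""
    values = [
        sa.t_est
        for sa in replicates
        if sa.t_est is not None and not sa.flags
    ]
    if not values:
        raise ValueError("no unflagged replicates to summarize")
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sd, int(arr.size)
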