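"""Closed-form kinetic and photometric models shared by all pipeline stages.

Units follow the platform's conventions throughout the package:

* substrate / chromophore concentrations in µM,
* initial reaction rates in mV s⁻¹,
* raw photodiode voltages in V.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MMParams",
    "LinearCal",
    "DoubleExpParams",
    "PhotometricModel",
    "mm_rate",
    "mm_inverse",
    "beer_lambert_voltage",
    "double_exp_eval",
    "initial_slope",
]


@dataclass(frozen=True)
class MMParams:
    """Michaelis–Menten calibration parameters ``y = v_max*x/(k_m + x) + c``.

    Attributes
    ----------
    v_max : float
        Saturation rate in mV s⁻¹. Must be positive.
    k_m : float
        Half-saturation concentration in µM. Must be positive.
    c : float
        Rate offset in mV s⁻¹ (may be negative).
    """

    v_max: float
    k_m: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.v_max > 0:
            raise ValueError(f"v_max must be positive, got {self.v_max}")
        if not self.k_m > 0:
            raise ValueError(f"k_m must be positive, got {self.k_m}")
        if not math.isfinite(self.c):
            raise ValueError("c must be finite")


@dataclass(frozen=True)
class LinearCal:
    """Linear calibration ``Y = s*x + baseline`` with fit diagnostics.

    ``s`` is the sensitivity in mV s⁻¹ mM⁻¹; ``linear_range`` is the
    (low, high) concentration interval in µM over which the model holds.
    """

    s: float
    baseline: float
    linear_range: tuple[float, float] = (0.0, math.inf)
    r2: float = float("nan")
    rmse: float = float("nan")

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"sensitivity must be positive, got {self.s}")
        lo, hi = self.linear_range
        if not (lo >= 0 and lo < hi):
            raise ValueError(f"invalid linear range {self.linear_range}")


@dataclass(frozen=True)
class DoubleExpParams:
    """Parameters of ``y(t) = y0 + a1*(1 - exp(-k1*t)) + a2*(1 - exp(-k2*t))``.

    The form is the two-stage generalization of the integrated first-order
    limit of saturating kinetics; its analytic derivative at t=0,
    ``a1*k1 + a2*k2``, is the initial reaction rate.
    """

    y0: float
    a1: float
    k1: float
    a2: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("rate constants must be non-negative")
        if not math.isfinite(self.a1 * self.k1 + self.a2 * self.k2):
            raise ValueError("initial slope must be finite")


@dataclass(frozen=True)
class PhotometricModel:
    """Absorbance-to-voltage transfer of the photodiode readout.

    ``kappa`` bundles molar absorptivity and optical path length into an
    effective decadic absorbance per µM of chromophore. ``i_dark`` and
    ``i_illum`` are the dark and fully illuminated steady-state voltages.
    """

    kappa: float = 2.0e-4
    i_dark: float = 0.486
    i_illum: float = 1.730

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not self.i_illum > self.i_dark:
            raise ValueError("illuminated level must exceed dark level")

    @property
    def dynamic_range(self) -> float:
        return self.i_illum - self.i_dark

    def voltage_rate_per_chromophore_rate(self) -> float:
        """mV s⁻¹ of (falling) voltage per µM s⁻¹ of chromophore production.

        Small-absorbance derivative of :func:`beer_lambert_voltage`:
        ``|dV/dP| = (i_illum - i_dark) * ln(10) * kappa`` at P = 0,
        expressed in mV per µM.
        """
        return 1e3 * self.dynamic_range * math.log(10.0) * self.kappa


def mm_rate(x, p: MMParams):
    """Michaelis–Menten initial rate at substrate concentration ``x`` (µM).

    Returns ``p.v_max * x / (p.k_m + x) + p.c`` in mV s⁻¹. Accepts scalars
    or arrays; negative concentrations are rejected.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("substrate concentration must be non-negative")
    out = p.v_max * x / (p.k_m + x) + p.c
    return out.item() if out.ndim == 0 else out


def mm_inverse(y, p: MMParams, include_offset: bool = False):
    """Invert the Michaelis–Menten curve: rate (mV s⁻¹) → concentration (µM).

    With ``include_offset=False`` (default) the rate is interpreted as the
    saturating term only, i.e. ``x = k_m*y/(v_max - y)``; with
    ``include_offset=True`` the offset is removed first (``y' = y - c``).
    The default convention matches how rate-domain detection limits are
    converted to concentration units.
    """
    y = np.asarray(y, dtype=float)
    yp = y - p.c if include_offset else y
    if np.any(yp < 0):
        raise ValueError("rate below the invertible range")
    if np.any(yp >= p.v_max):
        raise ValueError("rate at or above the saturation asymptote")
    out = p.k_m * yp / (p.v_max - yp)
    return out.item() if out.ndim == 0 else out


def beer_lambert_voltage(chromophore_conc, pm: PhotometricModel):
    """Photodiode voltage for a given chromophore concentration (µM).

    ``V = i_dark + (i_illum - i_dark) * 10**(-kappa * conc)``: the voltage
    falls monotonically from ``i_illum`` (transparent) towards ``i_dark``
    (opaque) as the colored product accumulates.
    """
    conc = np.asarray(chromophore_conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("chromophore concentration must be non-negative")
    out = pm.i_dark + pm.dynamic_range * np.power(10.0, -pm.kappa * conc)
    return out.item() if out.ndim == 0 else out


def double_exp_eval(p: DoubleExpParams, t):
    """Evaluate the double-exponential progress model at time ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = (
        p.y0
        + p.a1 * (1.0 - np.exp(-p.k1 * t))
        + p.a2 * (1.0 - np.exp(-p.k2 * t))
    )
    return out.item() if out.ndim == 0 else out


def initial_slope(p: DoubleExpParams) -> float:
    """Analytic derivative of the double-exponential model at t = 0.

    ``a1*k1 + a2*k2``, in the units of the fitted signal per second.
    """
    return p.a1 * p.k1 + p.a2 * p.k2
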