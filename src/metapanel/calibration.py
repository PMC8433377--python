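"""Calibration fitting, linear-range determination and detection limits.

Fits Michaelis–Menten and linear models to (concentration, rate) tables,
finds the zero-anchored linear range by the R² > 0.9 prefix rule, and
computes IUPAC detection limits in rate and concentration units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .models import LinearCal, MMParams, mm_inverse

__all__ = [
    "FitDiagnostics",
    "NegativeControlStats",
    "DetectionLimits",
    "fit_mm",
    "fit_linear",
    "linear_range",
    "detection_limits",
]


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary: R², RMSE and per-parameter SDs."""

    r2: float
    rmse: float
    param_sds: tuple

    def __post_init__(self) -> None:
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


@dataclass(frozen=True)
class NegativeControlStats:
    """Blank initial-rate statistics in µV s⁻¹ (mean, SD, count)."""

    mu_c: float
    delta_c: float
    n: int = 24

    def __post_init__(self) -> None:
        if self.delta_c < 0:
            raise ValueError("delta_c must be non-negative")


@dataclass(frozen=True)
class DetectionLimits:
    """IUPAC limits in rate (mV s⁻¹) and concentration (µM) units."""

    lod_rate: float
    loq_rate: float
    lod_conc: float
    loq_conc: float

    def __post_init__(self) -> None:
        if self.lod_rate > self.loq_rate or self.lod_conc > self.loq_conc:
            raise ValueError("LOD cannot exceed LOQ")


def _r2_rmse(y, y_hat) -> tuple[float, float]:
    resid = y - y_hat
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return r2, float(np.sqrt(np.mean(resid**2)))


def _mm_f(x, v_max, k_m, c):
    return v_max * x / (k_m + x) + c


def fit_mm(x, y) -> tuple[MMParams, FitDiagnostics]:
    """Nonlinear least-squares Michaelis–Menten fit.

    ``x`` in µM, ``y`` in mV s⁻¹. Initialization uses v_max = max(y),
    k_m = median(x); bounds keep the asymptote from collapsing. A few
    perturbed restarts are attempted on non-convergence.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    xpos = x[x > 0]
    p0 = np.array(
        [max(float(np.max(y)), 1e-6), float(np.median(xpos)) if xpos.size else 1.0, 0.0]
    )
    bounds = ([1e-12, 1e-12, -np.inf], [100.0, 1e6, np.inf])
    rng = np.random.default_rng(0)
    last_err: Exception | None = None
    for trial in range(4):
        start = p0 if trial == 0 else np.abs(p0 * (1 + rng.normal(0, 0.5, 3)) + 1e-9)
        start = np.clip(start, bounds[0], bounds[1])
        if trial > 0:
            start[2] = rng.normal(0, 0.1)
        try:
            popt, pcov = curve_fit(
                _mm_f, x, y, p0=start, bounds=bounds, maxfev=20000
            )
            break
        except (RuntimeError, ValueError) as err:
            last_err = err
    else:
        raise RuntimeError(f"Michaelis–Menten fit did not converge: {last_err}")
    r2, rmse = _r2_rmse(y, _mm_f(x, *popt))
    sds = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, np.inf)))
    return MMParams(v_max=popt[0], k_m=popt[1], c=popt[2]), FitDiagnostics(
        r2=r2, rmse=rmse, param_sds=sds
    )


def fit_linear(x, y, linear_range_um: tuple[float, float] | None = None) -> LinearCal:
    """Ordinary least squares ``Y = S*x + C``.

    ``x`` in µM, ``y`` in mV s⁻¹; the reported sensitivity ``s`` is in
    mV s⁻¹ mM⁻¹ (slope per µM × 1000).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    r2, rmse = _r2_rmse(y, slope * x + intercept)
    rng_ = (
        linear_range_um
        if linear_range_um is not None
        else (float(np.min(x)), float(np.max(x)))
    )
    return LinearCal(
        s=slope * 1e3, baseline=float(intercept), linear_range=rng_, r2=r2, rmse=rmse
    )


def linear_range(x, y, r2_threshold: float = 0.9) -> tuple[float, float]:
    """Longest zero-anchored prefix on which a linear fit keeps R² > threshold.

    ``x`` must be sorted ascending and start at 0. Returns the (0, x_k)
    concentration interval; at least one 3-point prefix must qualify.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) < 0):
        raise ValueError("concentrations must be sorted ascending")
    best_k = None
    for k in range(3, x.size + 1):
        slope, intercept = np.polyfit(x[:k], y[:k], 1)
        r2, _ = _r2_rmse(y[:k], slope * x[:k] + intercept)
        if r2 > r2_threshold:
            best_k = k
    if best_k is None:
        raise ValueError("no prefix of >= 3 points satisfies the R² threshold")
    return (float(x[0]), float(x[best_k - 1]))


def detection_limits(
    nc: NegativeControlStats, p: MMParams, rate_decimals: int | None = 3
) -> DetectionLimits:
    """IUPAC LOD/LOQ from blank statistics, converted to µM.

    Rate-domain limits are ``mu_c + 3.3*delta_c`` and ``mu_c + 10*delta_c``
    (µV s⁻¹ → mV s⁻¹). Concentration limits invert the Michaelis–Menten
    curve with the offset excluded. ``rate_decimals`` quotes the
    rate-domain limits at the platform's reporting resolution (default
    1 µV s⁻¹, i.e. 3 decimals in mV s⁻¹) before inversion, matching how
    the published concentration limits were derived; pass ``None`` to
    invert the unrounded rates.
    """
    lod_rate = (nc.mu_c + 3.3 * nc.delta_c) * 1e-3
    loq_rate = (nc.mu_c + 10.0 * nc.delta_c) * 1e-3
    if lod_rate >= p.v_max:
        raise ValueError("rate-domain LOD at or above v_max: assay cannot quantify")
    lod_q = round(lod_rate, rate_decimals) if rate_decimals is not None else lod_rate
    loq_q = round(loq_rate, rate_decimals) if rate_decimals is not None else loq_rate
    return DetectionLimits(
        lod_rate=lod_rate,
        loq_rate=loq_rate,
        lod_conc=mm_inverse(lod_q, p, include_offset=False),
        loq_conc=mm_inverse(loq_q, p, include_offset=False),
    )
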