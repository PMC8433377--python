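"""Synthetic generators for everything the physical platform produces.

Three families of artifacts are generated, all seeded and reproducible:

* photodiode frame stacks for assay runs (liquid or dried-reagent mode),
  via saturating-kinetics progress curves pushed through the
  absorbance-to-voltage transfer plus drift, noise, dead sensors and ADC
  quantization;
* calibration tables of (concentration, rate) points with multiplicative
  replicate noise;
* clinical-style cohort tables of per-sample panel concentrations with a
  binary group label, drawn from zero-truncated normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import truncnorm

from . import presets
from .models import MMParams, PhotometricModel, beer_lambert_voltage, mm_rate

__all__ = [
    "SensorModel",
    "AssayKinetics",
    "GroupSpec",
    "FrameStack",
    "ProgressTrace",
    "simulate_progress",
    "simulate_frame_stack",
    "simulate_cohort",
    "make_calibration_series",
    "mm_kinetics",
    "linear_kinetics",
    "control_kinetics",
    "expected_initial_rate",
]


@dataclass(frozen=True)
class SensorModel:
    """Geometry, timing and imperfection model of the photodiode array."""

    n_rows: int = 16
    n_cols: int = 16
    frame_rate: float = presets.FRAME_RATE_HZ
    adc_bits: int = presets.ADC_BITS
    adc_fullscale: float = presets.ADC_FULLSCALE_V
    noise_sd: float = 1.0e-3
    drift_dark: float = presets.DRIFT_DARK_V_S
    drift_illum: float = presets.DRIFT_ILLUM_V_S
    dead_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not (0 <= self.dead_fraction < 1):
            raise ValueError("dead_fraction must be in [0, 1)")
        if self.adc_bits < 1:
            raise ValueError("adc_bits must be >= 1")

    @property
    def lsb(self) -> float:
        """ADC quantization step in volts."""
        return self.adc_fullscale / 2**self.adc_bits


@dataclass(frozen=True)
class AssayKinetics:
    """Effective product-formation kinetics of one assay channel.

    ``v_max_eff`` (µM s⁻¹) and ``k_m_eff`` (µM) govern substrate
    consumption; each consumed substrate molecule yields
    ``chromophore_yield`` chromophore molecules. Channels with
    ``metabolite == "control"`` carry no enzyme and instead produce a
    drift-like blank signal drawn from the control-rate statistics.
    ``rate_rel_sd`` models run-to-run chemistry variability as a
    multiplicative factor on the realized rate.
    """

    metabolite: str
    v_max_eff: float = 0.0
    k_m_eff: float = 1.0
    chromophore_yield: float = 0.5
    reagent_mode: str = "liquid"
    control_rate_mean: float | None = None
    control_rate_sd: float | None = None
    rate_rel_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.reagent_mode not in ("liquid", "dried"):
            raise ValueError(f"unknown reagent mode {self.reagent_mode!r}")
        if not self.k_m_eff > 0:
            raise ValueError("k_m_eff must be positive")
        if self.control_rate_sd is not None and self.control_rate_sd < 0:
            raise ValueError("control_rate_sd must be non-negative")

    @property
    def control_stats_uv_s(self) -> tuple[float, float]:
        """(mean, SD) of the blank rate in µV s⁻¹ for this reagent mode."""
        default = presets.NEGATIVE_CONTROL_UV_S[self.reagent_mode]
        mean = self.control_rate_mean if self.control_rate_mean is not None else default[0]
        sd = self.control_rate_sd if self.control_rate_sd is not None else default[1]
        return mean, sd


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: size and per-metabolite concentration mean/SD (µM)."""

    label: str
    n: int
    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for m, mu in self.mean.items():
            if mu <= 0:
                raise ValueError(f"mean for {m} must be positive")
            if self.sd[m] < 0:
                raise ValueError(f"sd for {m} must be non-negative")


@dataclass
class FrameStack:
    """Timestamped voltage frames from one acquisition plus metadata.

    ``frames`` has shape (n_frames, n_rows, n_cols) in volts; ``times``
    is strictly increasing in seconds. ``metadata`` carries acquisition
    settings, the seed and (for synthetic stacks) the per-channel ground
    truth initial rate used by end-to-end oracles.
    """

    times: np.ndarray
    frames: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("frames must be (n_frames, n_rows, n_cols)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_rate(self) -> float:
        return float(self.metadata.get("frame_rate", 1.0 / np.median(np.diff(self.times))))


@dataclass(frozen=True)
class ProgressTrace:
    """Reaction progress: substrate and chromophore concentrations vs time."""

    times: np.ndarray
    substrate: np.ndarray
    product: np.ndarray


def simulate_progress(
    kin: AssayKinetics, substrate0: float, duration: float, dt: float
) -> ProgressTrace:
    """Integrate substrate consumption and chromophore formation.

    ``dS/dt = -v(S)`` with ``v(S) = v_max_eff*S/(k_m_eff + S)`` and
    ``P = (substrate0 - S) * chromophore_yield``, so mass balance
    ``S + P/yield = substrate0`` holds exactly at every step.
    """
    if substrate0 < 0:
        raise ValueError("substrate0 must be non-negative")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    times = np.arange(0.0, duration + 0.5 * dt, dt)
    if substrate0 == 0 or kin.v_max_eff == 0:
        zeros = np.zeros_like(times)
        return ProgressTrace(times, np.full_like(times, substrate0), zeros)

    def rhs(_t, s):
        return [-kin.v_max_eff * s[0] / (kin.k_m_eff + s[0])]

    sol = solve_ivp(
        rhs,
        (0.0, times[-1]),
        [substrate0],
        t_eval=times,
        method="LSODA",
        rtol=1e-9,
        atol=1e-12 * max(substrate0, 1.0),
    )
    if not sol.success:  # pragma: no cover - LSODA is robust for this RHS
        raise RuntimeError(f"progress integration failed: {sol.message}")
    substrate = np.clip(sol.y[0], 0.0, substrate0)
    product = (substrate0 - substrate) * kin.chromophore_yield
    return ProgressTrace(times, substrate, product)


def mm_kinetics(
    metabolite: str,
    pm: PhotometricModel = presets.DEFAULT_PHOTOMETRIC,
    params: MMParams | None = None,
    chromophore_yield: float = 0.5,
    reagent_mode: str = "liquid",
    rate_rel_sd: float = 0.0,
) -> AssayKinetics:
    """Kinetics whose measured voltage rate follows a given saturating curve.

    The effective ``v_max_eff`` is chosen so that the initial voltage rate
    of a simulated run equals ``mm_rate(substrate0, params with c = 0)``
    in mV s⁻¹ (the offset is a fit artifact, not chemistry).
    """
    p = params if params is not None else presets.MM_PARAMS[metabolite]
    scale = pm.voltage_rate_per_chromophore_rate() * chromophore_yield
    return AssayKinetics(
        metabolite=metabolite,
        v_max_eff=p.v_max / scale,
        k_m_eff=p.k_m,
        chromophore_yield=chromophore_yield,
        reagent_mode=reagent_mode,
        rate_rel_sd=rate_rel_sd,
    )


def linear_kinetics(
    metabolite: str,
    pm: PhotometricModel = presets.DEFAULT_PHOTOMETRIC,
    sensitivity: float | None = None,
    k_m_eff: float = 1.0e6,
    chromophore_yield: float = 0.5,
    reagent_mode: str = "liquid",
    rate_rel_sd: float = 0.0,
) -> AssayKinetics:
    """Kinetics operating in the first-order (quasi-linear) regime.

    ``sensitivity`` is the target voltage-rate sensitivity in
    mV s⁻¹ mM⁻¹ (defaults to the platform's linear-model sensitivity for
    the metabolite and reagent mode); ``k_m_eff`` is set far above the
    working range so the initial rate is linear in substrate
    concentration, which is the regime the standard-addition estimator
    assumes.
    """
    if sensitivity is None:
        table = (
            presets.SENSITIVITY if reagent_mode == "liquid" else presets.SENSITIVITY_DRIED
        )
        sensitivity = table[metabolite]
    sens_per_um = sensitivity / 1000.0  # mV s⁻¹ per µM
    scale = pm.voltage_rate_per_chromophore_rate() * chromophore_yield
    return AssayKinetics(
        metabolite=metabolite,
        v_max_eff=sens_per_um * k_m_eff / scale,
        k_m_eff=k_m_eff,
        chromophore_yield=chromophore_yield,
        reagent_mode=reagent_mode,
        rate_rel_sd=rate_rel_sd,
    )


def control_kinetics(reagent_mode: str = "liquid") -> AssayKinetics:
    """Negative-control channel: no enzyme, blank drift-like signal only."""
    return AssayKinetics(metabolite="control", v_max_eff=0.0, reagent_mode=reagent_mode)


def expected_initial_rate(
    kin: AssayKinetics,
    substrate0: float,
    pm: PhotometricModel = presets.DEFAULT_PHOTOMETRIC,
) -> float:
    """Noise-free initial voltage rate (mV s⁻¹) for a kinetics/concentration.

    This is the generator-side oracle against which the signal-processing
    chain is validated; drift is not included.
    """
    v_sub = kin.v_max_eff * substrate0 / (kin.k_m_eff + substrate0)
    return pm.voltage_rate_per_chromophore_rate() * kin.chromophore_yield * v_sub


def simulate_frame_stack(
    sample_conc: Mapping[int, float] | Sequence[float],
    channel_map,
    kinetics: Mapping[int, AssayKinetics],
    sm: SensorModel = SensorModel(),
    pm: PhotometricModel = presets.DEFAULT_PHOTOMETRIC,
    seed: int = 0,
    duration: float = presets.FRAME_DURATION_S,
    illuminated: bool = True,
    cartridge_rel_sd: float = 0.0,
) -> FrameStack:
    """Simulate one acquisition of the photodiode array.

    Per live sensor the voltage is the channel's absorbance signal plus
    drift and Gaussian noise, then ADC-quantized. Dead sensors either sit
    at the 0 V rail or freeze at their first value. Negative-control
    channels produce a linear blank signal drawn from the control-rate
    statistics of their reagent mode. Wall sensors (no channel) sit near
    the dark level.

    ``sample_conc`` maps channel id → substrate concentration (µM); a
    sequence is interpreted as channels 1..len(seq).

    Run-to-run chemistry variability has two components: a cartridge-level
    multiplicative factor (``cartridge_rel_sd``) shared by all assay
    channels of the run, and the per-channel factor from each kinetics'
    ``rate_rel_sd``. Replicate SD of a measurement reflects both in
    quadrature; only the per-channel part perturbs standard addition.
    """
    if not isinstance(sample_conc, Mapping):
        sample_conc = {i + 1: c for i, c in enumerate(sample_conc)}
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * sm.frame_rate))
    times = np.arange(n_frames) / sm.frame_rate

    channels = sorted(channel_map.channels)
    for ch in channels:
        if ch not in kinetics:
            raise ValueError(f"channel {ch} has no kinetics definition")

    drift = sm.drift_illum if illuminated else sm.drift_dark
    baseline = pm.i_illum if illuminated else pm.i_dark

    cartridge_factor = 1.0
    if cartridge_rel_sd > 0:
        cartridge_factor = max(rng.normal(1.0, cartridge_rel_sd), 0.05)

    channel_traces: dict[int, np.ndarray] = {}
    truth: dict[int, float] = {}
    for ch in channels:
        kin = kinetics[ch]
        if kin.metabolite == "control":
            slope_uv = rng.normal(*kin.control_stats_uv_s)
            trace = baseline - slope_uv * 1e-6 * times
            truth[ch] = abs(slope_uv) * 1e-3  # mV s⁻¹
        else:
            conc = float(sample_conc.get(ch, 0.0))
            factor = cartridge_factor
            if kin.rate_rel_sd > 0:
                factor *= max(rng.normal(1.0, kin.rate_rel_sd), 0.05)
            eff = AssayKinetics(
                metabolite=kin.metabolite,
                v_max_eff=kin.v_max_eff * factor,
                k_m_eff=kin.k_m_eff,
                chromophore_yield=kin.chromophore_yield,
                reagent_mode=kin.reagent_mode,
            )
            if illuminated and conc > 0 and eff.v_max_eff > 0:
                prog = simulate_progress(eff, conc, duration, 1.0 / sm.frame_rate)
                product = prog.product[:n_frames]
                trace = beer_lambert_voltage(product, pm) - drift * times
                truth[ch] = expected_initial_rate(eff, conc, pm) + drift * 1e3
            else:
                trace = baseline - drift * times
                truth[ch] = drift * 1e3
        channel_traces[ch] = trace

    wall_trace = pm.i_dark - sm.drift_dark * times

    frames = np.empty((n_frames, sm.n_rows, sm.n_cols))
    frames[:] = wall_trace[:, None, None]
    for ch in channels:
        mask = channel_map.channel_grid == ch
        frames[:, mask] = channel_traces[ch][:, None]

    if sm.noise_sd > 0:
        frames += rng.normal(0.0, sm.noise_sd, frames.shape)

    dead = rng.random((sm.n_rows, sm.n_cols)) < sm.dead_fraction
    rail = rng.random((sm.n_rows, sm.n_cols)) < 0.5
    for r, c in zip(*np.nonzero(dead)):
        frames[:, r, c] = 0.0 if rail[r, c] else frames[0, r, c]

    lsb = sm.lsb
    frames = np.clip(np.round(frames / lsb) * lsb, 0.0, sm.adc_fullscale)

    metadata = {
        "seed": int(seed),
        "frame_rate": sm.frame_rate,
        "duration_s": float(duration),
        "illuminated": bool(illuminated),
        "adc_bits": sm.adc_bits,
        "adc_fullscale_V": sm.adc_fullscale,
        "temperature_C": float(np.round(rng.normal(26.5, 1.0), 2)),
        "humidity_pct": float(np.round(rng.normal(47.0, 8.0), 2)),
        "channel_truth_mV_s": {int(k): float(v) for k, v in truth.items()},
        "channel_metabolite": {int(ch): kinetics[ch].metabolite for ch in channels},
    }
    return FrameStack(times=times, frames=frames, metadata=metadata)


def _default_groups() -> list[GroupSpec]:
    return [
        GroupSpec(label=label, n=spec["n"], mean=spec["mean"], sd=spec["sd"])
        for label, spec in presets.COHORT_GROUPS.items()
    ]


def simulate_cohort(
    groups: Sequence[GroupSpec] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a cohort table of per-sample panel concentrations.

    Concentrations are independent zero-truncated normals per sample and
    metabolite. Returns a data frame with ``sample_id``, ``group`` and
    one µM column per metabolite.
    """
    if groups is None:
        groups = _default_groups()
    rng = np.random.default_rng(seed)
    rows = []
    sample_id = 1
    for g in groups:
        metabolites = list(g.mean)
        for _ in range(g.n):
            row = {"sample_id": sample_id, "group": g.label}
            for m in metabolites:
                mu, sd = g.mean[m], g.sd[m]
                if sd == 0:
                    row[m] = mu
                else:
                    a = (0.0 - mu) / sd  # truncate at zero
                    row[m] = float(truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))
            rows.append(row)
            sample_id += 1
    return pd.DataFrame(rows)


def make_calibration_series(
    metabolite: str,
    concentrations: Sequence[float] | None = None,
    replicates: int = 3,
    noise_rel: float | None = None,
    seed: int = 0,
    params: MMParams | None = None,
) -> pd.DataFrame:
    """Generate a calibration table of (concentration, rate) points.

    Rates are drawn as ``mm_rate(x) * (1 + eps)`` with
    ``eps ~ Normal(0, noise_rel)``; ``noise_rel`` defaults to the
    platform's average relative replicate SD for the metabolite.
    """
    p = params if params is not None else presets.MM_PARAMS[metabolite]
    if concentrations is None:
        hi = presets.TEST_RANGE_UM.get(metabolite, 1000.0)
        concentrations = np.linspace(0.0, hi, 6)
    x = np.asarray(concentrations, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    if noise_rel is None:
        noise_rel = presets.REL_SD.get(metabolite, 0.18)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        y = mm_rate(x, p)
        if noise_rel > 0:
            y = y * (1.0 + rng.normal(0.0, noise_rel, x.shape))
        for xi, yi in zip(x, y):
            rows.append(
                {
                    "metabolite": metabolite,
                    "concentration_uM": float(xi),
                    "rate_mV_per_s": float(yi),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)
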