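"""Default platform characterization constants.

These are the published characterization values of the four-assay panel
(calibration parameters, negative-control statistics, acquisition
geometry, spike levels and cohort group statistics) used as generator and
pipeline defaults. All of them can be overridden per call.
"""

from __future__ import annotations

from .models import MMParams, PhotometricModel

METABOLITES = ("LAA", "glutamate", "choline", "sarcosine")

#: Michaelis–Menten calibration parameters per assay (mV s⁻¹, µM).
MM_PARAMS: dict[str, MMParams] = {
    "LAA": MMParams(v_max=3.63, k_m=2866.0, c=-0.032),
    "glutamate": MMParams(v_max=5.28, k_m=529.7, c=-0.087),
    "choline": MMParams(v_max=11.34, k_m=1382.0, c=0.082),
    "sarcosine": MMParams(v_max=11.03, k_m=1209.0, c=0.027),
}

#: Linear-model sensitivity per assay, mV s⁻¹ mM⁻¹ (liquid reagents).
SENSITIVITY: dict[str, float] = {
    "LAA": 0.83,
    "glutamate": 6.06,
    "choline": 9.98,
    "sarcosine": 7.84,
}

#: Sensitivity with pre-dried reagents, mV s⁻¹ mM⁻¹ (no dried sarcosine assay).
SENSITIVITY_DRIED: dict[str, float] = {
    "LAA": 0.72,
    "glutamate": 6.14,
    "choline": 7.78,
}

#: Upper bound of the linear range per assay, µM (lower bound is 0).
LINEAR_RANGE_UM: dict[str, float] = {
    "LAA": 1500.0,
    "glutamate": 320.0,
    "choline": 120.0,
    "sarcosine": 120.0,
}

#: Calibration test range upper bound per assay, µM.
TEST_RANGE_UM: dict[str, float] = {
    "LAA": 5400.0,
    "glutamate": 1500.0,
    "choline": 600.0,
    "sarcosine": 600.0,
}

#: Average relative replicate SD inside the linear range, per assay.
REL_SD: dict[str, float] = {
    "LAA": 0.183,
    "glutamate": 0.172,
    "choline": 0.164,
    "sarcosine": 0.192,
}

#: Negative-control initial-rate statistics (mean, SD) in µV s⁻¹.
NEGATIVE_CONTROL_UV_S = {"liquid": (5.0, 2.7), "dried": (23.0, 12.5)}

#: Standard-addition spike A level per assay, µM; spike B is 2×A.
SPIKE_A_UM: dict[str, float] = {
    "LAA": 500.0,
    "glutamate": 100.0,
    "choline": 100.0,
    "sarcosine": 100.0,
}

#: Acquisition defaults.
FRAME_RATE_HZ = 36.5
FRAME_DURATION_S = 300.0
ADC_BITS = 12
ADC_FULLSCALE_V = 3.3
ARRAY_SHAPE = (16, 16)
DRIFT_DARK_V_S = 1.4e-6
DRIFT_ILLUM_V_S = 0.9e-6
STEADY_STATE_DARK_V = 0.486
STEADY_STATE_ILLUM_V = 1.730

DEFAULT_PHOTOMETRIC = PhotometricModel(
    kappa=2.0e-4, i_dark=STEADY_STATE_DARK_V, i_illum=STEADY_STATE_ILLUM_V
)

#: Cohort group statistics: per-group sample size and per-metabolite
#: mean/SD of plasma concentration in µM.
COHORT_GROUPS = {
    "non-PCa": {
        "n": 10,
        "mean": {"LAA": 1984.0, "glutamate": 40.2, "choline": 10.0, "sarcosine": 11.5},
        "sd": {"LAA": 527.0, "glutamate": 11.2, "choline": 4.1, "sarcosine": 4.3},
    },
    "PCa": {
        "n": 16,
        "mean": {"LAA": 2694.0, "glutamate": 62.2, "choline": 13.4, "sarcosine": 10.0},
        "sd": {"LAA": 1052.0, "glutamate": 29.5, "choline": 7.9, "sarcosine": 6.9},
    },
}

#: Reference blood-test operating characteristics used for ROC comparison.
PSA_REFERENCE = {"sensitivity": 0.32, "specificity": 0.87, "auc": 0.68}

#: Default classifier feature panel (sarcosine showed no group signal).
CLASSIFIER_FEATURES = ("LAA", "glutamate", "choline")
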