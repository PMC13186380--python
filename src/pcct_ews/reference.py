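"""Age-referenced physiological baselines.

One source of truth shared by the cohort simulator (channel baselines) and the
standardiser (z-score means/SDs), so that z-scoring a quiet simulated episode
is centred near zero by construction. Values are a piecewise-linear grid over
age {0, 0.08, 1, 4, 11, 18} years, chosen to follow the usual paediatric
trajectory (neonatal tachycardia/tachypnoea relaxing towards adult values,
blood pressure rising with age). They are package reference values, not
clinical centiles.
"""

from __future__ import annotations

import numpy as np

#: Age grid in years (0.08 y ~ 1 month).
AGE_GRID = np.array([0.0, 0.08, 1.0, 4.0, 11.0, 18.0])

# mean and SD per z-scored channel family on the age grid
_REFERENCE = {
    "hr": {
        "mean": np.array([145.0, 140.0, 120.0, 100.0, 85.0, 75.0]),
        "sd": np.array([20.0, 20.0, 18.0, 15.0, 13.0, 12.0]),
    },
    "rr": {
        "mean": np.array([45.0, 40.0, 28.0, 22.0, 18.0, 14.0]),
        "sd": np.array([9.0, 8.0, 7.0, 5.0, 4.0, 3.5]),
    },
    "bp_sys": {
        "mean": np.array([70.0, 80.0, 90.0, 97.0, 105.0, 115.0]),
        "sd": np.array([9.0, 10.0, 10.0, 11.0, 11.0, 12.0]),
    },
    "bp_mean": {
        "mean": np.array([50.0, 57.0, 65.0, 72.0, 78.0, 85.0]),
        "sd": np.array([8.0, 8.0, 9.0, 9.0, 10.0, 10.0]),
    },
    "bp_dia": {
        "mean": np.array([38.0, 45.0, 52.0, 57.0, 62.0, 68.0]),
        "sd": np.array([7.0, 7.0, 8.0, 8.0, 9.0, 9.0]),
    },
}

#: Which reference row a z-scored channel uses.
CHANNEL_REFERENCE_KEY = {
    "hr": "hr",
    "rr_airway": "rr",
    "rr_impedance": "rr",
    "nibp_sys": "bp_sys",
    "nibp_mean": "bp_mean",
    "nibp_dia": "bp_dia",
    "ibp_sys": "bp_sys",
    "ibp_mean": "bp_mean",
    "ibp_dia": "bp_dia",
}

#: Fixed centres for affine-standardised channels: (centre, scale).
AFFINE_RULES = {
    "spo2": (97.0, 6.0),
    "etco2_min": (5.25, 1.5),
    "etco2_max": (5.25, 1.5),
    "temp_oesophageal": (36.75, 1.5),
    "temp_skin": (36.75, 1.5),
    "temp_core": (36.75, 1.5),
    "temp_unspecified": (36.75, 1.5),
}


def age_reference(channel: str, age_years: float) -> tuple[float, float]:
    """(mean, SD) for a z-scored channel at an age, linearly interpolated.

    Ages outside the grid are clamped to the nearest grid point.
    """
    key = CHANNEL_REFERENCE_KEY[channel]
    a = float(np.clip(age_years, AGE_GRID[0], AGE_GRID[-1]))
    ref = _REFERENCE[key]
    return (
        float(np.interp(a, AGE_GRID, ref["mean"])),
        float(np.interp(a, AGE_GRID, ref["sd"])),
    )


def channel_baseline(channel: str, age_years: float) -> tuple[float, float]:
    """Simulator baseline (level, SD) for any channel at an age.

    Z-scored channels use :func:`age_reference`; affine channels use their
    fixed centre with a nominal within-patient SD.
    """
    if channel in CHANNEL_REFERENCE_KEY:
        return age_reference(channel, age_years)
    centre, scale = AFFINE_RULES[channel]
    if channel == "spo2":
        return 97.5, 1.2  # healthy saturations sit in a narrow high band
    if channel.startswith("etco2"):
        return centre, 0.5
    return centre, 0.4  # temperature
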