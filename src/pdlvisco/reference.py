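"""Published reference values for human premolar PDL.

These are the printed per-slice collagen fractions, creep-model parameter
columns, and reduced-modulus values from the cadaveric nano-indentation /
Masson-staining study this package models.  They serve as fixture inputs
(e.g. generating truths for round-trip fits and averaging checks); the raw
specimens were never deposited, so they cannot be recomputed from data.
"""

from __future__ import annotations

from .constitutive import SchaperyParameters

# Collagen fiber volume fraction Vf (%) measured on five Masson-stained
# slices per root region.
COLLAGEN_VF_SLICES: dict[str, list[float]] = {
    "apex": [62.198, 59.01, 41.2, 51.417, 46.116],
    "middle": [58.249, 65.771, 65.65, 61.369, 64.669],
    "neck": [60.007, 51.991, 53.889, 67.895, 67.78],
}

# Published per-region Vf averages (%) — arithmetic means of the above.
COLLAGEN_VF_MEAN: dict[str, float] = {
    "apex": 51.9882,
    "middle": 63.1416,
    "neck": 60.3124,
}

# Fitted creep-model parameter columns (g0, g2 dimensionless; eta MPa*s in
# the unit-normalized context Etf = Em = sigma0 = 1, g1 = 1) with the
# reported coefficient of determination of each fit.
CREEP_PARAMETERS: dict[str, dict[str, float]] = {
    "neck-1": {"g0": 0.0049, "g2": -0.0096, "eta": 260.8893, "r_squared": 0.995},
    "neck-2": {"g0": 0.0057, "g2": -0.0118, "eta": 289.5958, "r_squared": 0.997},
    "middle-1": {"g0": 0.0030, "g2": -0.0060, "eta": 264.3402, "r_squared": 0.9985},
    "middle-2": {"g0": 0.0034, "g2": -0.0082, "eta": 254.2570, "r_squared": 0.995},
    "apex-1": {"g0": 0.0081, "g2": -0.0124, "eta": 370.6347, "r_squared": 0.996},
    "apex-2": {"g0": 0.0098, "g2": -0.0242, "eta": 191.9794, "r_squared": 0.993},
}

# Reduced elastic modulus E* (MPa) per region and sampling plane.
REDUCED_MODULUS_MPA: dict[str, dict[str, float]] = {
    "neck": {"transverse": 4.28, "longitudinal": 2.98},
    "middle": {"transverse": 5.08, "longitudinal": 4.79},
    "apex": {"transverse": 1.03, "longitudinal": 0.39},
}

# Indentation protocol of the study.
LOADING_RATE_MN_S = 0.5
PEAK_LOAD_MN = 3.0
HOLD_TIME_S = 200.0
INDENTER_RADIUS_UM = 100.0
POINTS_PER_REGION = 5
SLICES_PER_REGION = 5


def schapery_for(sample: str) -> SchaperyParameters:
    """SchaperyParameters for a named reference sample (g1 = 1 convention)."""
    p = CREEP_PARAMETERS[sample]
    return SchaperyParameters(g0=p["g0"], g1=1.0, g2=p["g2"])
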