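"""Published clinical anchor values used as package-wide defaults.

Normalization bounds default to the study cohort's printed per-variable
minima/maxima so that normalized thresholds are reproducible regardless of
the sample actually loaded; the risk-band edges are the printed normalized
values (stored as constants, not re-derived, because the printed K+ upper
edge 0.60 and the NT-proBNP band do not follow exactly from the raw
reference limits under min-max scaling).
"""

from __future__ import annotations

#: Canonical model variable names, in model input order.
INPUT_VARIABLES: tuple[str, ...] = ("ntprobnp", "na", "k")
OUTPUT_VARIABLES: tuple[str, ...] = ("ef", "epi_cysc")
MODEL_VARIABLES: tuple[str, ...] = INPUT_VARIABLES + OUTPUT_VARIABLES

#: Cohort min/max per variable (physical units); default normalization bounds.
FROZEN_BOUNDS: dict[str, tuple[float, float]] = {
    "ntprobnp": (10.0, 5000.0),   # pg/mL
    "na": (123.0, 150.0),         # mmol/L
    "k": (2.4, 7.8),              # mmol/L
    "ef": (12.0, 75.0),           # %
    "epi_cysc": (14.0, 146.0),    # mL/min/1.73 m^2
}

#: Laboratory reference ranges (physical units).
REFERENCE_RANGES: dict[str, tuple[float, float]] = {
    "na": (135.0, 150.0),
    "k": (3.5, 5.5),
}

#: NT-proBNP cutoffs (pg/mL) used at low vs. preserved GFR.
NTPROBNP_CUTOFF_LOW_GFR = 300.0
NTPROBNP_CUTOFF_NORMAL_GFR = 100.0

#: Normal-GFR lower limit (mL/min/1.73 m^2).
GFR_NORMAL_LIMIT = 90.0

#: Echocardiographic EF cutoffs (%): reduced below 40, normal at/above 50.
EF_REDUCED_PCT = 40.0
EF_NORMAL_PCT = 50.0

#: Normalized stability-band edges per input (configurable; printed values).
DEFAULT_BAND_EDGES: dict[str, tuple[float, float]] = {
    "ntprobnp": (0.30, 0.60),
    "na": (0.44, 1.00),
    "k": (0.20, 0.60),
}

#: Normalized output thresholds for risk classification.
EF_THRESHOLD_NORM = 0.50
EPI_THRESHOLD_NORM = 0.58

#: Cohort composition.
COHORT_N = 90
COHORT_MALES = 52

#: Target sample moments (mean, sd) per generated variable, physical units.
#: Bounds for generation are FROZEN_BOUNDS (age: 18-88 years).
VARIABLE_TARGETS: dict[str, tuple[float, float]] = {
    "na": (138.0, 4.12),
    "k": (4.85, 0.88),
    "ntprobnp": (1275.77, 1533.89),
    "age": (65.98, 15.74),
}

AGE_BOUNDS: tuple[float, float] = (18.0, 88.0)
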