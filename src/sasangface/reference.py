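"""Published summary statistics of the Korean Sasang facial-metric cohort.

These constants transcribe the study's printed group summaries and serve as
the default calibration targets of the synthetic generator and as the fixed
coefficients of the published predictive equations.  They are reference
values, not measurements made by this package.

Strata are coded ``M20s``, ``F20s``, ``M60s``, ``F60s`` (sex × age decade);
Sasang constitutional types are ``TE`` (TaeEum), ``SE`` (SoEum) and ``SY``
(SoYang).  Metric keys match :data:`sasangface.metrics.METRIC_NAMES`.
"""

from __future__ import annotations

__all__ = [
    "STRATA",
    "TYPES",
    "GROUP_SUMMARIES",
    "POOLED_BMI_CORRELATIONS",
    "POOLED_STRATUM_N",
    "SIGNIFICANT_CORRELATIONS",
    "EXTERNAL_CORRELATIONS",
    "PRINTED_EQUATIONS",
    "COMPARISON_UNITS",
    "stratum_groups",
]

STRATA = ("M20s", "F20s", "M60s", "F60s")
TYPES = ("TE", "SE", "SY")

# Per-group (stratum, type) sample size and mean/SD of BMI, height (m),
# and the seven facial metrics.  Each entry: {"n", "mean": {...}, "sd": {...}}.
GROUP_SUMMARIES: dict[tuple[str, str], dict] = {
    ("M20s", "TE"): {
        "n": 96,
        "mean": {"bmi": 25.1, "height_m": 1.754, "PAR": 0.045, "WHR": 2.16,
                 "CJWR": 1.13, "eye_size": 32.60, "LF_FH": 0.63,
                 "FW_LFH": 1.21, "EH_mean": 16.58},
        "sd": {"bmi": 3.4, "height_m": 0.052, "PAR": 0.002, "WHR": 0.14,
               "CJWR": 0.05, "eye_size": 1.79, "LF_FH": 0.03,
               "FW_LFH": 0.06, "EH_mean": 2.11},
    },
    ("M20s", "SE"): {
        "n": 57,
        "mean": {"bmi": 20.7, "height_m": 1.739, "PAR": 0.046, "WHR": 2.08,
                 "CJWR": 1.17, "eye_size": 31.66, "LF_FH": 0.62,
                 "FW_LFH": 1.19, "EH_mean": 16.22},
        "sd": {"bmi": 2.1, "height_m": 0.053, "PAR": 0.002, "WHR": 0.13,
               "CJWR": 0.05, "eye_size": 1.80, "LF_FH": 0.03,
               "FW_LFH": 0.07, "EH_mean": 1.86},
    },
    ("M20s", "SY"): {
        "n": 77,
        "mean": {"bmi": 22.3, "height_m": 1.746, "PAR": 0.046, "WHR": 2.11,
                 "CJWR": 1.16, "eye_size": 32.19, "LF_FH": 0.62,
                 "FW_LFH": 1.19, "EH_mean": 16.63},
        "sd": {"bmi": 2.0, "height_m": 0.052, "PAR": 0.0018, "WHR": 0.14,
               "CJWR": 0.05, "eye_size": 1.72, "LF_FH": 0.02,
               "FW_LFH": 0.06, "EH_mean": 1.68},
    },
    ("F20s", "TE"): {
        "n": 93,
        "mean": {"bmi": 19.35, "height_m": 1.616, "PAR": 0.047, "WHR": 2.18,
                 "CJWR": 1.16, "eye_size": 31.72, "LF_FH": 0.61,
                 "FW_LFH": 1.23, "EH_mean": 17.92},
        "sd": {"bmi": 2.28, "height_m": 0.049, "PAR": 0.002, "WHR": 0.13,
               "CJWR": 0.04, "eye_size": 1.73, "LF_FH": 0.02,
               "FW_LFH": 0.05, "EH_mean": 1.85},
    },
    ("F20s", "SE"): {
        "n": 54,
        "mean": {"bmi": 16.63, "height_m": 1.602, "PAR": 0.048, "WHR": 2.14,
                 "CJWR": 1.19, "eye_size": 31.16, "LF_FH": 0.60,
                 "FW_LFH": 1.23, "EH_mean": 17.82},
        "sd": {"bmi": 2.18, "height_m": 0.051, "PAR": 0.002, "WHR": 0.13,
               "CJWR": 0.05, "eye_size": 1.77, "LF_FH": 0.02,
               "FW_LFH": 0.05, "EH_mean": 1.97},
    },
    ("F20s", "SY"): {
        "n": 82,
        "mean": {"bmi": 17.38, "height_m": 1.622, "PAR": 0.048, "WHR": 2.15,
                 "CJWR": 1.18, "eye_size": 31.52, "LF_FH": 0.60,
                 "FW_LFH": 1.25, "EH_mean": 18.04},
        "sd": {"bmi": 1.94, "height_m": 0.052, "PAR": 0.002, "WHR": 0.13,
               "CJWR": 0.05, "eye_size": 1.60, "LF_FH": 0.02,
               "FW_LFH": 0.05, "EH_mean": 2.06},
    },
    ("M60s", "TE"): {
        "n": 87,
        "mean": {"bmi": 24.18, "height_m": 1.668, "PAR": 0.045, "WHR": 2.08,
                 "CJWR": 1.06, "eye_size": 29.62, "LF_FH": 0.62,
                 "FW_LFH": 1.21, "EH_mean": 18.29},
        "sd": {"bmi": 2.74, "height_m": 0.059, "PAR": 0.002, "WHR": 0.14,
               "CJWR": 0.04, "eye_size": 1.96, "LF_FH": 0.02,
               "FW_LFH": 0.06, "EH_mean": 2.57},
    },
    ("M60s", "SE"): {
        "n": 51,
        "mean": {"bmi": 19.99, "height_m": 1.664, "PAR": 0.045, "WHR": 1.99,
                 "CJWR": 1.11, "eye_size": 28.70, "LF_FH": 0.61,
                 "FW_LFH": 1.19, "EH_mean": 17.72},
        "sd": {"bmi": 2.66, "height_m": 0.055, "PAR": 0.002, "WHR": 0.13,
               "CJWR": 0.05, "eye_size": 2.34, "LF_FH": 0.02,
               "FW_LFH": 0.06, "EH_mean": 3.12},
    },
    ("M60s", "SY"): {
        "n": 80,
        "mean": {"bmi": 21.88, "height_m": 1.655, "PAR": 0.045, "WHR": 2.02,
                 "CJWR": 1.09, "eye_size": 29.06, "LF_FH": 0.62,
                 "FW_LFH": 1.20, "EH_mean": 18.28},
        "sd": {"bmi": 2.60, "height_m": 0.052, "PAR": 0.002, "WHR": 0.11,
               "CJWR": 0.04, "eye_size": 2.03, "LF_FH": 0.02,
               "FW_LFH": 0.05, "EH_mean": 2.98},
    },
    ("F60s", "TE"): {
        "n": 90,
        "mean": {"bmi": 21.03, "height_m": 1.546, "PAR": 0.047, "WHR": 2.13,
                 "CJWR": 1.07, "eye_size": 28.99, "LF_FH": 0.63,
                 "FW_LFH": 1.21, "EH_mean": 20.28},
        "sd": {"bmi": 1.97, "height_m": 0.048, "PAR": 0.002, "WHR": 0.15,
               "CJWR": 0.04, "eye_size": 1.86, "LF_FH": 0.02,
               "FW_LFH": 0.06, "EH_mean": 3.18},
    },
    ("F60s", "SE"): {
        "n": 60,
        "mean": {"bmi": 17.54, "height_m": 1.533, "PAR": 0.048, "WHR": 2.12,
                 "CJWR": 1.10, "eye_size": 28.22, "LF_FH": 0.62,
                 "FW_LFH": 1.22, "EH_mean": 19.90},
        "sd": {"bmi": 2.03, "height_m": 0.047, "PAR": 0.003, "WHR": 0.13,
               "CJWR": 0.04, "eye_size": 2.40, "LF_FH": 0.02,
               "FW_LFH": 0.05, "EH_mean": 2.87},
    },
    ("F60s", "SY"): {
        "n": 84,
        "mean": {"bmi": 19.13, "height_m": 1.534, "PAR": 0.047, "WHR": 2.12,
                 "CJWR": 1.09, "eye_size": 28.90, "LF_FH": 0.62,
                 "FW_LFH": 1.21, "EH_mean": 19.47},
        "sd": {"bmi": 2.08, "height_m": 0.044, "PAR": 0.003, "WHR": 0.16,
               "CJWR": 0.04, "eye_size": 1.94, "LF_FH": 0.02,
               "FW_LFH": 0.06, "EH_mean": 2.76},
    },
}

# Pooled Pearson correlation of each metric with BMI per stratum, as printed.
POOLED_BMI_CORRELATIONS: dict[str, dict[str, float]] = {
    "M20s": {"PAR": -0.30, "WHR": 0.30, "CJWR": -0.40, "eye_size": 0.29,
             "LF_FH": 0.12, "FW_LFH": 0.12, "EH_mean": 0.05},
    "F20s": {"PAR": -0.23, "WHR": 0.28, "CJWR": -0.29, "eye_size": 0.26,
             "LF_FH": 0.10, "FW_LFH": 0.05, "EH_mean": 0.16},
    "M60s": {"PAR": -0.18, "WHR": 0.28, "CJWR": -0.40, "eye_size": 0.27,
             "LF_FH": 0.07, "FW_LFH": 0.16, "EH_mean": 0.11},
    "F60s": {"PAR": -0.28, "WHR": 0.06, "CJWR": -0.27, "eye_size": 0.21,
             "LF_FH": 0.29, "FW_LFH": 0.052, "EH_mean": 0.12},
}

# Pooled stratum sample sizes as printed in the correlation table.  Note the
# male-sixties figure (219) exceeds the sum of the printed group sizes (218);
# the printed value is kept here because it belongs to the published (r, n)
# pairs used in Fisher comparisons.
POOLED_STRATUM_N: dict[str, int] = {"M20s": 230, "F20s": 229, "M60s": 219, "F60s": 234}

# Metrics whose pooled correlation is starred significant (P < .05) per stratum.
SIGNIFICANT_CORRELATIONS: dict[str, tuple[str, ...]] = {
    "M20s": ("PAR", "WHR", "CJWR", "eye_size"),
    "F20s": ("PAR", "WHR", "CJWR", "eye_size", "EH_mean"),
    "M60s": ("PAR", "WHR", "CJWR", "eye_size", "FW_LFH"),
    "F60s": ("PAR", "CJWR", "eye_size", "LF_FH"),
}

# Published external comparison cohort (young Caucasian/African sample):
# (r, n) per sex for the three shared metrics.
EXTERNAL_CORRELATIONS: dict[str, dict[str, tuple[float, int]]] = {
    "M": {"PAR": (-0.22, 187), "WHR": (0.17, 187), "CJWR": (-0.20, 187)},
    "F": {"PAR": (-0.12, 194), "WHR": (0.36, 194), "CJWR": (-0.29, 194)},
}

# Published predictive equations for the probability of the TE type:
# probability = 1 / (1 + exp(x)), x = b0 + b_bmi·BMI + b_cjwr·CJWR.
PRINTED_EQUATIONS: dict[str, tuple[float, float, float]] = {
    "M20s": (0.236, -0.454, 9.237),
    "M60s": (-8.572, -0.373, 16.254),
    "F20s": (0.556, -0.4617, 6.9579),
    "F60s": (-1.77824, -0.54430, 11.99360),
}

# Odds-ratio comparison units (chosen close to each predictor's SD).
COMPARISON_UNITS: dict[str, float] = {
    "bmi": 1.0, "PAR": 0.002, "WHR": 0.14, "CJWR": 0.05,
    "eye_size": 1.0, "LF_FH": 0.02, "FW_LFH": 0.06, "EH_mean": 1.0,
}


def stratum_groups(stratum: str) -> dict[str, dict]:
    """The three per-type group summaries of one stratum, keyed by type."""
    if stratum not in STRATA:
        raise KeyError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    return {t: GROUP_SUMMARIES[(stratum, t)] for t in TYPES}
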