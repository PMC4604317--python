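"""Published per-cohort summary statistics for the serum-urate index variant.

These are the printed per-cohort regression estimates (beta, SE) for the
urate-raising allele of the SLC2A9 index variant rs6449173 in the five
European study samples, plus the published genotype × group cell contrasts
for mean urate. They are inputs to the meta-analysis layer: pooling them
reproduces the published combined rows without individual-level data.

Betas are in mmol/L per effect allele for the mean effect and in z² units
per effect allele for the variance effects.
"""

from __future__ import annotations

from typing import Mapping

COHORTS = ("ARIC", "FHS", "ARIC_diuretics", "CHS", "CARDIA")

#: Additive mean effect of the effect allele on serum urate, per cohort.
MEAN_EFFECT: Mapping[str, tuple[float, float]] = {
    "ARIC": (0.023, 0.002),
    "FHS": (0.023, 0.002),
    "ARIC_diuretics": (0.031, 0.004),
    "CHS": (0.023, 0.003),
    "CARDIA": (0.026, 0.003),
}

#: Variance effect (z² per allele) before adjusting for the mean effect.
UNADJUSTED_VARIANCE_EFFECT: Mapping[str, tuple[float, float]] = {
    "ARIC": (-0.153, 0.033),
    "FHS": (-0.192, 0.042),
    "ARIC_diuretics": (-0.117, 0.073),
    "CHS": (-0.156, 0.045),
    "CARDIA": (-0.079, 0.062),
}

#: Variance effect after genotype-mean adjustment.
ADJUSTED_VARIANCE_EFFECT: Mapping[str, tuple[float, float]] = {
    "ARIC": (0.024, 0.033),
    "FHS": (0.063, 0.043),
    "ARIC_diuretics": (0.043, 0.073),
    "CHS": (-0.016, 0.045),
    "CARDIA": (0.208, 0.061),
}

#: Mean-adjusted variance effect by analysis group (cohorts with no usable
#: group, e.g. no pre-menopausal women, are simply absent).
STRATA_VARIANCE_EFFECT: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "men": {
        "ARIC": (-0.053, 0.050),
        "FHS": (-0.008, 0.063),
        "ARIC_diuretics": (-0.088, 0.126),
        "CHS": (-0.121, 0.073),
        "CARDIA": (0.112, 0.092),
    },
    "pre": {
        "ARIC": (0.188, 0.105),
        "FHS": (0.165, 0.062),
        "ARIC_diuretics": (0.430, 0.271),
        "CARDIA": (0.231, 0.100),
    },
    "post": {
        "ARIC": (0.083, 0.063),
        "FHS": (-0.015, 0.187),
        "ARIC_diuretics": (0.102, 0.128),
        "CHS": (0.093, 0.062),
        "CARDIA": (0.269, 0.369),
    },
}

#: Published combined (pooled) rows, for reference alongside recomputation.
COMBINED = {
    "mean": (0.024, 0.00095),
    "var_unadjusted": (-0.152, 0.020),
    "var_adjusted": (0.047, 0.020),
    "men": (-0.038, 0.031),
    "pre": (0.191, 0.046),
    "post": (0.087, 0.040),
}

#: Published genotype × group cell betas for mean urate (mmol/L) relative to
#: men with zero copies of the effect allele; genotype class = copies of the
#: effect allele (0 = GG, 1 = GT, 2 = TT).
GENOTYPE_GROUP_CELLS: Mapping[tuple[str, int], float] = {
    ("men", 0): 0.000,
    ("men", 1): 0.021,
    ("men", 2): 0.038,
    ("post", 0): -0.088,
    ("post", 1): -0.047,
    ("post", 2): -0.023,
    ("pre", 0): -0.135,
    ("pre", 1): -0.090,
    ("pre", 2): -0.060,
}

#: Published allele × group interaction betas on mean urate (mmol/L).
INTERACTION_MEAN = {"pre": 0.013, "post": 0.012}
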