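"""Multi-cohort simulator for a serum-urate variance-QTL study design.

Generates per-individual cohort tables with the statistical structure the
downstream analysis assumes: Hardy–Weinberg genotypes at an index variant,
urate means driven by age, BMI, sex, menopause status and an additive allele
effect, optional genotype-dependent residual dispersion (a true variance-QTL
effect), group-specific allele slopes (genotype × menopause interaction on
the mean), and participant-exclusion flags mirroring epidemiological cohort
practice (medication use, diagnosed gout or kidney disease, and the
menopause-analysis exclusions).

The residual model is log-linear in dosage within each analysis group::

    urate = mu(cohort, covariates, genotype, group) + eps
    eps ~ Normal(0, sigma0 * exp(d_group * dosage))

so ``d_group = 0`` for every group is the homoscedastic (no-vQTL) null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FLAG_NAMES",
    "CohortConfig",
    "simulate_cohort",
    "simulate_region",
    "apply_exclusions",
    "five_cohort_preset",
    "simulate_preset",
    "COHORT_DEMOGRAPHICS",
    "STRATIFIED_DISPERSION",
]

#: Per-group log-SD dispersion slopes for the "stratified scenario" preset,
#: calibrated once so that the pooled mean-adjusted variance effects land on
#: the published group pattern (pre ~ 0.19, post ~ 0.09, men ~ 0 in z² units
#: per allele) at the five-cohort study scale.
STRATIFIED_DISPERSION: Mapping[str, float] = {"men": 0.0, "pre": 0.22, "post": 0.14}

#: Recognised participant exclusion flags.
FLAG_NAMES = (
    "urate_lowering",
    "antihypertensive",
    "diuretic",
    "gout",
    "kidney_disease",
    "pregnant",
    "breastfeeding",
    "hrt",
    "menstruated_12mo",
    "missing_menopause",
)

#: Flags that only ever apply to women.
FEMALE_ONLY_FLAGS = frozenset(
    {"pregnant", "breastfeeding", "hrt", "menstruated_12mo", "missing_menopause"}
)

DEFAULT_FLAG_RATES: Mapping[str, float] = {
    "urate_lowering": 0.01,
    "antihypertensive": 0.10,
    "diuretic": 0.05,
    "gout": 0.02,
    "kidney_disease": 0.01,
    "pregnant": 0.01,
    "breastfeeding": 0.01,
    "hrt": 0.04,
    "menstruated_12mo": 0.02,
    "missing_menopause": 0.02,
}


@dataclass
class CohortConfig:
    """Data-generating parameters for one simulated cohort.

    Effect sizes are in mmol/L of serum urate. ``beta_allele`` is the additive
    mean effect per copy of the effect (urate-raising) allele;
    ``interaction_pre`` / ``interaction_post`` are the *extra* per-allele
    slopes in pre-/post-menopausal women relative to men.
    ``log_sigma_per_allele_by_group`` holds the per-allele dispersion slope on
    the log-SD scale for the groups ``men``, ``pre`` and ``post``.
    """

    cohort_name: str
    n: int
    effect_allele_freq: float
    mean_intercept: float
    beta_allele: float = 0.024
    beta_age: float = 0.0005
    beta_bmi: float = 0.006
    beta_female: float = -0.09
    beta_postmeno: float = 0.02
    interaction_pre: float = 0.0
    interaction_post: float = 0.0
    sigma0: float = 0.07
    log_sigma_per_allele_by_group: Mapping[str, float] = field(
        default_factory=lambda: {"men": 0.0, "pre": 0.0, "post": 0.0}
    )
    age_mean: float = 50.0
    age_sd: float = 8.0
    bmi_mean: float = 26.5
    bmi_sd: float = 5.0
    frac_female: float = 0.54
    frac_postmeno_of_women: float = 0.40
    exclusion_flag_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLAG_RATES)
    )
    #: SD of truncated-Normal noise added to hard genotype calls to emulate
    #: imputation uncertainty; 0 keeps hard 0/1/2 calls (the default).
    dosage_noise_sd: float = 0.0
    #: Whether the main analysis for this cohort excludes antihypertensive
    #: users (cohort-specific study policy).
    drop_antihypertensive: bool = True
    seed: int = 0

    def validate(self) -> None:
        scalar_fields = (
            "n", "effect_allele_freq", "mean_intercept", "beta_allele",
            "beta_age", "beta_bmi", "beta_female", "beta_postmeno",
            "interaction_pre", "interaction_post", "sigma0", "age_mean",
            "age_sd", "bmi_mean", "bmi_sd", "frac_female",
            "frac_postmeno_of_women", "dosage_noise_sd",
        )
        for name in scalar_fields:
            value = getattr(self, name)
            if not math.isfinite(float(value)):
                raise ValueError(f"non-finite value for config field {name!r}")
        for key, value in self.log_sigma_per_allele_by_group.items():
            if not math.isfinite(float(value)):
                raise ValueError(
                    f"non-finite value for config field "
                    f"log_sigma_per_allele_by_group[{key!r}]"
                )
        for key, value in self.exclusion_flag_rates.items():
            if not math.isfinite(float(value)) or not 0.0 <= value <= 1.0:
                raise ValueError(
                    f"invalid rate for config field exclusion_flag_rates[{key!r}]"
                )
        if self.n < 1:
            raise ValueError("config field n must be >= 1")
        if not 0.0 < self.effect_allele_freq < 1.0:
            raise ValueError("config field effect_allele_freq must be in (0, 1)")
        if self.sigma0 <= 0:
            raise ValueError("config field sigma0 must be > 0")
        for name in ("frac_female", "frac_postmeno_of_women"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"config field {name} must be in [0, 1]")


def _dispersion_sd(config: CohortConfig, dosage: np.ndarray, group: np.ndarray) -> np.ndarray:
    slopes = {"men": 0.0, "pre": 0.0, "post": 0.0}
    slopes.update(config.log_sigma_per_allele_by_group)
    slope = np.array([slopes[g] for g in group])
    return config.sigma0 * np.exp(slope * dosage)


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate one cohort table under Hardy–Weinberg genotypes.

    Returns a DataFrame with columns ``id, cohort, sex, age, bmi, menopause,
    group, urate, genotype, dosage, pc1, pc2, flags``. ``genotype`` is the
    hard call (0/1/2 copies of the effect allele); ``dosage`` equals the hard
    call unless ``dosage_noise_sd > 0``, in which case truncated-Normal noise
    emulating imputation uncertainty is added. ``flags`` is a comma-joined
    string of exclusion flags (empty when none apply).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    return _assemble_cohort(
        config, rng,
        rng.binomial(2, config.effect_allele_freq, size=config.n).astype(float),
    )


def _assemble_cohort(
    config: CohortConfig, rng: np.random.Generator, genotype: np.ndarray
) -> pd.DataFrame:
    """Build covariates, groups, flags and urate around a given genotype."""
    n = config.n
    dosage = genotype
    if config.dosage_noise_sd > 0:
        dosage = np.clip(genotype + rng.normal(0.0, config.dosage_noise_sd, n), 0.0, 2.0)

    female = rng.random(n) < config.frac_female
    sex = np.where(female, "female", "male")
    age = np.maximum(18.0, rng.normal(config.age_mean, config.age_sd, n))
    bmi = np.maximum(15.0, rng.normal(config.bmi_mean, config.bmi_sd, n))
    pc1 = rng.standard_normal(n)
    pc2 = rng.standard_normal(n)

    postmeno = female & (rng.random(n) < config.frac_postmeno_of_women)
    menopause = np.where(~female, "NA", np.where(postmeno, "post", "pre"))

    # Exclusion flags; female-only flags drawn only for the women they can
    # apply to (pregnancy/breastfeeding only pre-menopausal, menstruated_12mo
    # only recorded against a post-menopausal self-report).
    rates = dict(DEFAULT_FLAG_RATES)
    rates.update(config.exclusion_flag_rates)
    flag_sets: list[list[str]] = [[] for _ in range(n)]
    premeno = female & ~postmeno
    for name in FLAG_NAMES:
        rate = rates.get(name, 0.0)
        if rate <= 0:
            continue
        draw = rng.random(n) < rate
        if name in ("pregnant", "breastfeeding"):
            draw &= premeno
        elif name == "menstruated_12mo":
            draw &= postmeno
        elif name in FEMALE_ONLY_FLAGS:
            draw &= female
        for i in np.nonzero(draw)[0]:
            flag_sets[i].append(name)

    missing = np.array(["missing_menopause" in f for f in flag_sets])
    menopause = np.where(missing & female, "unknown", menopause)

    group = np.where(~female, "men", np.where(menopause == "post", "post", "pre"))
    # Women with unknown menopause status keep the underlying (latent) group
    # for phenotype generation but are flagged for strata exclusion.

    inter = np.zeros(n)
    inter[(group == "pre") & female] = config.interaction_pre
    inter[(group == "post") & female] = config.interaction_post

    mu = (
        config.mean_intercept
        + (config.beta_allele + inter) * dosage
        + config.beta_age * age
        + config.beta_bmi * bmi
        + config.beta_female * female
        + config.beta_postmeno * postmeno
    )
    sd = _dispersion_sd(config, dosage, group)
    urate = np.maximum(0.01, mu + rng.normal(0.0, 1.0, n) * sd)

    return pd.DataFrame(
        {
            "id": [f"{config.cohort_name}_{i:06d}" for i in range(n)],
            "cohort": config.cohort_name,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "menopause": menopause,
            "group": group,
            "urate": urate,
            "genotype": genotype,
            "dosage": dosage,
            "pc1": pc1,
            "pc2": pc2,
            "flags": [",".join(f) for f in flag_sets],
        }
    )


def simulate_region(
    n_snps: int,
    ld_decay: float,
    causal_index: int,
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort plus a dosage matrix of ``n_snps`` correlated variants.

    Variants share the causal variant's allele frequency and are generated by
    Markov haplotype copying: each haplotype allele copies its left neighbour
    with probability ``ld_decay``, giving an exact AR(1) correlation
    ``ld_decay ** |i - j|`` between dosage columns. Only the variant at
    ``causal_index`` enters the phenotype model.

    Returns ``(table, dosage_matrix)`` where the matrix has one column per
    variant named ``snp0001`` ... in positional order.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0.0 <= ld_decay < 1.0:
        raise ValueError("ld_decay must be in [0, 1)")
    if not 0 <= causal_index < n_snps:
        raise ValueError("causal_index out of range")
    config.validate()

    rng = np.random.default_rng(config.seed)
    n, p = config.n, config.effect_allele_freq

    haplotypes = np.empty((2, n, n_snps), dtype=np.int8)
    for h in range(2):
        alleles = np.empty((n, n_snps), dtype=np.int8)
        alleles[:, 0] = rng.random(n) < p
        for j in range(1, n_snps):
            copy = rng.random(n) < ld_decay
            fresh = rng.random(n) < p
            alleles[:, j] = np.where(copy, alleles[:, j - 1], fresh)
        haplotypes[h] = alleles
    dosages = haplotypes.sum(axis=0).astype(float)

    # The causal column is the genotype the phenotype model sees.
    table = _assemble_cohort(config, rng, dosages[:, causal_index])

    width = max(4, len(str(n_snps)))
    columns = [f"snp{j + 1:0{width}d}" for j in range(n_snps)]
    matrix = pd.DataFrame(dosages, columns=columns, index=table["id"].to_numpy())
    return table, matrix


#: Flags always removed in the main analysis.
_MAIN_DROP = ("urate_lowering", "gout", "kidney_disease")
#: Additional female-strata exclusions for the menopause analysis.
_STRATA_DROP = ("pregnant", "breastfeeding", "hrt", "missing_menopause")


def apply_exclusions(
    table: pd.DataFrame,
    mode: str = "main",
    drop_antihypertensive: bool | None = None,
    drop_diuretic: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply participant-exclusion rules; returns (table, removal report).

    ``mode="main"`` removes urate-lowering medication users, self-reported
    gout and kidney disease, plus antihypertensive users where the cohort's
    policy says so (``drop_antihypertensive=None`` looks the policy up in the
    table's ``drop_antihypertensive`` attr, defaulting to True).

    ``mode="menopause_strata"`` additionally removes, from women only,
    pregnancy, breastfeeding, hormone-replacement therapy, missing menopause
    status, and inconsistent post-menopausal reports (menstruated within the
    last 12 months). Rules are applied in order; the report counts rows
    removed by the first rule that matches them, and surviving rows are
    returned unmodified.
    """
    if mode not in ("main", "menopause_strata"):
        raise ValueError(f"unknown exclusion mode: {mode!r}")
    if drop_antihypertensive is None:
        drop_antihypertensive = bool(table.attrs.get("drop_antihypertensive", True))

    flags = table["flags"].fillna("").astype(str)
    has = {name: flags.str.split(",").apply(lambda f, n=name: n in f) for name in FLAG_NAMES}
    female = table["sex"].to_numpy() == "female"

    rules: list[tuple[str, np.ndarray]] = [(r, has[r].to_numpy()) for r in _MAIN_DROP]
    if drop_antihypertensive:
        rules.append(("antihypertensive", has["antihypertensive"].to_numpy()))
    if drop_diuretic:
        rules.append(("diuretic", has["diuretic"].to_numpy()))
    if mode == "menopause_strata":
        for r in _STRATA_DROP:
            rules.append((r, has[r].to_numpy() & female))
        inconsistent = (
            has["menstruated_12mo"].to_numpy()
            & female
            & (table["menopause"].to_numpy() == "post")
        )
        rules.append(("post_menopausal_menstruated_12mo", inconsistent))

    removed = np.zeros(len(table), dtype=bool)
    report: dict[str, int] = {}
    for name, mask in rules:
        newly = mask & ~removed
        report[name] = int(newly.sum())
        removed |= mask
    return table.loc[~removed].copy(), report


#: Published demographic and clinical summaries of the five study samples:
#: size, mean (SD) urate in mmol/L, mean (SD) age, % female, mean (SD) BMI,
#: % post-menopausal among women, and whether the cohort's main analysis
#: excluded antihypertensive users.
COHORT_DEMOGRAPHICS: Mapping[str, Mapping[str, float | bool]] = {
    "ARIC": dict(n=5362, urate_mean=0.332, age_mean=53.5, age_sd=5.58,
                 frac_female=0.542, bmi_mean=26.0, bmi_sd=4.33,
                 frac_postmeno=0.498, drop_antihypertensive=True),
    "FHS": dict(n=3282, urate_mean=0.308, age_mean=39.4, age_sd=8.64,
                frac_female=0.538, bmi_mean=26.4, bmi_sd=5.18,
                frac_postmeno=0.090, drop_antihypertensive=True),
    "ARIC_diuretics": dict(n=1196, urate_mean=0.398, age_mean=55.9, age_sd=5.55,
                           frac_female=0.657, bmi_mean=29.2, bmi_sd=5.71,
                           frac_postmeno=0.510, drop_antihypertensive=False),
    "CARDIA": dict(n=1496, urate_mean=0.284, age_mean=40.7, age_sd=3.33,
                   frac_female=0.537, bmi_mean=27.1, bmi_sd=5.85,
                   frac_postmeno=0.052, drop_antihypertensive=False),
    # CHS women are all post-menopausal at the cohort's ages: its
    # pre-menopausal partition is empty in the stratified analysis.
    "CHS": dict(n=2799, urate_mean=0.328, age_mean=72.4, age_sd=5.47,
                frac_female=0.611, bmi_mean=26.2, bmi_sd=4.42,
                frac_postmeno=1.0, drop_antihypertensive=False),
}


def five_cohort_preset(
    seed: int,
    beta_allele: float = 0.024,
    effect_allele_freq: float = 0.77,
    interaction_pre: float = 0.0,
    interaction_post: float = 0.0,
    dispersion_by_group: Mapping[str, float] | None = None,
    exclusion_flag_rates: Mapping[str, float] | None = None,
    n_scale: float = 1.0,
) -> list[CohortConfig]:
    """Configs for the five study-like cohorts.

    The demographic structure follows the published cohort summaries; the
    genetic model defaults to a pure additive mean effect of 0.024 mmol/L per
    effect allele at frequency 0.77 (the urate-raising major allele) with no
    dispersion or interaction effect. The per-cohort intercept is solved so
    the expected urate mean matches the published cohort mean. ``n_scale``
    shrinks every cohort proportionally for quick smoke runs; the default 1.0
    keeps the study sizes.
    """
    configs = []
    for i, (name, demo) in enumerate(COHORT_DEMOGRAPHICS.items()):
        cfg = CohortConfig(
            cohort_name=name,
            n=max(1, int(round(demo["n"] * n_scale))),
            effect_allele_freq=effect_allele_freq,
            mean_intercept=0.0,
            beta_allele=beta_allele,
            interaction_pre=interaction_pre,
            interaction_post=interaction_post,
            log_sigma_per_allele_by_group=dict(dispersion_by_group or {}),
            age_mean=float(demo["age_mean"]),
            age_sd=float(demo["age_sd"]),
            bmi_mean=float(demo["bmi_mean"]),
            bmi_sd=float(demo["bmi_sd"]),
            frac_female=float(demo["frac_female"]),
            frac_postmeno_of_women=float(demo["frac_postmeno"]),
            drop_antihypertensive=bool(demo["drop_antihypertensive"]),
            seed=(seed + i * 1_000_003) % (2**31 - 1),
        )
        if exclusion_flag_rates is not None:
            cfg.exclusion_flag_rates = dict(exclusion_flag_rates)
        # Solve the intercept so E[urate] matches the published cohort mean.
        ff, fp = cfg.frac_female, cfg.frac_postmeno_of_women
        mean_dosage = 2 * effect_allele_freq
        expected = (
            (beta_allele + interaction_pre * ff * (1 - fp) + interaction_post * ff * fp)
            * mean_dosage
            + cfg.beta_age * cfg.age_mean
            + cfg.beta_bmi * cfg.bmi_mean
            + cfg.beta_female * ff
            + cfg.beta_postmeno * ff * fp
        )
        cfg.mean_intercept = float(demo["urate_mean"]) - expected
        configs.append(cfg)
    return configs


def simulate_preset(configs: Sequence[CohortConfig]) -> dict[str, pd.DataFrame]:
    """Simulate every cohort in a preset; tables carry the exclusion policy."""
    tables = {}
    for cfg in configs:
        table = simulate_cohort(cfg)
        table.attrs["drop_antihypertensive"] = cfg.drop_antihypertensive
        tables[cfg.cohort_name] = table
    return tables
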