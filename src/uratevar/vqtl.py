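"""Per-variant association tests: mean effect, variance effect, region scan.

The mean test regresses urate on effect-allele dosage plus covariates within
a cohort; the variance test regresses the z² variance phenotype on dosage.
The "adjusted" variance test removes genotype-class mean urate before the z²
pipeline, so it is robust to a pure mean effect. p-values come from the t
distribution with residual degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phenotype_prep import BLOM_OFFSET, VariancePhenotype, make_variance_phenotype

__all__ = [
    "EffectEstimate",
    "VqtlResult",
    "mean_effect_test",
    "variance_effect_test",
    "run_vqtl",
    "region_scan",
]


@dataclass
class EffectEstimate:
    """One regression coefficient: beta, SE, two-sided p, n used, and the
    proportion of outcome variance attributable to the dosage term (partial
    r² for the covariate-adjusted mean model, model r² for the simple
    variance regression)."""

    beta: float
    se: float
    p: float
    n: int
    r2: float


@dataclass
class VqtlResult:
    """Mean / unadjusted-variance / adjusted-variance estimates for one
    variant, computed on the same post-exclusion sample."""

    variant: str
    mean: EffectEstimate
    var_unadjusted: EffectEstimate
    var_adjusted: EffectEstimate


def _check_dosage(dosage: np.ndarray, n_rows: int) -> np.ndarray:
    dosage = np.asarray(dosage, dtype=float)
    if len(dosage) != n_rows:
        raise ValueError("dosage vector is not aligned with the table")
    if np.ptp(dosage) == 0:
        raise ValueError("monomorphic variant: dosage has zero variance")
    return dosage


def mean_effect_test(table: pd.DataFrame, dosage: np.ndarray) -> EffectEstimate:
    """Additive mean-effect test: OLS of urate on dosage + age + BMI + sex +
    PC1 + PC2 within a cohort. Reports the dosage coefficient with its
    partial r² (incremental sum of squares over the covariate-only model)."""
    if len(table) < 30:
        raise ValueError("mean_effect_test requires >= 30 individuals")
    dosage = _check_dosage(dosage, len(table))

    female = (table["sex"].to_numpy() == "female").astype(float)
    cols = {"dosage": dosage, "age": table["age"], "bmi": table["bmi"],
            "pc1": table["pc1"], "pc2": table["pc2"]}
    if np.ptp(female) > 0:
        cols["female"] = female
    X = sm.add_constant(pd.DataFrame(cols, index=table.index))
    y = table["urate"].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()

    reduced = sm.OLS(y, X.drop(columns="dosage")).fit()
    sst = float(np.sum((y - y.mean()) ** 2))
    partial_r2 = float((reduced.ssr - fit.ssr) / sst) if sst > 0 else 0.0
    return EffectEstimate(
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        p=float(fit.pvalues["dosage"]),
        n=len(table),
        r2=partial_r2,
    )


def variance_effect_test(vp: VariancePhenotype, dosage: np.ndarray) -> EffectEstimate:
    """Variance-effect test: simple OLS of z² on dosage (with intercept)."""
    y = vp.z2
    dosage = _check_dosage(dosage, len(y))
    n = len(y)
    x = dosage - dosage.mean()
    yc = y - y.mean()
    sxx = float(x @ x)
    beta = float(x @ yc) / sxx
    resid = yc - beta * x
    df = n - 2
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    sst = float(yc @ yc)
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return EffectEstimate(beta=beta, se=float(se), p=float(p), n=n, r2=r2)


def run_vqtl(
    table: pd.DataFrame,
    dosage: np.ndarray,
    variant: str = "variant",
    offset: float = BLOM_OFFSET,
    residualize_first: bool = False,
) -> VqtlResult:
    """Run the three tests for one variant on one post-exclusion sample."""
    dosage = _check_dosage(np.asarray(dosage, dtype=float), len(table))
    mean = mean_effect_test(table, dosage)
    vp_u = make_variance_phenotype(table, adjust_for_genotype=False, offset=offset)
    vp_a = make_variance_phenotype(
        table,
        adjust_for_genotype=True,
        variant_dosage=dosage,
        offset=offset,
        residualize_first=residualize_first,
    )
    return VqtlResult(
        variant=variant,
        mean=mean,
        var_unadjusted=variance_effect_test(vp_u, dosage),
        var_adjusted=variance_effect_test(vp_a, dosage),
    )


def region_scan(
    table: pd.DataFrame,
    dosage_matrix: pd.DataFrame,
    mode: str = "unadjusted",
    positions: np.ndarray | None = None,
    offset: float = BLOM_OFFSET,
) -> pd.DataFrame:
    """Variance-effect scan across every variant column of ``dosage_matrix``.

    ``mode="unadjusted"`` computes the variance phenotype once and tests each
    variant against it; ``mode="adjusted"`` recomputes the genotype-mean
    adjustment per variant. Monomorphic variants are skipped with a warning
    and recorded in the output's ``skipped_monomorphic`` attr. Output rows
    are sorted by position and carry a -log10 p column plus a Bonferroni
    column (for convenience; inference uses the raw p-values).
    """
    if mode not in ("unadjusted", "adjusted"):
        raise ValueError(f"unknown scan mode: {mode!r}")
    if dosage_matrix.shape[1] < 1:
        raise ValueError("region_scan requires at least one variant")
    if positions is None:
        positions = np.arange(1, dosage_matrix.shape[1] + 1)

    vp_shared = None
    if mode == "unadjusted":
        vp_shared = make_variance_phenotype(table, adjust_for_genotype=False, offset=offset)

    rows, skipped = [], []
    for j, name in enumerate(dosage_matrix.columns):
        dosage = dosage_matrix[name].to_numpy(dtype=float)
        if np.ptp(dosage) == 0:
            warnings.warn(f"skipping monomorphic variant {name}")
            skipped.append(name)
            continue
        if mode == "unadjusted":
            est = variance_effect_test(vp_shared, dosage)
        else:
            vp = make_variance_phenotype(
                table, adjust_for_genotype=True, variant_dosage=dosage, offset=offset
            )
            est = variance_effect_test(vp, dosage)
        rows.append(
            dict(variant=name, position=int(positions[j]), beta=est.beta,
                 se=est.se, p=est.p, neglog10p=-np.log10(est.p), n=est.n,
                 mode=mode)
        )
    out = pd.DataFrame(
        rows,
        columns=["variant", "position", "beta", "se", "p", "neglog10p", "n", "mode"],
    )
    if len(out):
        out = out.sort_values("position", kind="stable").reset_index(drop=True)
        out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    else:
        out["p_bonferroni"] = pd.Series(dtype=float)
    out.attrs["skipped_monomorphic"] = skipped
    return out
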