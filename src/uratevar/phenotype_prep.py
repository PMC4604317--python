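"""Construction of the serum-urate variance phenotype.

The variance variable z² is built in three steps within each sex × cohort
stratum: (1) ordinary least-squares residualization of urate on age, BMI and
the top two genetic principal components; (2) a ranked inverse-normal
transform (Blom offset) of the absolute residuals, yielding z; (3) squaring,
yielding z². An optional mean-adjustment step subtracts the genotype-class
mean urate first, so a pure additive mean effect cannot masquerade as a
variance effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "BLOM_OFFSET",
    "VariancePhenotype",
    "residualize",
    "rank_inverse_normal",
    "make_variance_phenotype",
]

#: Default rank-quantile offset c in (rank - c) / (n - 2c + 1).
BLOM_OFFSET = 0.375

_COVARIATES = ("age", "bmi", "pc1", "pc2")


@dataclass
class VariancePhenotype:
    """Per-individual variance phenotype aligned with its source table.

    ``data`` holds columns ``id, stratum, residual, z, z2``; ``adjusted``
    records whether genotype-class means were subtracted before
    residualization.
    """

    data: pd.DataFrame
    adjusted: bool

    @property
    def z(self) -> np.ndarray:
        return self.data["z"].to_numpy()

    @property
    def z2(self) -> np.ndarray:
        return self.data["z2"].to_numpy()


def _strata(table: pd.DataFrame) -> pd.core.groupby.DataFrameGroupBy:
    return table.groupby(["cohort", "sex"], sort=False, observed=True)


def residualize(table: pd.DataFrame, response: np.ndarray | None = None) -> np.ndarray:
    """OLS residuals of urate on age, BMI, PC1, PC2 within sex × cohort strata.

    ``response`` optionally replaces the ``urate`` column (used by the
    genotype-mean-adjusted pipeline). Residuals are returned aligned to the
    input rows and sum to ~0 within each stratum.

    Raises ``ValueError`` naming the stratum if its design matrix is rank
    deficient or the stratum is too small to fit five coefficients.
    """
    y_all = table["urate"].to_numpy(dtype=float) if response is None else np.asarray(response, dtype=float)
    resid = np.empty(len(table), dtype=float)
    for (cohort, sex), idx in _strata(table).indices.items():
        sub = table.iloc[idx]
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in _COVARIATES]
        )
        if len(idx) <= X.shape[1]:
            raise ValueError(
                f"stratum ({cohort}, {sex}) too small to residualize: n={len(idx)}"
            )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design in stratum ({cohort}, {sex})")
        y = y_all[idx]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid[idx] = y - X @ beta
    return resid


def rank_inverse_normal(values: np.ndarray, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Ranked inverse-normal transform z_i = Phi^-1((r_i - c) / (n - 2c + 1)).

    Ranks are ascending with ties given their mean rank; ``offset`` is the
    Blom constant c (3/8 by default; 0.5 and 0 are the usual alternatives).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("rank_inverse_normal requires a 1-d vector with n >= 2")
    if not np.all(np.isfinite(values)):
        raise ValueError("rank_inverse_normal requires finite values")
    ranks = rankdata(values, method="average")
    n = len(values)
    return ndtri((ranks - offset) / (n - 2 * offset + 1))


def _genotype_class_means(
    urate: np.ndarray, genotype: np.ndarray, stratum_label: str
) -> np.ndarray:
    """Per-observation genotype-class mean urate; merges sparse classes.

    A genotype class with fewer than 2 members in the stratum is merged into
    the nearest (by allele count) occupied class, with a warning.
    """
    classes = np.unique(genotype)
    counts = {c: int((genotype == c).sum()) for c in classes}
    merged = {}
    for c in classes:
        if counts[c] >= 2:
            merged[c] = c
            continue
        others = [o for o in classes if counts[o] >= 2]
        if not others:
            merged[c] = c
            continue
        target = min(others, key=lambda o: abs(o - c))
        merged[c] = target
        warnings.warn(
            f"genotype class {int(c)} has <2 members in stratum {stratum_label}; "
            f"merged with class {int(target)}"
        )
    effective = np.array([merged[c] for c in genotype])
    out = np.empty(len(urate))
    for c in np.unique(effective):
        mask = effective == c
        out[mask] = urate[mask].mean()
    return out


def make_variance_phenotype(
    table: pd.DataFrame,
    adjust_for_genotype: bool = False,
    variant_dosage: np.ndarray | None = None,
    offset: float = BLOM_OFFSET,
    residualize_first: bool = False,
) -> VariancePhenotype:
    """Run the full variance-phenotype pipeline on a cohort table.

    With ``adjust_for_genotype``, continuous dosages are rounded to genotype
    classes {0,1,2} and the class-specific mean urate (computed within each
    sex × cohort stratum) is subtracted before covariate residualization;
    ``residualize_first`` flips that order (residualize covariates first,
    then remove genotype-class means of the residuals). The INT is applied to
    absolute residuals within each stratum.
    """
    if adjust_for_genotype:
        if variant_dosage is None:
            raise ValueError("adjust_for_genotype requires variant_dosage")
        dosage = np.asarray(variant_dosage, dtype=float)
        if len(dosage) != len(table):
            raise ValueError("variant_dosage is not aligned with the table")
        genotype = np.rint(np.clip(dosage, 0.0, 2.0))

    urate = table["urate"].to_numpy(dtype=float)
    groups = _strata(table).indices

    if adjust_for_genotype and not residualize_first:
        working = urate.copy()
        for (cohort, sex), idx in groups.items():
            working[idx] -= _genotype_class_means(
                urate[idx], genotype[idx], f"({cohort}, {sex})"
            )
        resid = residualize(table, response=working)
    else:
        resid = residualize(table)
        if adjust_for_genotype:
            resid = resid.copy()
            for (cohort, sex), idx in groups.items():
                resid[idx] -= _genotype_class_means(
                    resid[idx], genotype[idx], f"({cohort}, {sex})"
                )

    z = np.empty(len(table))
    for _, idx in groups.items():
        z[idx] = rank_inverse_normal(np.abs(resid[idx]), offset=offset)

    data = pd.DataFrame(
        {
            "id": table["id"].to_numpy(),
            "stratum": [f"{c}:{s}" for c, s in zip(table["cohort"], table["sex"])],
            "residual": resid,
            "z": z,
            "z2": z**2,
        },
        index=table.index,
    )
    return VariancePhenotype(data=data, adjusted=adjust_for_genotype)
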