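"""Stratified variance tests and genotype × menopause interaction models.

Participants are partitioned into men, pre-menopausal women, and
post-menopausal women (after the menopause-analysis exclusions). The
mean-adjusted variance test is run per group per cohort and pooled across
cohorts; interaction models compare each female group against men as
referent, for the mean (urate ~ age + BMI + allele + group + allele:group)
and for the variance phenotype (z² ~ allele + group + allele:group), with
cohort fixed effects when cohorts are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .meta_analysis import MetaResult, auto_meta
from .phenotype_prep import BLOM_OFFSET, VariancePhenotype, make_variance_phenotype
from .synthetic_data import apply_exclusions
from .vqtl import EffectEstimate, variance_effect_test

__all__ = [
    "GROUPS",
    "InteractionResult",
    "GenotypeGroupMeans",
    "stratify",
    "stratified_vqtl",
    "mean_interaction_model",
    "variance_interaction_model",
    "genotype_group_means",
    "tt_minus_gg_contrast",
]

GROUPS = ("men", "pre", "post")


@dataclass
class InteractionResult:
    """Allele × group interaction estimate with model-fit increments."""

    beta_interaction: float
    se: float
    p_interaction: float
    r2_base: float
    r2_full: float
    referent: str
    comparison: str
    n: int


@dataclass
class GenotypeGroupMeans:
    """Per (group, genotype-class) mean-urate contrasts vs the men /
    zero-copies reference cell (beta = 0 there by construction)."""

    betas: Mapping[tuple[str, int], float] = field(default_factory=dict)
    pvalues: Mapping[tuple[str, int], float] = field(default_factory=dict)
    referent: tuple[str, int] = ("men", 0)


def stratify(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a cohort table into men / pre / post groups.

    Assumes the menopause-analysis exclusions are already applied for the
    female partitions: women with unknown menopause status fall in no
    partition; all men are retained. Empty partitions are allowed.
    """
    men = table[table["sex"] == "male"]
    women = table[table["sex"] == "female"]
    return {
        "men": men,
        "pre": women[women["menopause"] == "pre"],
        "post": women[women["menopause"] == "post"],
    }


def stratified_vqtl(
    cohorts: Mapping[str, tuple[pd.DataFrame, np.ndarray]],
    min_n: int = 30,
    offset: float = BLOM_OFFSET,
    het_threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, MetaResult | None]]:
    """Mean-adjusted variance test per group per cohort, pooled across cohorts.

    ``cohorts`` maps cohort name to (main-excluded table, aligned dosage).
    Within each cohort the menopause-strata exclusions are applied, the
    adjusted variance phenotype is built on the surviving sample, and the
    z² ~ dosage regression is run within each group with at least ``min_n``
    members (smaller groups are reported with missing estimates, like a
    cohort with no pre-menopausal women). Per-group pooling uses the
    heterogeneity-gated meta-analysis.

    Returns (per-cohort long table, {group: pooled MetaResult or None}).
    """
    rows = []
    per_group: dict[str, list[EffectEstimate]] = {g: [] for g in GROUPS}
    for cohort, (table, dosage) in cohorts.items():
        dosage = np.asarray(dosage, dtype=float)
        keep_pos = np.arange(len(table))
        sub, _ = apply_exclusions(table.reset_index(drop=True), mode="menopause_strata")
        dos = dosage[sub.index.to_numpy()]
        sub = sub.reset_index(drop=True)
        vp = make_variance_phenotype(
            sub, adjust_for_genotype=True, variant_dosage=dos, offset=offset
        )
        parts = stratify(sub)
        for group in GROUPS:
            part = parts[group]
            row = dict(cohort=cohort, group=group, n=len(part),
                       beta=np.nan, se=np.nan, p=np.nan, r2=np.nan)
            if len(part) >= min_n:
                idx = part.index.to_numpy()
                d = dos[idx]
                if np.ptp(d) > 0:
                    sub_vp = VariancePhenotype(
                        data=vp.data.iloc[idx], adjusted=True
                    )
                    est = variance_effect_test(sub_vp, d)
                    row.update(beta=est.beta, se=est.se, p=est.p, r2=est.r2)
                    per_group[group].append(est)
            rows.append(row)
    pooled: dict[str, MetaResult | None] = {}
    for group in GROUPS:
        ests = per_group[group]
        pooled[group] = auto_meta(ests, het_threshold=het_threshold) if ests else None
    return pd.DataFrame(rows), pooled


def _pooled_design(
    frames: Sequence[pd.DataFrame], add_cohort_effects: bool
) -> pd.DataFrame | None:
    if not add_cohort_effects:
        return None
    cohorts = pd.concat(frames)["cohort"]
    if cohorts.nunique() <= 1:
        return None
    return pd.get_dummies(cohorts, prefix="cohort", drop_first=True, dtype=float)


def mean_interaction_model(
    table: pd.DataFrame,
    dosage: np.ndarray,
    comparison_group: str,
    cohort_effects: bool = True,
) -> tuple[InteractionResult, GenotypeGroupMeans]:
    """Genotype × group interaction on mean urate, men as referent.

    Fits urate ~ age + BMI + allele + group + allele:group on the men +
    comparison-group subset (additive allele coding; cohort indicator
    covariates when several cohorts are pooled). Also fits the saturated
    group × genotype cell-means model (men / zero-copies reference) from
    which per-genotype contrasts such as beta_TT - beta_GG are read off.
    """
    if comparison_group not in ("pre", "post"):
        raise ValueError(f"comparison_group must be 'pre' or 'post', got {comparison_group!r}")
    dosage = np.asarray(dosage, dtype=float)
    parts = stratify(table)
    men, comp = parts["men"], parts[comparison_group]
    if len(men) == 0 or len(comp) == 0:
        raise ValueError("both referent and comparison groups must be non-empty")

    sub = pd.concat([men, comp])
    pos = np.concatenate([men.index.to_numpy(), comp.index.to_numpy()])
    # positional alignment: dosage is aligned with the original table rows
    loc = table.index.get_indexer(pos)
    d = dosage[loc]
    for label, dd in (("men", d[: len(men)]), (comparison_group, d[len(men):])):
        if np.ptp(dd) == 0:
            raise ValueError(f"monomorphic dosage in group {label!r}")
    is_comp = np.concatenate([np.zeros(len(men)), np.ones(len(comp))])

    X = pd.DataFrame(
        {"age": sub["age"].to_numpy(dtype=float),
         "bmi": sub["bmi"].to_numpy(dtype=float),
         "allele": d,
         "group": is_comp,
         "allele_x_group": d * is_comp},
        index=range(len(sub)),
    )
    dummies = _pooled_design([sub], cohort_effects)
    if dummies is not None:
        X = pd.concat([X, dummies.reset_index(drop=True)], axis=1)
    y = sub["urate"].to_numpy(dtype=float)
    full = sm.OLS(y, sm.add_constant(X)).fit()
    base = sm.OLS(y, sm.add_constant(X.drop(columns="allele_x_group"))).fit()

    result = InteractionResult(
        beta_interaction=float(full.params["allele_x_group"]),
        se=float(full.bse["allele_x_group"]),
        p_interaction=float(full.pvalues["allele_x_group"]),
        r2_base=float(base.rsquared),
        r2_full=float(full.rsquared),
        referent="men",
        comparison=comparison_group,
        n=len(sub),
    )
    cells = genotype_group_means(table, dosage, groups=("men", comparison_group),
                                 cohort_effects=cohort_effects)
    return result, cells


def genotype_group_means(
    table: pd.DataFrame,
    dosage: np.ndarray,
    groups: Sequence[str] = GROUPS,
    cohort_effects: bool = True,
) -> GenotypeGroupMeans:
    """Saturated group × genotype cell-means model for mean urate.

    Dosages are rounded to genotype classes; each (group, class) cell other
    than the men / zero-copies reference gets an indicator, and the model
    adjusts for age, BMI and (optionally) cohort. Returns per-cell betas and
    p-values relative to the reference cell.
    """
    dosage = np.asarray(dosage, dtype=float)
    parts = stratify(table)
    frames = [parts[g].assign(_group=g) for g in groups if len(parts[g])]
    sub = pd.concat(frames)
    loc = table.index.get_indexer(sub.index.to_numpy())
    geno = np.rint(np.clip(dosage[loc], 0, 2)).astype(int)
    glab = sub["_group"].to_numpy()

    ref = ("men", 0)
    cells = sorted({(g, c) for g, c in zip(glab, geno)})
    X = pd.DataFrame({"age": sub["age"].to_numpy(dtype=float),
                      "bmi": sub["bmi"].to_numpy(dtype=float)},
                     index=range(len(sub)))
    for cell in cells:
        if cell == ref:
            continue
        name = f"cell_{cell[0]}_{cell[1]}"
        X[name] = ((glab == cell[0]) & (geno == cell[1])).astype(float)
    dummies = _pooled_design([sub], cohort_effects)
    if dummies is not None:
        X = pd.concat([X, dummies.reset_index(drop=True)], axis=1)
    fit = sm.OLS(sub["urate"].to_numpy(dtype=float), sm.add_constant(X)).fit()

    betas = {ref: 0.0}
    pvals = {ref: 1.0}
    for cell in cells:
        if cell == ref:
            continue
        name = f"cell_{cell[0]}_{cell[1]}"
        betas[cell] = float(fit.params[name])
        pvals[cell] = float(fit.pvalues[name])
    return GenotypeGroupMeans(betas=betas, pvalues=pvals, referent=ref)


def tt_minus_gg_contrast(cells: GenotypeGroupMeans | Mapping, group: str) -> float:
    """Contrast of the two-copies vs zero-copies cell within a group.

    Accepts either a fitted ``GenotypeGroupMeans`` or a plain mapping from
    (group, genotype class) to beta — e.g. published per-cell estimates.
    """
    betas = cells.betas if isinstance(cells, GenotypeGroupMeans) else cells
    return float(betas[(group, 2)] - betas[(group, 0)])


def variance_interaction_model(
    vp_adjusted: VariancePhenotype,
    dosage: np.ndarray,
    groups: np.ndarray,
    comparison_group: str,
    cohorts: np.ndarray | None = None,
) -> InteractionResult:
    """Genotype × group interaction on the mean-adjusted variance phenotype.

    Fits z² ~ allele + group + allele:group on men + comparison group (men
    referent, additive allele coding; optional cohort fixed effects) and
    reports the interaction beta with plain model r² with and without the
    interaction term.
    """
    if not vp_adjusted.adjusted:
        raise ValueError("variance_interaction_model requires the mean-adjusted phenotype")
    if comparison_group not in ("pre", "post"):
        raise ValueError(f"comparison_group must be 'pre' or 'post', got {comparison_group!r}")
    dosage = np.asarray(dosage, dtype=float)
    groups = np.asarray(groups)
    keep = (groups == "men") | (groups == comparison_group)
    if keep.sum() == 0 or (groups == comparison_group).sum() == 0 or (groups == "men").sum() == 0:
        raise ValueError("both referent and comparison groups must be non-empty")
    d = dosage[keep]
    is_comp = (groups[keep] == comparison_group).astype(float)
    for label, dd in (("men", d[is_comp == 0]), (comparison_group, d[is_comp == 1])):
        if np.ptp(dd) == 0:
            raise ValueError(f"monomorphic dosage in group {label!r}")

    X = pd.DataFrame({"allele": d, "group": is_comp, "allele_x_group": d * is_comp})
    if cohorts is not None:
        labels = pd.Series(np.asarray(cohorts)[keep])
        if labels.nunique() > 1:
            X = pd.concat(
                [X, pd.get_dummies(labels, prefix="cohort", drop_first=True, dtype=float)],
                axis=1,
            )
    y = vp_adjusted.z2[keep]
    full = sm.OLS(y, sm.add_constant(X)).fit()
    base = sm.OLS(y, sm.add_constant(X.drop(columns="allele_x_group"))).fit()
    return InteractionResult(
        beta_interaction=float(full.params["allele_x_group"]),
        se=float(full.bse["allele_x_group"]),
        p_interaction=float(full.pvalues["allele_x_group"]),
        r2_base=float(base.rsquared),
        r2_full=float(full.rsquared),
        referent="men",
        comparison=comparison_group,
        n=int(keep.sum()),
    )
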