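"""End-to-end orchestration of the variance-QTL analysis.

A :class:`PipelineConfig` either names simulation presets (the five
study-like cohorts with a chosen genetic scenario) or points at phenotype /
dosage files. :func:`run_pipeline` then applies exclusions, runs the
per-cohort mean and variance tests, pools them with the heterogeneity-gated
meta-analysis, runs the stratified tests and the interaction models, and
writes every table as TSV plus a plain-text log. Identical seed + config
give identical outputs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_dosages, read_phenotypes, write_phenotypes
from .meta_analysis import auto_meta
from .phenotype_prep import BLOM_OFFSET, make_variance_phenotype
from .strata import (
    mean_interaction_model,
    stratified_vqtl,
    variance_interaction_model,
)
from .synthetic_data import apply_exclusions, five_cohort_preset, simulate_preset
from .vqtl import run_vqtl

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``preset`` (kwargs forwarded to the five-cohort preset,
    e.g. ``{"interaction_pre": 0.013}``) or ``cohort_files`` (mapping of
    cohort name to ``{"phenotypes": path, "dosages": path}``) must be given.
    """

    preset: Mapping | None = None
    cohort_files: Mapping[str, Mapping[str, str]] | None = None
    variant: str | None = None  # dosage-matrix column; default: first column
    int_offset: float = BLOM_OFFSET
    residualize_first: bool = False
    het_threshold: float = 0.05
    min_stratum_n: int = 30
    seed: int = 0
    out_dir: str = "results/pipeline"

    def validate(self) -> None:
        if (self.preset is None) == (self.cohort_files is None):
            raise ValueError("config must set exactly one of preset / cohort_files")
        if not 0.0 < self.het_threshold < 1.0:
            raise ValueError("het_threshold must be in (0, 1)")
        if self.cohort_files is not None:
            for name, paths in self.cohort_files.items():
                for key in ("phenotypes", "dosages"):
                    if not os.path.exists(paths[key]):
                        raise ValueError(f"missing file for cohort {name}: {paths[key]}")


def load_config(path: str) -> PipelineConfig:
    """Load a PipelineConfig from a YAML (or JSON) key-value file."""
    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _load_cohorts(config: PipelineConfig, log: list[str]) -> dict[str, tuple[pd.DataFrame, np.ndarray]]:
    cohorts: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
    if config.preset is not None:
        configs = five_cohort_preset(seed=config.seed, **dict(config.preset))
        for name, table in simulate_preset(configs).items():
            cohorts[name] = (table, table["dosage"].to_numpy())
        log.append(f"simulated {len(cohorts)} cohorts from preset (seed={config.seed})")
    else:
        for name, paths in config.cohort_files.items():
            table = read_phenotypes(paths["phenotypes"])
            matrix = read_dosages(paths["dosages"], sample_ids=table["id"].tolist())
            column = config.variant or matrix.columns[0]
            cohorts[name] = (table, matrix[column].to_numpy(dtype=float))
            log.append(f"loaded cohort {name}: n={len(table)}, variant={column}")
    return cohorts


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis; returns the result tables and writes TSVs."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log: list[str] = [f"uratevar {__version__}", f"seed {config.seed}"]

    raw_cohorts = _load_cohorts(config, log)
    cohorts: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}
    for name, (table, dosage) in raw_cohorts.items():
        if config.preset is not None:
            write_phenotypes(table, os.path.join(config.out_dir, f"cohort_{name}.tsv"))
        table = table.reset_index(drop=True)
        kept, report = apply_exclusions(table, mode="main")
        dosage = np.asarray(dosage)[kept.index.to_numpy()]
        log.append(
            f"exclusions[{name}]: " + ", ".join(f"{k}={v}" for k, v in report.items())
            + f"; analysed {len(kept)}/{len(table)}"
        )
        cohorts[name] = (kept.reset_index(drop=True), dosage)

    # Per-cohort mean / variance tests.
    vqtl_rows = []
    per_effect = {"mean": [], "var_unadjusted": [], "var_adjusted": []}
    for name, (table, dosage) in cohorts.items():
        res = run_vqtl(table, dosage, offset=config.int_offset,
                       residualize_first=config.residualize_first)
        for effect, est in (("mean", res.mean),
                            ("var_unadjusted", res.var_unadjusted),
                            ("var_adjusted", res.var_adjusted)):
            vqtl_rows.append(dict(cohort=name, effect=effect, beta=est.beta,
                                  se=est.se, p=est.p, n=est.n, r2=est.r2))
            per_effect[effect].append(est)
    vqtl_table = pd.DataFrame(vqtl_rows)

    meta_rows = []
    for effect, ests in per_effect.items():
        meta = auto_meta(ests, het_threshold=config.het_threshold)
        log.append(f"meta[{effect}]: model={meta.model_used} (P_Het={meta.p_het:.3g})")
        meta_rows.append(dict(effect=effect, beta=meta.beta_pooled, se=meta.se_pooled,
                              p=meta.p_pooled, q=meta.q, df=meta.df, p_het=meta.p_het,
                              tau2=meta.tau2, model=meta.model_used, k=meta.k))
    meta_table = pd.DataFrame(meta_rows)

    # Stratified variance tests (menopause exclusions applied internally).
    strata_table, pooled = stratified_vqtl(
        cohorts, min_n=config.min_stratum_n, offset=config.int_offset,
        het_threshold=config.het_threshold,
    )
    strata_meta_rows = []
    for group, meta in pooled.items():
        if meta is None:
            continue
        log.append(f"meta[strata:{group}]: model={meta.model_used} (P_Het={meta.p_het:.3g})")
        strata_meta_rows.append(dict(group=group, beta=meta.beta_pooled,
                                     se=meta.se_pooled, p=meta.p_pooled, q=meta.q,
                                     p_het=meta.p_het, tau2=meta.tau2,
                                     model=meta.model_used, k=meta.k))
    strata_meta = pd.DataFrame(strata_meta_rows)

    # Pooled interaction models on the menopause-analysis sample.
    frames, dose_parts = [], []
    for name, (table, dosage) in cohorts.items():
        sub, _ = apply_exclusions(table, mode="menopause_strata")
        dose_parts.append(np.asarray(dosage)[sub.index.to_numpy()])
        frames.append(sub.reset_index(drop=True))
    pooled_table = pd.concat(frames, ignore_index=True)
    pooled_dosage = np.concatenate(dose_parts)
    vp_adj = make_variance_phenotype(
        pooled_table, adjust_for_genotype=True, variant_dosage=pooled_dosage,
        offset=config.int_offset, residualize_first=config.residualize_first,
    )
    groups = np.where(pooled_table["sex"] == "male", "men",
                      pooled_table["menopause"].to_numpy())
    inter_rows = []
    for comparison in ("pre", "post"):
        if (groups == comparison).sum() < config.min_stratum_n:
            continue
        mean_ir, _cells = mean_interaction_model(pooled_table, pooled_dosage, comparison)
        var_ir = variance_interaction_model(
            vp_adj, pooled_dosage, groups, comparison,
            cohorts=pooled_table["cohort"].to_numpy(),
        )
        for model, ir in (("mean", mean_ir), ("variance", var_ir)):
            inter_rows.append(dict(model=model, comparison=ir.comparison,
                                   beta_interaction=ir.beta_interaction, se=ir.se,
                                   p=ir.p_interaction, r2_base=ir.r2_base,
                                   r2_full=ir.r2_full, n=ir.n))
    inter_table = pd.DataFrame(inter_rows)

    results = {
        "vqtl_per_cohort": vqtl_table,
        "meta_combined": meta_table,
        "strata_per_cohort": strata_table,
        "strata_combined": strata_meta,
        "interactions": inter_table,
    }
    for name, frame in results.items():
        frame.to_csv(os.path.join(config.out_dir, f"{name}.tsv"), sep="\t",
                     index=False, na_rep="NA", float_format="%.6g")
    with open(os.path.join(config.out_dir, "log.txt"), "wt", encoding="utf-8") as fh:
        fh.write("\n".join(log) + "\n")
    return results
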