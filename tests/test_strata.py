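import numpy as np
import pandas as pd
import pytest

from conftest import build_table
from uratevar import published
from uratevar.phenotype_prep import make_variance_phenotype
from uratevar.strata import (
    genotype_group_means,
    mean_interaction_model,
    stratified_vqtl,
    stratify,
    tt_minus_gg_contrast,
    variance_interaction_model,
)
from uratevar.synthetic_data import (
    CohortConfig,
    apply_exclusions,
    simulate_cohort,
)


def _interaction_cohort(seed, n=6000, pre=0.013, post=0.012, disp=None):
    cfg = CohortConfig(
        cohort_name="sim", n=n, effect_allele_freq=0.77, mean_intercept=0.2,
        interaction_pre=pre, interaction_post=post,
        log_sigma_per_allele_by_group=dict(disp or {}),
        frac_female=0.5, frac_postmeno_of_women=0.3, seed=seed,
    )
    table = simulate_cohort(cfg)
    table, _ = apply_exclusions(table.reset_index(drop=True), mode="menopause_strata")
    return table.reset_index(drop=True), table["dosage"].to_numpy()


class TestStratify:
    def test_counts_by_hand(self):
        table = build_table(
            10,
            sex=["female"] * 6 + ["male"] * 4,
            menopause=["pre", "pre", "post", "post", "post", "unknown"] + ["NA"] * 4,
        )
        parts = stratify(table)
        assert len(parts["men"]) == 4
        assert len(parts["pre"]) == 2
        assert len(parts["post"]) == 3

    def test_all_male_cohort(self):
        table = build_table(5, sex=["male"] * 5)
        parts = stratify(table)
        assert len(parts["men"]) == 5
        assert len(parts["pre"]) == 0 and len(parts["post"]) == 0

    def test_partitions_disjoint_and_exclude_unknown(self):
        table = build_table(200, seed=1)
        table.loc[table.index[:5], "menopause"] = np.where(
            table["sex"].iloc[:5] == "female", "unknown", "NA"
        )
        parts = stratify(table)
        ids = pd.concat([p["id"] for p in parts.values()])
        assert ids.is_unique
        unknown_women = table[(table["sex"] == "female") & (table["menopause"] == "unknown")]
        assert not ids.isin(unknown_women["id"]).any()


class TestStratifiedVqtl:
    def test_empty_pre_partition_tolerated(self):
        """A cohort with no pre-menopausal women yields a missing-estimate
        row, not an error."""
        cfg = CohortConfig(cohort_name="elder", n=1500, effect_allele_freq=0.77,
                           mean_intercept=0.25, frac_female=0.6,
                           frac_postmeno_of_women=1.0, seed=2)
        table = simulate_cohort(cfg)
        per, pooled = stratified_vqtl({"elder": (table, table["dosage"].to_numpy())})
        pre_row = per[per["group"] == "pre"].iloc[0]
        assert np.isnan(pre_row["beta"])
        assert pooled["pre"] is None
        assert pooled["men"] is not None

    def test_dispersion_in_pre_only_detected(self):
        """A pre-menopausal-only dispersion effect shows up in the pre pooled
        beta and not in men."""
        pre_betas, men_betas = [], []
        for seed in range(5):
            table, dosage = _interaction_cohort(
                100 + seed, n=12_000, pre=0.0, post=0.0,
                disp={"men": 0.0, "pre": 0.3, "post": 0.0},
            )
            _, pooled = stratified_vqtl({"sim": (table, dosage)})
            pre_betas.append(pooled["pre"].beta_pooled)
            men_betas.append(pooled["men"].beta_pooled)
        assert sum(b > 0 for b in pre_betas) >= 4
        assert abs(np.mean(men_betas)) < 0.05

    def test_group_homogeneous_betas_agree(self):
        table, dosage = _interaction_cohort(
            7, n=12_000, pre=0.0, post=0.0,
            disp={"men": 0.15, "pre": 0.15, "post": 0.15},
        )
        _, pooled = stratified_vqtl({"sim": (table, dosage)})
        betas = {g: pooled[g] for g in ("men", "pre", "post")}
        for a in betas.values():
            for b in betas.values():
                delta = abs(a.beta_pooled - b.beta_pooled)
                assert delta < 2.5 * np.hypot(a.se_pooled, b.se_pooled)


class TestMeanInteraction:
    def test_recovers_simulated_interaction(self):
        betas = []
        for seed in range(10):
            table, dosage = _interaction_cohort(200 + seed)
            result, _ = mean_interaction_model(table, dosage, "pre")
            betas.append(result.beta_interaction)
        assert np.mean(betas) == pytest.approx(0.013, abs=0.004)

    def test_null_interaction_near_zero(self):
        betas = []
        for seed in range(10):
            table, dosage = _interaction_cohort(300 + seed, pre=0.0, post=0.0)
            result, _ = mean_interaction_model(table, dosage, "pre")
            betas.append(result.beta_interaction)
        assert abs(np.mean(betas)) < 0.003

    def test_swapping_referent_negates_beta(self):
        """Relabelling the two groups flips the interaction coefficient."""
        table, dosage = _interaction_cohort(55)
        result, _ = mean_interaction_model(table, dosage, "pre")
        swapped = table.copy()
        men = swapped["sex"] == "male"
        pre = (swapped["sex"] == "female") & (swapped["menopause"] == "pre")
        swapped.loc[men, ["sex", "menopause"]] = ["female", "pre"]
        swapped.loc[pre, ["sex", "menopause"]] = ["male", "NA"]
        result_swapped, _ = mean_interaction_model(swapped, dosage, "pre")
        assert result_swapped.beta_interaction == pytest.approx(
            -result.beta_interaction, abs=1e-9
        )

    def test_r2_increases_with_interaction_term(self):
        table, dosage = _interaction_cohort(66)
        result, _ = mean_interaction_model(table, dosage, "pre")
        assert result.r2_full >= result.r2_base

    def test_monomorphic_group_rejected(self):
        table, dosage = _interaction_cohort(77, n=2000)
        dosage = dosage.copy()
        pre = ((table["sex"] == "female") & (table["menopause"] == "pre")).to_numpy()
        dosage[pre] = 2.0
        with pytest.raises(ValueError, match="monomorphic"):
            mean_interaction_model(table, dosage, "pre")


class TestGenotypeGroupMeans:
    def test_reference_cell_zero_and_contrast(self):
        table, dosage = _interaction_cohort(88)
        cells = genotype_group_means(table, dosage)
        assert cells.betas[("men", 0)] == 0.0
        contrast = tt_minus_gg_contrast(cells, "pre")
        assert contrast == pytest.approx(
            cells.betas[("pre", 2)] - cells.betas[("pre", 0)], abs=1e-12
        )

    def test_contrast_on_published_cells(self):
        """Published per-cell betas give the reported TT-GG gaps per group."""
        assert tt_minus_gg_contrast(published.GENOTYPE_GROUP_CELLS, "pre") == pytest.approx(0.075)
        assert tt_minus_gg_contrast(published.GENOTYPE_GROUP_CELLS, "post") == pytest.approx(0.065)
        assert tt_minus_gg_contrast(published.GENOTYPE_GROUP_CELLS, "men") == pytest.approx(0.038)

    def test_cell_means_agree_with_saturated_interaction_model(self):
        """With a binary variant the additive+interaction model spans the
        same cell structure: fitted values coincide."""
        import statsmodels.api as sm

        table, dosage = _interaction_cohort(91, n=3000)
        dosage = (dosage > 1).astype(float)  # binary carrier coding
        parts = stratify(table)
        sub = pd.concat([parts["men"], parts["pre"]])
        loc = table.index.get_indexer(sub.index.to_numpy())
        d = dosage[loc]
        is_pre = np.concatenate([np.zeros(len(parts["men"])), np.ones(len(parts["pre"]))])
        covs = np.column_stack([sub["age"], sub["bmi"]])
        X_add = sm.add_constant(np.column_stack([covs, d, is_pre, d * is_pre]))
        X_cell = sm.add_constant(np.column_stack(
            [covs] + [((d == a) & (is_pre == g)).astype(float)
                      for a, g in ((1, 0), (0, 1), (1, 1))]
        ))
        y = sub["urate"].to_numpy()
        fitted_add = sm.OLS(y, X_add).fit().fittedvalues
        fitted_cell = sm.OLS(y, X_cell).fit().fittedvalues
        np.testing.assert_allclose(fitted_add, fitted_cell, atol=1e-8)


class TestVarianceInteraction:
    def _vp_and_groups(self, table, dosage):
        vp = make_variance_phenotype(table, adjust_for_genotype=True,
                                     variant_dosage=dosage)
        groups = np.where(table["sex"] == "male", "men", table["menopause"].to_numpy())
        return vp, groups

    def test_detects_pre_specific_dispersion(self):
        table, dosage = _interaction_cohort(
            111, n=10_000, pre=0.0, post=0.0,
            disp={"men": 0.0, "pre": 0.3, "post": 0.0},
        )
        vp, groups = self._vp_and_groups(table, dosage)
        result = variance_interaction_model(vp, dosage, groups, "pre")
        assert result.beta_interaction > 0
        assert result.p_interaction < 0.05
        assert result.r2_full >= result.r2_base

    def test_null_r2_increment_negligible(self):
        increments = []
        for seed in range(8):
            table, dosage = _interaction_cohort(500 + seed, n=4000, pre=0.0, post=0.0)
            vp, groups = self._vp_and_groups(table, dosage)
            result = variance_interaction_model(vp, dosage, groups, "pre")
            increments.append(result.r2_full - result.r2_base)
        assert np.median(increments) < 1e-3

    def test_requires_adjusted_phenotype(self):
        table, dosage = _interaction_cohort(120, n=1500)
        vp = make_variance_phenotype(table)
        groups = np.where(table["sex"] == "male", "men", table["menopause"].to_numpy())
        with pytest.raises(ValueError, match="adjusted"):
            variance_interaction_model(vp, dosage, groups, "pre")
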