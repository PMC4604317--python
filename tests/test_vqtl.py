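import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from conftest import build_table
from uratevar.phenotype_prep import VariancePhenotype, make_variance_phenotype
from uratevar.synthetic_data import CohortConfig, simulate_cohort, simulate_region
from uratevar.vqtl import (
    mean_effect_test,
    region_scan,
    run_vqtl,
    variance_effect_test,
)


def _vp_from_z2(z2):
    z2 = np.asarray(z2, dtype=float)
    data = pd.DataFrame({"id": [f"i{k}" for k in range(len(z2))],
                         "stratum": "toy:male",
                         "residual": 0.0, "z": np.sqrt(z2), "z2": z2})
    return VariancePhenotype(data=data, adjusted=False)


class TestMeanEffectTest:
    def test_matches_normal_equations_oracle(self):
        """Dosage beta equals the closed-form (XᵀX)⁻¹Xᵀy coefficient."""
        rng = np.random.default_rng(8)
        n = 40
        table = build_table(n, seed=8)
        dosage = rng.binomial(2, 0.6, n).astype(float)
        est = mean_effect_test(table, dosage)
        female = (table["sex"] == "female").astype(float)
        X = np.column_stack([np.ones(n), dosage, table["age"], table["bmi"],
                             table["pc1"], table["pc2"], female])
        beta = np.linalg.solve(X.T @ X, X.T @ table["urate"].to_numpy())
        assert est.beta == pytest.approx(beta[1], abs=1e-10)
        # SE and p from the standard OLS formulas
        resid = table["urate"].to_numpy() - X @ beta
        df = n - X.shape[1]
        cov = np.linalg.inv(X.T @ X) * (resid @ resid / df)
        se = np.sqrt(cov[1, 1])
        assert est.se == pytest.approx(se, abs=1e-10)
        assert est.p == pytest.approx(2 * stats.t.sf(abs(beta[1] / se), df), abs=1e-10)

    def test_monomorphic_rejected(self):
        table = build_table(50)
        with pytest.raises(ValueError, match="monomorphic"):
            mean_effect_test(table, np.full(50, 2.0))

    def test_too_small_sample_rejected(self):
        table = build_table(20)
        with pytest.raises(ValueError, match="30"):
            mean_effect_test(table, np.random.default_rng(0).binomial(2, 0.5, 20).astype(float))

    def test_covariate_rescaling_leaves_dosage_beta(self):
        """Age in decades instead of years must not move the dosage beta."""
        table = build_table(500, seed=13)
        dosage = np.random.default_rng(14).binomial(2, 0.7, 500).astype(float)
        est_years = mean_effect_test(table, dosage)
        rescaled = table.copy()
        rescaled["age"] = rescaled["age"] / 10.0
        est_decades = mean_effect_test(rescaled, dosage)
        assert est_years.beta == pytest.approx(est_decades.beta, abs=1e-10)
        assert est_years.p == pytest.approx(est_decades.p, abs=1e-10)


class TestVarianceEffectTest:
    def test_six_row_closed_form_slope(self):
        z2 = [0.2, 1.4, 0.9, 2.0, 0.1, 1.1]
        dosage = np.array([0.0, 1, 1, 2, 0, 2])
        est = variance_effect_test(_vp_from_z2(z2), dosage)
        x = dosage - dosage.mean()
        y = np.asarray(z2) - np.mean(z2)
        assert est.beta == pytest.approx(float(x @ y / (x @ x)), abs=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(21)
        z2 = rng.chisquare(1, 300)
        dosage = rng.binomial(2, 0.6, 300).astype(float)
        est = variance_effect_test(_vp_from_z2(z2), dosage)
        fit = sm.OLS(z2, sm.add_constant(dosage)).fit()
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert est.p == pytest.approx(fit.pvalues[1], abs=1e-10)
        assert est.r2 == pytest.approx(fit.rsquared, abs=1e-10)

    def test_z2_supplied_or_recomputed_identical(self):
        table = build_table(200, seed=5)
        vp = make_variance_phenotype(table)
        dosage = np.random.default_rng(6).binomial(2, 0.7, 200).astype(float)
        est1 = variance_effect_test(vp, dosage)
        vp2 = VariancePhenotype(data=vp.data.assign(z2=vp.z**2), adjusted=False)
        est2 = variance_effect_test(vp2, dosage)
        assert est1.beta == est2.beta and est1.p == est2.p

    def test_null_pvalues_uniform(self):
        """Under the global null the variance-test p-values are uniform."""
        ps = []
        for seed in range(300):
            rng = np.random.default_rng(1000 + seed)
            z2 = rng.chisquare(1, 400)
            dosage = rng.binomial(2, 0.77, 400).astype(float)
            ps.append(variance_effect_test(_vp_from_z2(z2), dosage).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_dispersion_power(self):
        """A +0.15 log-SD-per-allele effect is detected with positive sign."""
        positives = 0
        for seed in range(10):
            cfg = CohortConfig(cohort_name="c", n=3000, effect_allele_freq=0.77,
                               mean_intercept=0.2, beta_allele=0.0,
                               log_sigma_per_allele_by_group={"men": 0.15, "pre": 0.15, "post": 0.15},
                               seed=700 + seed)
            table = simulate_cohort(cfg)
            dosage = table["dosage"].to_numpy()
            vp = make_variance_phenotype(table, adjust_for_genotype=True,
                                         variant_dosage=dosage)
            positives += variance_effect_test(vp, dosage).beta > 0
        assert positives >= 9


class TestRunVqtl:
    def test_pure_mean_effect_sign_pattern(self):
        """Major effect allele, mean effect only: the unadjusted variance
        beta is systematically negative while the adjusted one sits at
        zero (averaged over replicates to beat sampling noise)."""
        unadj, adj_z = [], []
        for seed in (99, 100, 101, 102):
            cfg = CohortConfig(cohort_name="c", n=30_000, effect_allele_freq=0.77,
                               mean_intercept=0.2, beta_allele=0.024, seed=seed)
            table = simulate_cohort(cfg)
            res = run_vqtl(table, table["dosage"].to_numpy())
            unadj.append(res.var_unadjusted.beta)
            adj_z.append(res.var_adjusted.beta / res.var_adjusted.se)
            assert res.mean.beta == pytest.approx(0.024, abs=3 * res.mean.se)
        assert np.mean(unadj) < 0
        assert sum(b < 0 for b in unadj) >= 3
        assert abs(np.mean(adj_z)) < 2.0

    def test_pure_dispersion_pattern(self):
        cfg = CohortConfig(cohort_name="c", n=20_000, effect_allele_freq=0.77,
                           mean_intercept=0.2, beta_allele=0.0,
                           log_sigma_per_allele_by_group={"men": 0.2, "pre": 0.2, "post": 0.2},
                           seed=17)
        table = simulate_cohort(cfg)
        res = run_vqtl(table, table["dosage"].to_numpy())
        assert abs(res.mean.beta) < 3 * res.mean.se
        assert res.var_unadjusted.beta > 0
        assert res.var_adjusted.beta > 0


class TestRegionScan:
    def test_single_variant_matches_variance_test(self):
        table = build_table(200, seed=31)
        dosage = np.random.default_rng(32).binomial(2, 0.6, 200).astype(float)
        matrix = pd.DataFrame({"snp1": dosage})
        scan = region_scan(table, matrix)
        vp = make_variance_phenotype(table)
        est = variance_effect_test(vp, dosage)
        assert scan.loc[0, "beta"] == pytest.approx(est.beta, abs=1e-12)
        assert scan.loc[0, "p"] == pytest.approx(est.p, abs=1e-12)

    def test_causal_variant_attains_minimum_p(self):
        """The causal dispersion variant wins the scan in most seeds."""
        wins = 0
        for seed in range(6):
            cfg = CohortConfig(cohort_name="c", n=5000, effect_allele_freq=0.6,
                               mean_intercept=0.2, beta_allele=0.0,
                               log_sigma_per_allele_by_group={"men": 0.25, "pre": 0.25, "post": 0.25},
                               seed=400 + seed)
            table, matrix = simulate_region(5, 0.5, 2, cfg)
            scan = region_scan(table, matrix, mode="adjusted")
            wins += scan.loc[scan["p"].idxmin(), "variant"] == "snp0003"
        assert wins >= 4

    def test_all_monomorphic_yields_empty_result_with_warnings(self):
        table = build_table(100, seed=41)
        matrix = pd.DataFrame({"snp1": np.zeros(100), "snp2": np.full(100, 2.0)})
        with pytest.warns(UserWarning, match="monomorphic"):
            scan = region_scan(table, matrix)
        assert len(scan) == 0
        assert scan.attrs["skipped_monomorphic"] == ["snp1", "snp2"]

    def test_unknown_mode_rejected(self):
        table = build_table(100)
        matrix = pd.DataFrame({"snp1": np.random.default_rng(0).binomial(2, 0.5, 100)})
        with pytest.raises(ValueError, match="mode"):
            region_scan(table, matrix, mode="bogus")
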