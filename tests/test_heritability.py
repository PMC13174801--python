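"""Burden heritability: scores, regression recovery, liability transform, partition."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from rvburden import bhr_regression, burden_scores, liability_transform, partition_h2
from rvburden.errors import ConfigurationError, EstimationError
from rvburden.heritability import burden_summary_stats


from conftest import summary_sim


class TestBurdenScores:
    def _vt(self, rows):
        return pd.DataFrame(
            [{"variant_id": f"v{i}", "gene": g, "consequence": c, "maf_max": f,
              "revel_damaging": dmg, "am_damaging": False,
              "pai3d_damaging": False, "popeve_damaging": False}
             for i, (g, c, f, dmg) in enumerate(rows)]
        )

    def test_single_variant_definition(self):
        out = burden_scores(self._vt([("G", "PTV", 1e-5, False)]))
        assert len(out) == 1
        assert out["gamma"].iloc[0] == pytest.approx(2e-5 * (1 - 1e-5))
        assert out["bin"].iloc[0] == "ultrarare.PTV"

    def test_gamma_additivity(self):
        one = burden_scores(self._vt([("G", "PTV", 8e-6, False)]))
        two = burden_scores(self._vt([("G", "PTV", 8e-6, False), ("G", "PTV", 8e-6, False)]))
        assert two["gamma"].iloc[0] == pytest.approx(2 * one["gamma"].iloc[0])

    def test_frequency_exclusion_and_binning(self):
        out = burden_scores(self._vt([
            ("G", "PTV", 5e-6, False),        # ultrarare
            ("G", "PTV", 5e-5, False),        # rare
            ("G", "PTV", 5e-4, False),        # excluded (> 1e-4)
            ("G", "missense", 5e-6, True),    # damaging missense
            ("G", "missense", 5e-6, False),   # non-damaging missense
            ("G", "synonymous", 5e-6, False),
        ]))
        assert set(out["bin"]) == {
            "ultrarare.PTV", "rare.PTV", "ultrarare.damaging_missense",
            "ultrarare.nondamaging_missense", "ultrarare.synonymous"}

    def test_gamma_matches_empirical_burden_variance(self):
        """Simulation oracle: gamma equals the variance of the allele-sum burden."""
        from rvburden import SimulationConfig, StudySpec, simulate_cohort

        config = SimulationConfig(
            n_genes=30, variants_per_gene=12.0, freq_range=(1e-5, 1e-4),
            studies=(StudySpec(2000, 38_000),), seed=3)
        study = simulate_cohort(config, 0)
        vt = study.variant_table
        scores = burden_scores(vt, freq_column="true_freq")
        idx = study.variant_index
        checked = 0
        for _, row in scores.iterrows():
            if row["gamma"] < 5e-5:
                continue
            sel = vt.loc[(vt["gene"] == row["gene"]), :]
            from rvburden.heritability import _annotation_bin
            ann = _annotation_bin(sel)
            fb = np.where(sel["true_freq"] <= 1e-5, "ultrarare", "rare")
            vids = sel.loc[[f"{f}.{a}" == row["bin"] for f, a in zip(fb, ann)], "variant_id"]
            g = np.asarray(study.genotypes[:, idx.get_indexer(vids)].sum(axis=1)).ravel()
            emp_var = g.var()
            # for rare counts the variance of the sample variance is fourth-
            # moment driven: Var(s^2) ~ E[(g-mu)^4]/n ~ gamma/n
            mc_se = math.sqrt(2.0 * row["gamma"] / study.n_samples)
            assert abs(emp_var - row["gamma"]) < 3 * mc_se
            checked += 1
        assert checked >= 3


class TestBhrRegression:
    def test_null_recovery(self):
        tab = summary_sim(h2=0.0, frac_causal=0.0, seed=1)
        est = bhr_regression(tab)
        assert abs(est.h2_obs) < 2 * est.se

    def test_planted_h2_recovered(self):
        tab = summary_sim(h2=0.02, seed=2)
        est = bhr_regression(tab)
        assert abs(est.h2_obs - 0.02) < 2 * est.se
        assert est.se < 0.02  # informative fit

    def test_scale_equivariance(self):
        t1 = summary_sim(h2=0.01, seed=4)
        t2 = t1.copy()
        t2["alpha_hat"] *= 2.0  # doubling effects quadruples h2
        e1, e2 = bhr_regression(t1), bhr_regression(t2)
        assert e2.h2_obs == pytest.approx(4 * e1.h2_obs, rel=0.25)

    def test_fixed_genes_contribution_added_back(self):
        tab = summary_sim(h2=0.02, seed=5, concentrated_gene=("G7", 0.5))
        est = bhr_regression(tab, fixed_genes=("G7",))
        assert "G7" in est.fixed_genes
        assert abs(est.h2_obs - 0.02) < 2.5 * est.se

    def test_point_estimate_invariant_to_gene_order(self):
        tab = summary_sim(h2=0.02, seed=6)
        est = bhr_regression(tab)
        shuffled = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        est2 = bhr_regression(shuffled)
        assert est2.h2_obs == pytest.approx(est.h2_obs, rel=1e-9)

    def test_too_few_genes_rejected(self):
        with pytest.raises(EstimationError):
            bhr_regression(summary_sim(n_genes=20, seed=7))

    def test_jackknife_se_shrinks_with_gene_count(self):
        ses = [bhr_regression(summary_sim(n_genes=n, h2=0.02, seed=8)).se
               for n in (500, 2000, 8000)]
        assert ses[0] > ses[1] > ses[2]


class TestLiabilityTransform:
    def test_zero_maps_to_zero(self):
        assert liability_transform(0.0, 0.05, 0.3) == 0.0

    def test_population_sample_closed_form(self):
        K = 0.05
        z = norm.pdf(norm.isf(K))
        expected = 0.01 * K * (1 - K) / z**2
        assert liability_transform(0.01, K) == pytest.approx(expected, rel=1e-12)

    def test_general_formula_reduces_at_p_equals_k(self):
        K = 0.0530  # EUR-ancestry population prevalence used in practice
        assert liability_transform(0.01, K, K) == pytest.approx(liability_transform(0.01, K))
        K2 = 0.0217  # AFR-ancestry population prevalence
        assert liability_transform(0.01, K2) > liability_transform(0.01, K)

    def test_monotone_in_h2(self):
        vals = [liability_transform(h, 0.05, 0.3) for h in (0.0, 0.01, 0.02)]
        assert vals == sorted(vals)

    def test_boundary_prevalence_rejected(self):
        with pytest.raises(ConfigurationError):
            liability_transform(0.01, 0.0)
        with pytest.raises(ConfigurationError):
            liability_transform(0.01, 0.05, 1.0)


class TestPartition:
    def test_full_gene_set_accounts_for_everything(self):
        tab = summary_sim(h2=0.02, seed=9)
        est = bhr_regression(tab)
        frac = partition_h2(est, {"all": list(tab["gene"])})
        assert frac["all"] == pytest.approx(1.0, abs=1e-9)

    def test_empty_set_is_zero(self):
        est = bhr_regression(summary_sim(h2=0.02, seed=10))
        assert partition_h2(est, {"none": []})["none"] == 0.0

    def test_concentrated_gene_recovers_its_share(self):
        tab = summary_sim(h2=0.02, seed=11, concentrated_gene=("G7", 0.5))
        est = bhr_regression(tab, fixed_genes=("G7",))
        frac = partition_h2(est, {"top": ["G7"]})["top"]
        assert frac == pytest.approx(0.5, abs=0.15)


class TestSummaryStatsFromStudy:
    def test_alpha_se_scale_and_cmac_filter(self):
        from rvburden import SimulationConfig, StudySpec, simulate_cohort

        config = SimulationConfig(
            n_genes=40, variants_per_gene=10.0, freq_range=(1e-5, 1e-4),
            studies=(StudySpec(1000, 19_000),), seed=12)
        study = simulate_cohort(config, 0)
        table = burden_summary_stats(study, min_cmac=20).table
        assert (table["cmac"] >= 20).all()
        assert np.allclose(table["se"], 1 / math.sqrt(study.n_samples))
        # null phenotype: standardised effects are noise of order se
        assert np.abs(table["alpha_hat"]).max() < 6 / math.sqrt(study.n_samples)
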