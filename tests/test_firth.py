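"""Firth burden tests: oracle equivalence, separation, shrinkage, calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit

from rvburden import firth_logistic, run_study_scan
from rvburden.errors import DegeneratePredictorError


def two_by_two(case_car, ctrl_car, case_non, ctrl_non):
    """Phenotype/burden vectors for a 2x2 carrier table."""
    y = np.concatenate([
        np.ones(case_car), np.zeros(ctrl_car), np.ones(case_non), np.zeros(ctrl_non)])
    b = np.concatenate([
        np.ones(case_car + ctrl_car), np.zeros(case_non + ctrl_non)])
    return b, y


def penalized_loglik_2x2(b0, b1, table):
    """Independent penalized log-likelihood for a 2x2, written from scratch."""
    a, b, c, d = table  # cases/controls among carriers; cases/controls among non-carriers
    eta1, eta0 = b0 + b1, b0
    p1, p0 = expit(eta1), expit(eta0)
    ll = a * math.log(p1) + b * math.log(1 - p1) + c * math.log(p0) + d * math.log(1 - p0)
    w1 = (a + b) * p1 * (1 - p1)
    w0 = (c + d) * p0 * (1 - p0)
    # X = [[1,1],[1,0]] blocks: I = [[w1+w0, w1],[w1, w1]]
    det = w1 * w0
    return ll + 0.5 * math.log(det)


def grid_search_firth_2x2(table, lo=-6.0, hi=6.0):
    """Profile grid search oracle for the penalized MLE of beta_burden."""
    def profile(b1):
        res = minimize_scalar(
            lambda b0: -penalized_loglik_2x2(b0, b1, table),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-12},
        )
        return -res.fun

    grid = np.linspace(lo, hi, 2401)
    vals = np.array([profile(b) for b in grid])
    k = int(np.argmax(vals))
    fine = np.linspace(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)], 2001)
    vals_f = np.array([profile(b) for b in fine])
    return float(fine[np.argmax(vals_f)])


class TestFirthOracles:
    def test_balanced_null_gives_zero_beta(self):
        b, y = two_by_two(5, 5, 995, 995)
        res = firth_logistic(b, y, mode="exact")
        assert res.beta == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_exact_mode_matches_grid_search(self):
        table = (8, 2, 492, 498)
        b, y = two_by_two(*table)
        res = firth_logistic(b, y, mode="exact")
        oracle = grid_search_firth_2x2(table)
        assert res.beta == pytest.approx(oracle, abs=1e-4)

    def test_exact_mode_matches_half_cell_correction(self):
        # on a 2x2 the Jeffreys-penalized MLE is the add-1/2 log odds ratio
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, bb, c, d = rng.integers(1, 40, 4)
            bvec, y = two_by_two(a, bb, c, d)
            res = firth_logistic(bvec, y, mode="exact")
            oracle = math.log(((a + 0.5) * (d + 0.5)) / ((bb + 0.5) * (c + 0.5)))
            assert res.beta == pytest.approx(oracle, abs=1e-6)

    def test_complete_separation_yields_finite_estimates(self):
        b, y = two_by_two(6, 0, 0, 994)
        res = firth_logistic(b, y, mode="exact")
        assert np.isfinite(res.beta) and np.isfinite(res.se)
        assert res.converged

    def test_firth_shrinks_toward_zero_relative_to_ml(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 50:
            a, bb, c, d = rng.integers(1, 30, 4)
            ml = math.log((a * d) / (bb * c))
            if ml == 0.0:
                continue
            bvec, y = two_by_two(a, bb, c, d)
            firth = firth_logistic(bvec, y, mode="exact").beta
            assert abs(firth) <= abs(ml) + 1e-9
            checked += 1

    def test_invariants_on_result(self):
        b, y = two_by_two(10, 4, 490, 496)
        res = firth_logistic(b, y, mode="exact")
        assert res.odds_ratio == pytest.approx(math.exp(res.beta))
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert 0 < res.p_value <= 1

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegeneratePredictorError):
            firth_logistic(np.zeros(10), np.r_[np.ones(5), np.zeros(5)])
        with pytest.raises(DegeneratePredictorError):
            firth_logistic(np.r_[np.ones(5), np.zeros(5)], np.ones(10))


class TestApproximateMode:
    def test_agrees_with_exact_on_well_behaved_fixture(self):
        rng = np.random.default_rng(2)
        n = 4000
        C = rng.normal(size=(n, 2))
        eta = -1.5 + 0.3 * C[:, 0] - 0.2 * C[:, 1]
        y = (rng.random(n) < expit(eta)).astype(float)
        carriers = rng.random(n) < 0.02  # ~80 carriers
        y[carriers] = (rng.random(carriers.sum()) < expit(eta[carriers] + 0.8)).astype(float)
        exact = firth_logistic(carriers.astype(float), y, covariates=C, mode="exact")
        approx = firth_logistic(carriers.astype(float), y, covariates=C, mode="approximate")
        assert approx.beta == pytest.approx(exact.beta, rel=0.05)

    def test_fast_path_matches_general_path(self):
        rng = np.random.default_rng(3)
        n = 2000
        y = (rng.random(n) < 0.1).astype(float)
        carriers = rng.random(n) < 0.01
        y[carriers] = (rng.random(carriers.sum()) < 0.3).astype(float)
        offset = np.full(n, math.log(0.1 / 0.9))
        from rvburden.firth import _firth_burden_fast, _fit_pair
        b1, pllf, pll0, conv, _ = _firth_burden_fast(carriers, y, offset)
        X = np.column_stack([np.ones(n), carriers.astype(float)])
        beta_full, pll_full, pll_null, conv_g, _ = _fit_pair(X, y, offset, 1)
        assert b1 == pytest.approx(beta_full[1], abs=1e-7)
        assert pllf == pytest.approx(pll_full, abs=1e-8)
        assert pll0 == pytest.approx(pll_null, abs=1e-8)


class TestStudyScan:
    def test_cmac_threshold_filters_results(self, small_cohort):
        _, studies = small_cohort
        from rvburden import add_maf_max, enumerate_masks_all_genes

        study = studies[0]
        masks = enumerate_masks_all_genes(add_maf_max(study.variant_table))
        res10 = run_study_scan(study, masks, cmac_min=10)
        res50 = run_study_scan(study, masks, cmac_min=50)
        assert (res10["cmac"] >= 10).all()
        assert (res50["cmac"] >= 50).all()
        assert len(res50) < len(res10)

    def test_null_scan_pvalues_are_uniform(self):
        """Type-I error control of the per-study Firth scan under the null.

        One mask per gene is tested so the p-values are independent (the
        nested/union masks of a gene share variants and would be strongly
        correlated).
        """
        from scipy.stats import kstest

        from rvburden import SimulationConfig, StudySpec, simulate_cohort
        from rvburden import add_maf_max, enumerate_masks_all_genes

        config = SimulationConfig(
            n_genes=2000, variants_per_gene=8.0, prevalence=0.10,
            freq_range=(1e-4, 1e-2),
            studies=(StudySpec(n_cases=400, n_referents=3600),), seed=31)
        study = simulate_cohort(config, 0)
        masks = enumerate_masks_all_genes(add_maf_max(study.variant_table))
        one_per_gene = [m for m in masks
                        if (m.annotation_group, m.freq_tier) == ("miss1of4", "RL")]
        res = run_study_scan(study, one_per_gene, cmac_min=10)
        assert len(res) > 800
        assert kstest(res["p_value"], "uniform").pvalue > 0.01
        alpha = 0.05
        rate = (res["p_value"] < alpha).mean()
        mc_se = math.sqrt(alpha * (1 - alpha) / len(res))
        assert abs(rate - alpha) < max(3 * mc_se, 0.02)
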