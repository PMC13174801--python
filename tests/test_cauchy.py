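"""Cauchy combination, layered gene tests, lambda90, sensitivity subsets."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import cauchy, chi2, kstest

from rvburden import cauchy_combine, lambda90, layered_gene_pvalue, sensitivity_recombine
from rvburden.cauchy import gene_level_results


def mask_frame(rows):
    """Rows: (annotation_group, freq_tier, p, cmac)."""
    return pd.DataFrame(
        [
            {"gene": "G", "stratum": "all", "annotation_group": g, "freq_tier": t,
             "p_ivw": p, "p_spa": np.nan, "cmac_total": c,
             "beta_meta": 0.1, "se_meta": 0.1, "n_studies": 2}
            for g, t, p, c in rows
        ]
    )


class TestCauchyCombine:
    def test_all_half_gives_half(self):
        assert cauchy_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-15)

    def test_single_p_identity(self):
        assert cauchy_combine([0.037]) == pytest.approx(0.037, abs=1e-12)

    def test_matches_independent_formula_evaluation(self):
        # high-precision independent evaluation of the tangent formula
        plist = [0.01, 0.2, 0.9]
        t = sum(math.tan((0.5 - p) * math.pi) for p in plist) / 3
        expected = 0.5 - math.atan(t) / math.pi
        assert cauchy_combine(plist) == pytest.approx(expected, abs=1e-12)

    def test_matches_cauchy_mixture_monte_carlo(self):
        # the combined statistic is standard Cauchy under independent uniforms;
        # cross-check the tail via the Cauchy survival function
        plist = [0.01, 0.2, 0.9]
        t = sum(math.tan((0.5 - p) * math.pi) for p in plist) / 3
        assert cauchy_combine(plist) == pytest.approx(float(cauchy.sf(t)), abs=1e-12)

    def test_tiny_p_uses_stable_tail(self):
        p = cauchy_combine([1e-300, 0.5])
        assert 0 < p < 1e-299 * 2 * math.pi

    def test_p_equal_one_is_clipped(self):
        assert 0 < cauchy_combine([1.0, 1.0]) <= 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])
        with pytest.raises(ValueError):
            cauchy_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            cauchy_combine([1.5])

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_max=False), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_permutation_and_duplication_invariance(self, plist):
        base = cauchy_combine(plist)
        assert cauchy_combine(list(reversed(plist))) == pytest.approx(base, rel=1e-9)
        assert cauchy_combine(plist + plist) == pytest.approx(base, rel=1e-9)

    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=6),
        st.integers(min_value=0, max_value=5),
        st.floats(min_value=0.1, max_value=0.9),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_each_component(self, plist, idx, factor):
        idx = idx % len(plist)
        smaller = list(plist)
        smaller[idx] = plist[idx] * factor
        assert cauchy_combine(smaller) <= cauchy_combine(plist) + 1e-12

    def test_combined_uniforms_are_uniform(self):
        """ACAT exactness: combining independent uniforms is uniform."""
        rng = np.random.default_rng(5)
        p = rng.uniform(size=(100_000, 5))
        t = np.tan((0.5 - p) * np.pi).mean(axis=1)
        combined = 0.5 - np.arctan(t) / np.pi
        assert kstest(combined, "uniform").pvalue > 0.01
        # same path through the public function on a subsample
        sub = np.array([cauchy_combine(row) for row in p[:2000]])
        assert kstest(sub, "uniform").pvalue > 0.01


class TestLayered:
    def test_single_layer_passthrough(self):
        gr = layered_gene_pvalue(mask_frame([("PTV", "UR", 0.01, 30), ("PTVnoflag", "UR", 0.02, 25)]))
        assert set(gr.layers) == {"PTV"}
        assert gr.p_final == pytest.approx(gr.layers["PTV"].p_layer)

    def test_all_half_stays_half(self):
        gr = layered_gene_pvalue(mask_frame(
            [("PTV", "UR", 0.5, 30), ("missREVEL", "R", 0.5, 40), ("PTV+missAM", "RL", 0.5, 50)]))
        assert gr.p_final == pytest.approx(0.5, abs=1e-12)

    def test_matches_manual_two_layer_combination(self):
        rows = [
            ("missREVEL", "UR", 0.02, 30), ("missAM", "R", 0.15, 40),
            ("PTV", "UR", 0.001, 20), ("PTVnoflag", "R", 0.004, 25),
            ("PTV+missREVEL", "UR", 0.003, 45), ("PTV+missAM", "R", 0.2, 55),
        ]
        gr = layered_gene_pvalue(mask_frame(rows))
        p_mis = cauchy_combine([0.02, 0.15])
        p_ptv = cauchy_combine([0.001, 0.004])
        p_both = cauchy_combine([0.003, 0.2])
        assert gr.p_final == pytest.approx(cauchy_combine([p_mis, p_ptv, p_both]), abs=1e-14)
        assert gr.layers["missense"].n_masks_combined == 2

    def test_best_mask_selection_with_ties(self):
        rows = [("PTV", "UR", 0.01, 30), ("PTVnoflag", "UR", 0.01, 50), ("missAM", "R", 0.5, 10)]
        gr = layered_gene_pvalue(mask_frame(rows))
        assert gr.best_mask == "PTVnoflag.UR"  # tie on p -> larger cmac wins
        assert gr.best_cmac == 50

    def test_spa_p_preferred_when_present(self):
        df = mask_frame([("PTV", "UR", 0.01, 30)])
        df.loc[0, "p_spa"] = 0.04
        gr = layered_gene_pvalue(df)
        assert gr.p_final == pytest.approx(0.04)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            layered_gene_pvalue(mask_frame([]))


class TestLambda90:
    def test_uniform_grid_gives_unity(self):
        n = 100_000
        p = (np.arange(1, n + 1)) / (n + 1)
        assert lambda90(p) == pytest.approx(1.0, abs=1e-3)

    def test_inflated_statistics_recovered(self):
        n = 100_000
        p = (np.arange(1, n + 1)) / (n + 1)
        stats = chi2.isf(p, 1) * 1.2
        p_inflated = chi2.sf(stats, 1)
        assert lambda90(p_inflated) == pytest.approx(1.2, abs=0.01)

    def test_degenerate_identical_pvalues(self):
        lam = lambda90(np.full(500, 0.3))
        assert lam == pytest.approx(chi2.isf(0.3, 1) / chi2.ppf(0.9, 1))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            lambda90(np.full(99, 0.5))


class TestSensitivity:
    def _frame(self):
        return mask_frame(
            [("PTV", "UR", 0.2, 30), ("missREVEL", "RL", 1e-6, 400),
             ("PTV+missREVEL", "RL", 1e-5, 420), ("missREVEL", "UR", 0.3, 25)])

    def test_full_subset_is_identity(self):
        full = layered_gene_pvalue(self._frame())
        sub = sensitivity_recombine(self._frame(), freq_tiers=("UR", "R", "RL"))
        assert sub.p_final == pytest.approx(full.p_final)

    def test_ptv_only_subset(self):
        sub = sensitivity_recombine(self._frame(), layers=("PTV",))
        assert sub.p_final == pytest.approx(0.2)

    def test_rare_only_attenuates_low_frequency_signal(self):
        """Dropping the low-frequency tier removes the planted RL-tier driver."""
        full = layered_gene_pvalue(self._frame())
        rare = sensitivity_recombine(self._frame(), freq_tiers=("UR", "R"))
        assert rare.p_final > full.p_final * 100

    def test_empty_restriction_returns_none(self):
        assert sensitivity_recombine(self._frame(), freq_tiers=("nope",)) is None

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_recombine(self._frame())


class TestGeneLevel:
    def test_bonferroni_uses_test_count(self):
        frames = []
        for i, p in enumerate([1e-9, 0.2, 0.3, 0.4]):
            f = mask_frame([("PTV", "UR", p, 30)])
            f["gene"] = f"G{i}"
            frames.append(f)
        out = gene_level_results(pd.concat(frames, ignore_index=True))
        assert out.attrs["alpha"] == pytest.approx(0.05 / 4)
        assert out["significant"].sum() == 1
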