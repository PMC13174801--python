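"""Integration of gene-level rare-variant results with common-variant GWAS.

Three analyses connect the two study designs:

* **Enrichment grids** - for a grid of rare-variant significance cutoffs and
  GWAS prioritisation-score cutoffs, a Fisher exact test measures how
  strongly significant burden genes concentrate among GWAS-nominated genes.
  The reported odds ratio is the conditional maximum-likelihood estimate of
  the noncentral hypergeometric model with an exact (test-inversion)
  confidence interval; the sample cross-product OR is also emitted.
* **Subset discovery** - GWAS narrows the burden-test search space: within a
  nominated gene subset the Bonferroni threshold is 0.05 / |subset|, which
  can reveal genes missed at the exome-wide threshold.
* **Effect-size power law** - across common variants, low-frequency variants
  and rare burden masks, log |beta| is regressed on log MAF (a logarithmic
  power law); refitting with the confidence bounds of |beta| gives an upper
  and lower band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import fisher_exact, nchypergeom_fisher

from .errors import EstimationError

__all__ = [
    "EnrichmentCell",
    "PowerLawFit",
    "fisher_enrichment",
    "subset_discovery",
    "fit_powerlaw",
]


@dataclass
class EnrichmentCell:
    """One cell of the RVAS x GWAS enrichment grid."""

    rvas_cutoff: float
    geneprio_cutoff: int
    a: int  # RVAS-significant and GWAS-nominated
    b: int  # RVAS-significant only
    c: int  # GWAS-nominated only
    d: int  # neither
    or_cmle: float
    or_sample: float
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool = False


@dataclass
class PowerLawFit:
    """log|beta| = intercept + slope * log(MAF), with CI-bound band fits."""

    intercept: float
    slope: float
    band_lower: tuple[float, float]  # (intercept, slope) fit on CI lower bounds
    band_upper: tuple[float, float]


def _cond_mle_or(a: int, b: int, c: int, d: int) -> float:
    """Conditional MLE of the odds ratio given all margins.

    For Fisher's noncentral hypergeometric model the conditional MLE solves
    E_psi[X] = a; the boundary cells give 0 or infinity.
    """
    M, n, N = a + b + c + d, a + b, a + c
    lo, hi = max(0, n + N - M), min(n, N)
    if a <= lo:
        return 0.0
    if a >= hi:
        return np.inf

    def mean_minus_a(log_psi: float) -> float:
        return nchypergeom_fisher.mean(M, n, N, np.exp(log_psi)) - a

    left, right = -1.0, 1.0
    while mean_minus_a(left) > 0:
        left *= 2
        if left < -500:
            return 0.0
    while mean_minus_a(right) < 0:
        right *= 2
        if right > 500:
            return np.inf
    return float(np.exp(brentq(mean_minus_a, left, right, xtol=1e-12)))


def _exact_ci(a: int, b: int, c: int, d: int, level: float = 0.95) -> tuple[float, float]:
    """Exact tail-inversion confidence interval for the odds ratio."""
    M, n, N = a + b + c + d, a + b, a + c
    lo_supp, hi_supp = max(0, n + N - M), min(n, N)
    alpha = (1.0 - level) / 2.0

    def sf_at(log_psi: float) -> float:  # P(X >= a | psi)
        return nchypergeom_fisher.sf(a - 1, M, n, N, np.exp(log_psi))

    def cdf_at(log_psi: float) -> float:  # P(X <= a | psi)
        return nchypergeom_fisher.cdf(a, M, n, N, np.exp(log_psi))

    if a <= lo_supp:
        ci_low = 0.0
    else:
        f = lambda lp: sf_at(lp) - alpha
        left, right = -1.0, 1.0
        while f(left) > 0:
            left *= 2
            if left < -500:
                break
        while f(right) < 0:
            right *= 2
            if right > 500:
                break
        ci_low = float(np.exp(brentq(f, left, right, xtol=1e-10)))
    if a >= hi_supp:
        ci_high = np.inf
    else:
        g = lambda lp: cdf_at(lp) - alpha
        left, right = -1.0, 1.0
        while g(left) < 0:
            left *= 2
            if left < -500:
                break
        while g(right) > 0:
            right *= 2
            if right > 500:
                break
        ci_high = float(np.exp(brentq(g, left, right, xtol=1e-10)))
    return ci_low, ci_high


def fisher_enrichment(
    gene_results: pd.DataFrame,
    gwas_table: pd.DataFrame,
    rvas_cutoffs=(2.5e-6, 1e-5, 1e-4, 1e-3),
    geneprio_cutoffs=(0, 1, 2, 3),
) -> list[EnrichmentCell]:
    """Fisher exact enrichment grid of burden-significant vs GWAS-nominated genes.

    The gene universe is the intersection of the two tables.  A GWAS cutoff
    of 0 nominates any gene inside a GWAS locus; positive cutoffs require
    the prioritisation score to reach the cutoff.
    """
    merged = gene_results.merge(gwas_table, on="gene", how="inner")
    if merged.empty:
        raise ValueError("gene universes of the two tables do not overlap")
    p = merged["p_final"].to_numpy(float)
    in_locus = merged["in_locus"].to_numpy(bool)
    score = merged["geneprio_score"].to_numpy(int)
    cells: list[EnrichmentCell] = []
    for pc in rvas_cutoffs:
        sig = p < pc
        for gc in geneprio_cutoffs:
            nom = in_locus if gc == 0 else (in_locus & (score >= gc))
            a = int(np.sum(sig & nom))
            b = int(np.sum(sig & ~nom))
            c = int(np.sum(~sig & nom))
            d = int(np.sum(~sig & ~nom))
            degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
            if degenerate:
                cells.append(EnrichmentCell(pc, gc, a, b, c, d, np.nan, np.nan, np.nan, np.nan, np.nan, True))
                continue
            or_sample = (a * d) / (b * c) if b * c > 0 else np.inf
            pval = float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
            or_cmle = _cond_mle_or(a, b, c, d)
            ci_low, ci_high = _exact_ci(a, b, c, d)
            cells.append(EnrichmentCell(pc, gc, a, b, c, d, or_cmle, or_sample, ci_low, ci_high, pval))
    return cells


def enrichment_frame(cells: list[EnrichmentCell]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in cells])


def subset_discovery(gene_results: pd.DataFrame, gene_subset) -> pd.DataFrame:
    """Bonferroni discovery within a GWAS-nominated gene subset.

    The significance threshold is 0.05 divided by the subset size; returns
    the subset genes below it, with the threshold in ``attrs["alpha"]``.
    """
    subset = list(gene_subset)
    if not subset:
        raise ValueError("gene subset is empty")
    alpha = 0.05 / len(subset)
    sub = gene_results[gene_results["gene"].isin(subset)]
    hits = sub[sub["p_final"] < alpha].sort_values("p_final").reset_index(drop=True)
    hits.attrs["alpha"] = alpha
    hits.attrs["n_subset"] = len(subset)
    return hits


def fit_powerlaw(effect_table: pd.DataFrame) -> PowerLawFit:
    """Logarithmic power-law fit of absolute effect size on allele frequency.

    ``effect_table`` needs columns ``maf``, ``abs_beta``, ``ci_lo``,
    ``ci_hi`` (CI bounds of |beta|); all values must be positive.  The point
    fit is OLS of log|beta| on log MAF; the band fits substitute the CI
    bounds for |beta|.
    """
    required = {"maf", "abs_beta", "ci_lo", "ci_hi"}
    if not required <= set(effect_table.columns):
        raise ValueError(f"effect table must have columns {sorted(required)}")
    if len(effect_table) < 3:
        raise EstimationError("power-law fit needs at least 3 rows")
    maf = effect_table["maf"].to_numpy(float)
    for col in ("maf", "abs_beta", "ci_lo", "ci_hi"):
        vals = effect_table[col].to_numpy(float)
        if np.any(vals <= 0) or np.any(~np.isfinite(vals)):
            raise ValueError(f"column {col} must be strictly positive and finite")
    x = np.log(maf)

    def ols(yvals: np.ndarray) -> tuple[float, float]:
        slope, intercept = np.polyfit(x, np.log(yvals), 1)
        return float(intercept), float(slope)

    point = ols(effect_table["abs_beta"].to_numpy(float))
    lower = ols(effect_table["ci_lo"].to_numpy(float))
    upper = ols(effect_table["ci_hi"].to_numpy(float))
    return PowerLawFit(intercept=point[0], slope=point[1], band_lower=lower, band_upper=upper)
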