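"""Burden-score heritability regression for rare coding variation.

The burden heritability of a frequency x annotation bin is the fraction of
phenotypic variance explained by per-gene burden genotypes built from that
bin's variants, assuming homogeneous per-allele effects within a gene mask.
Writing gamma_g = sum_i 2 p_i (1 - p_i) for the burden score of gene g
(the variance of its allele-count burden genotype under independence) and
alpha_g for the effect of the standardised burden genotype on the
standardised observed phenotype, E[alpha_hat_g^2 - se_g^2] = b_g^2 gamma_g.
If squared per-allele effects are exchangeable across genes, regressing
(alpha_hat_g^2 - se_g^2) on gamma_g with a free intercept (absorbing
stratification and relatedness) gives a slope whose product with the total
burden score estimates the bin's observed-scale heritability:

    h2_obs = slope * sum_g gamma_g.

Genes with outlying large effects violate exchangeability; the
``fixed_genes`` option removes listed genes from the regression and adds
their contributions back directly as alpha_hat_g^2 - se_g^2, which also
yields the per-gene heritability partition.  ``genomewide_correction``
projects the component aligned with the genome-wide aggregate burden out
of the effect estimates before regressing.  Standard errors combine a
block jackknife over contiguous gene blocks (regression part) with the
delta-method variance of the fixed-gene contributions.  Observed-scale
estimates are mapped to the liability scale with the standard
prevalence-based transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, EstimationError

__all__ = [
    "FREQ_BINS",
    "ANNOTATION_BINS",
    "BurdenScoreTable",
    "HeritabilityEstimate",
    "burden_scores",
    "burden_summary_stats",
    "bhr_regression",
    "liability_transform",
    "partition_h2",
]

logger = logging.getLogger(__name__)

#: Frequency bins (strict upper bounds; variants above 1e-4 are excluded).
FREQ_BINS = {"ultrarare": (0.0, 1e-5), "rare": (1e-5, 1e-4)}

#: Annotation bins; non-damaging missense = called damaging by no tool.
ANNOTATION_BINS = ("PTV", "damaging_missense", "nondamaging_missense", "synonymous")

_TOOL_COLS = ("revel_damaging", "am_damaging", "pai3d_damaging", "popeve_damaging")


@dataclass
class BurdenScoreTable:
    """Per gene x bin burden scores and standardised effect estimates."""

    table: pd.DataFrame  # columns: gene, bin, gamma, alpha_hat, se, cmac

    def for_bin(self, bin_label: str) -> pd.DataFrame:
        return self.table[self.table["bin"] == bin_label].reset_index(drop=True)

    @property
    def bins(self) -> list[str]:
        return list(dict.fromkeys(self.table["bin"]))


@dataclass
class HeritabilityEstimate:
    """Observed- (and optionally liability-) scale burden heritability."""

    bin: str
    h2_obs: float
    se: float
    intercept: float
    slope: float
    n_genes: int
    total_gamma: float
    h2_liab: float | None = None
    se_liab: float | None = None
    fixed_genes: tuple[str, ...] = ()
    genomewide_correction: bool = False
    gene_contributions: dict[str, float] = field(default_factory=dict)

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.h2_obs - 1.96 * self.se, self.h2_obs + 1.96 * self.se)


def _annotation_bin(variants: pd.DataFrame) -> np.ndarray:
    cons = variants["consequence"].to_numpy()
    any_call = np.zeros(len(variants), bool)
    for c in _TOOL_COLS:
        if c in variants.columns:
            any_call |= variants[c].to_numpy(bool)
    out = np.where(
        cons == "PTV", "PTV",
        np.where(cons == "synonymous", "synonymous",
                 np.where(any_call, "damaging_missense", "nondamaging_missense")),
    )
    return out


def burden_scores(
    variant_table: pd.DataFrame,
    freq_bins=None,
    freq_column: str = "maf_max",
    max_freq: float = 1e-4,
) -> pd.DataFrame:
    """Per gene x bin burden scores gamma_g = sum_i 2 p_i (1 - p_i).

    Variants above ``max_freq`` are excluded; the rest are binned by
    frequency and annotation class.  Returns a frame with gene, bin,
    gamma and the member variant count.
    """
    if freq_bins is None:
        freq_bins = FREQ_BINS
    vt = variant_table.copy()
    p = vt[freq_column].to_numpy(float)
    keep = (p > 0) & (p <= max_freq)
    excluded = int((~keep).sum())
    if excluded:
        logger.info("burden_scores: excluded %d variants with frequency outside (0, %g]", excluded, max_freq)
    vt = vt.loc[keep]
    p = p[keep]
    ann = _annotation_bin(vt)
    fb = np.full(len(vt), "", dtype=object)
    for label, (lo, hi) in freq_bins.items():
        fb[(p > lo) & (p <= hi)] = label
    vt = vt.assign(_gamma=2 * p * (1 - p), _bin=[f"{f}.{a}" for f, a in zip(fb, ann)])
    vt = vt[fb != ""]
    out = (
        vt.groupby(["gene", "_bin"], sort=True)["_gamma"]
        .agg(["sum", "size"])
        .reset_index()
        .rename(columns={"_bin": "bin", "sum": "gamma", "size": "n_variants"})
    )
    return out


def burden_summary_stats(
    study,
    freq_bins=None,
    freq_column: str = "true_freq",
    max_freq: float = 1e-4,
    min_cmac: int = 20,
) -> BurdenScoreTable:
    """Burden scores plus marginal standardised effect estimates for a study.

    For each gene x bin, the allele-count burden genotype is standardised by
    sqrt(gamma) and regressed marginally on the standardised 0/1 phenotype;
    se = 1/sqrt(n).  Gene-bin masks with cMAC below ``min_cmac`` are
    excluded, mirroring the count filters of the association scan.
    """
    vt = study.variant_table
    scores = burden_scores(vt, freq_bins=freq_bins, freq_column=freq_column, max_freq=max_freq)
    y = np.asarray(study.phenotype, float)
    y_std = (y - y.mean()) / y.std()
    n = y.size
    index = study.variant_index
    p = vt[freq_column].to_numpy(float)
    ann = _annotation_bin(vt)
    if freq_bins is None:
        freq_bins = FREQ_BINS
    fb = np.full(len(vt), "", dtype=object)
    for label, (lo, hi) in freq_bins.items():
        fb[(p > lo) & (p <= hi)] = label
    bin_of = pd.Series([f"{f}.{a}" if f else "" for f, a in zip(fb, ann)], index=vt["variant_id"].to_numpy())

    rows = []
    for _, row in scores.iterrows():
        gene, bin_label, gamma = row["gene"], row["bin"], row["gamma"]
        vids = vt.loc[(vt["gene"] == gene).to_numpy() & (bin_of.to_numpy() == bin_label), "variant_id"]
        cols = index.get_indexer(vids)
        g = np.asarray(study.genotypes[:, cols].sum(axis=1)).ravel().astype(float)
        cmac = int(g.sum())
        if cmac < min_cmac:
            continue
        g_std = (g - g.mean()) / np.sqrt(gamma)
        alpha_hat = float(np.dot(g_std, y_std) / n)
        rows.append(
            {"gene": gene, "bin": bin_label, "gamma": float(gamma),
             "alpha_hat": alpha_hat, "se": 1.0 / np.sqrt(n), "cmac": cmac}
        )
    return BurdenScoreTable(pd.DataFrame(rows, columns=["gene", "bin", "gamma", "alpha_hat", "se", "cmac"]))


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares with intercept; returns (intercept, slope)."""
    sw = w.sum()
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    if sxx <= 0:
        raise EstimationError("burden scores are constant; regression is rank deficient")
    slope = np.sum(w * (x - mx) * (y - my)) / sxx
    return float(my - slope * mx), float(slope)


def bhr_regression(
    score_table: pd.DataFrame,
    fixed_genes=(),
    genomewide_correction: bool = False,
    n_blocks: int = 100,
    min_gene_bins: int = 50,
    bin_label: str = "",
) -> HeritabilityEstimate:
    """Observed-scale burden heritability for one bin's gene table.

    ``score_table`` needs columns gene, gamma, alpha_hat, se (one row per
    gene within a single frequency x annotation bin).
    """
    df = score_table.reset_index(drop=True)
    if len(df) < min_gene_bins:
        raise EstimationError(
            f"bhr_regression needs >= {min_gene_bins} gene-bins, got {len(df)}"
        )
    gamma = df["gamma"].to_numpy(float)
    if np.any(gamma <= 0):
        raise EstimationError("burden scores must be positive")
    alpha = df["alpha_hat"].to_numpy(float).copy()
    se = df["se"].to_numpy(float)

    if genomewide_correction:
        # project out the component aligned with the genome-wide aggregate burden
        root = np.sqrt(gamma)
        mu = float(np.sum(root * alpha) / np.sum(gamma))
        alpha = alpha - mu * root

    yv = alpha**2 - se**2
    fixed = [g for g in fixed_genes if g in set(df["gene"])]
    is_fixed = df["gene"].isin(fixed).to_numpy()
    xr, yr, ser = gamma[~is_fixed], yv[~is_fixed], se[~is_fixed]
    if xr.size < 2:
        raise EstimationError("too few non-fixed genes for regression")

    _, slope0 = _wls(xr, yr, np.ones_like(xr))
    w = 1.0 / (2.0 * (xr * max(slope0, 0.0) + ser**2) ** 2)
    intercept, slope = _wls(xr, yr, w)

    total_gamma_r = float(xr.sum())
    fixed_contrib = {g: float(yv[is_fixed][i]) for i, g in enumerate(df.loc[is_fixed, "gene"])}
    h2 = slope * total_gamma_r + sum(fixed_contrib.values())

    # per-gene contributions: fixed genes their own (alpha^2 - se^2),
    # the rest slope * gamma_g, so contributions sum exactly to h2
    contributions = dict(fixed_contrib)
    for g, gm in zip(df.loc[~is_fixed, "gene"], xr):
        contributions[g] = float(slope * gm)

    # block jackknife over contiguous non-fixed gene blocks for the slope part
    B = int(min(n_blocks, xr.size))
    blocks = np.array_split(np.arange(xr.size), B)
    sw, swx, swy = w.sum(), np.sum(w * xr), np.sum(w * yr)
    swxx, swxy = np.sum(w * xr * xr), np.sum(w * xr * yr)
    slopes = np.empty(B)
    for bi, idx in enumerate(blocks):
        bw = w[idx].sum()
        bwx = np.sum(w[idx] * xr[idx])
        bwy = np.sum(w[idx] * yr[idx])
        bwxx = np.sum(w[idx] * xr[idx] ** 2)
        bwxy = np.sum(w[idx] * xr[idx] * yr[idx])
        s, sx, sy = sw - bw, swx - bwx, swy - bwy
        sxx, sxy = swxx - bwxx, swxy - bwxy
        denom = sxx - sx * sx / s
        slopes[bi] = (sxy - sx * sy / s) / denom
    var_slope = (B - 1) / B * float(np.sum((slopes - slopes.mean()) ** 2))
    var_fixed = 0.0
    if fixed:
        a_f = alpha[is_fixed]
        s_f = se[is_fixed]
        var_fixed = float(np.sum(4 * a_f**2 * s_f**2 + 2 * s_f**4))
    se_h2 = float(np.sqrt(var_slope * total_gamma_r**2 + var_fixed))

    return HeritabilityEstimate(
        bin=bin_label or (df["bin"].iloc[0] if "bin" in df else ""),
        h2_obs=float(h2),
        se=se_h2,
        intercept=float(intercept),
        slope=float(slope),
        n_genes=int(len(df)),
        total_gamma=float(gamma.sum()),
        fixed_genes=tuple(fixed),
        genomewide_correction=genomewide_correction,
        gene_contributions=contributions,
    )


def liability_transform(h2_obs: float, K: float, P: float | None = None) -> float:
    """Observed-scale (0/1) to liability-scale heritability.

    ``K`` is the population prevalence, ``P`` the sample case fraction
    (defaults to K for population-based samples, where the formula reduces
    to h2_obs * K(1-K)/z^2 with z the standard normal density at the
    liability threshold).
    """
    if not (0.0 < K < 1.0):
        raise ConfigurationError("population prevalence K must lie in (0, 1)")
    if P is None:
        P = K
    if not (0.0 < P < 1.0):
        raise ConfigurationError("sample prevalence P must lie in (0, 1)")
    z = norm.pdf(norm.isf(K))
    return float(h2_obs * K**2 * (1 - K) ** 2 / (z**2 * P * (1 - P)))


def partition_h2(estimate: HeritabilityEstimate, gene_sets) -> dict[str, float]:
    """Fraction of a bin's burden heritability attributable to gene sets.

    ``gene_sets`` maps set name -> genes.  Fixed genes contribute their own
    alpha_hat^2 - se^2; other genes contribute their slope * gamma_g share,
    so the full gene set partitions the estimate exactly.  Genes absent
    from the fit are skipped with a notice.
    """
    if estimate.h2_obs == 0:
        raise EstimationError("cannot partition a zero heritability estimate")
    if not isinstance(gene_sets, dict):
        gene_sets = {"set": list(gene_sets)}
    out: dict[str, float] = {}
    for name, genes in gene_sets.items():
        total = 0.0
        for g in genes:
            if g in estimate.gene_contributions:
                total += estimate.gene_contributions[g]
            else:
                logger.info("partition_h2: gene %s not among fixed genes; skipped", g)
        out[name] = total / estimate.h2_obs
    return out
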