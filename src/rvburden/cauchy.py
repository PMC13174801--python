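"""Layered Cauchy (ACAT) combination of mask p-values into gene-level tests.

The Cauchy combination transforms each p-value through the standard Cauchy
quantile, averages, and transforms back:

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i,    p = 0.5 - arctan(T)/pi.

The statistic is valid under arbitrary dependence of the inputs, which is
what permits pooling the many overlapping masks of a gene.  Masks are
combined in two layers: first within the missense-only, PTV-only and
PTV+missense annotation families, then across the (up to three) family
p-values into the final gene p-value.  Genes on chrX are combined per sex
stratum.  Calibration of a set of tests is summarised by the genomic
inflation factor at the 90th percentile of the chi-square-transformed
p-value distribution (lambda90).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .masks import LAYER_OF_GROUP

__all__ = [
    "CauchyLayerResult",
    "GeneResult",
    "cauchy_combine",
    "layered_gene_pvalue",
    "gene_level_results",
    "lambda90",
    "sensitivity_recombine",
]

logger = logging.getLogger(__name__)

LAYERS = ("missense", "PTV", "PTV+missense")

_CHI2_90 = float(chi2.ppf(0.9, 1))  # ~2.70554


@dataclass(frozen=True)
class CauchyLayerResult:
    layer: str
    t_stat: float
    p_layer: float
    n_masks_combined: int


@dataclass
class GeneResult:
    """Layered Cauchy combination for one gene (and sex stratum on chrX)."""

    gene: str
    stratum: str
    layers: dict[str, CauchyLayerResult]
    p_final: float
    best_mask: str
    best_or: float
    best_ci: tuple[float, float]
    best_cmac: int
    exome_wide_significant: bool | None = None


def _cauchy_terms(p: np.ndarray) -> np.ndarray:
    p = np.minimum(p, 1.0 - 1e-15)  # tan singularity at p=1
    terms = np.tan((0.5 - p) * np.pi)
    tiny = p < 1e-15
    if tiny.any():
        terms = np.where(tiny, 1.0 / (p * np.pi), terms)
    return terms


def cauchy_combine(p_values, weights=None) -> float:
    """Combine p-values with the Cauchy combination test.

    Weights default to equal.  Inputs must lie in (0, 1]; values of exactly
    1 are clipped just below 1, and values below 1e-15 use the numerically
    stable tail substitution tan((0.5-p)pi) ~ 1/(p pi).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("cauchy_combine needs at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.size != p.size or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative and match p-values")
        w = w / w.sum()
    t = float(np.sum(w * _cauchy_terms(p)))
    if t > 1e15:
        return float(min(max(1.0 / (t * np.pi), 5e-324), 1.0))
    return float(np.clip(0.5 - np.arctan(t) / np.pi, 5e-324, 1.0))


def _cauchy_stat(p_values) -> tuple[float, float]:
    p = np.asarray(list(p_values), dtype=float)
    w = np.full(p.size, 1.0 / p.size)
    t = float(np.sum(w * _cauchy_terms(p)))
    return t, cauchy_combine(p)


def _mask_p(row) -> float:
    p = row["p_spa"] if "p_spa" in row and np.isfinite(row["p_spa"]) else np.nan
    if not np.isfinite(p):
        p = row["p_ivw"]
    return float(min(max(p, 5e-324), 1.0))


def layered_gene_pvalue(mask_results: pd.DataFrame, alpha: float | None = None) -> GeneResult:
    """Two-layer Cauchy combination of one gene+stratum's mask results.

    ``mask_results`` rows must share one gene and stratum and carry
    ``annotation_group``, ``p_ivw`` (and optionally ``p_spa``, used when
    present), plus odds-ratio columns for best-mask reporting.  Masks are
    partitioned into missense / PTV / PTV+missense layers; each layer is
    combined by the Cauchy test, then the available layer p-values are
    combined again.  Absent layers are dropped, not imputed.
    """
    if mask_results.empty:
        raise ValueError("no mask results supplied for gene-level combination")
    genes = mask_results["gene"].unique()
    if len(genes) != 1:
        raise ValueError(f"expected one gene, got {list(genes)}")
    stratum = mask_results["stratum"].iloc[0] if "stratum" in mask_results else "all"

    pvals = mask_results.apply(_mask_p, axis=1).to_numpy()
    layer_of = mask_results["annotation_group"].map(LAYER_OF_GROUP).to_numpy()
    layers: dict[str, CauchyLayerResult] = {}
    for layer in LAYERS:
        sel = layer_of == layer
        if not sel.any():
            continue
        t, p = _cauchy_stat(pvals[sel])
        layers[layer] = CauchyLayerResult(layer=layer, t_stat=t, p_layer=p, n_masks_combined=int(sel.sum()))
    p_final = cauchy_combine([lr.p_layer for lr in layers.values()])

    # best mask: minimum p, ties by larger total cMAC then mask name
    mr = mask_results.assign(_p=pvals)
    cmac_col = "cmac_total" if "cmac_total" in mr else "cmac"
    mr = mr.assign(_name=mr["annotation_group"] + "." + mr["freq_tier"])
    mr = mr.sort_values(["_p", cmac_col, "_name"], ascending=[True, False, True], kind="stable")
    best = mr.iloc[0]
    or_col = "odds_ratio" if "odds_ratio" in mr else None
    best_or = float(np.exp(best["beta_meta"])) if "beta_meta" in mr else float(best[or_col]) if or_col else np.nan
    if "beta_meta" in mr and "se_meta" in mr:
        half = 1.959963984540054 * best["se_meta"]
        best_ci = (float(np.exp(best["beta_meta"] - half)), float(np.exp(best["beta_meta"] + half)))
    elif {"ci_low", "ci_high"} <= set(mr.columns):
        best_ci = (float(best["ci_low"]), float(best["ci_high"]))
    else:
        best_ci = (np.nan, np.nan)

    return GeneResult(
        gene=str(genes[0]),
        stratum=str(stratum),
        layers=layers,
        p_final=p_final,
        best_mask=str(best["_name"]),
        best_or=best_or,
        best_ci=best_ci,
        best_cmac=int(best[cmac_col]),
        exome_wide_significant=(p_final < alpha) if alpha is not None else None,
    )


def gene_level_results(meta_results: pd.DataFrame, alpha_total: float = 0.05) -> pd.DataFrame:
    """Gene-level table from a (filtered) meta-analysis result table.

    The Bonferroni threshold is ``alpha_total`` divided by the number of
    gene-stratum tests actually performed.
    """
    if meta_results.empty:
        return pd.DataFrame(
            columns=["gene", "stratum", "p_missense", "p_ptv", "p_ptv_miss", "p_final",
                     "best_mask", "best_or", "best_ci_low", "best_ci_high", "best_cmac",
                     "significant"]
        )
    groups = list(meta_results.groupby(["gene", "stratum"], sort=False))
    alpha = alpha_total / len(groups)
    rows = []
    for (gene, stratum), grp in groups:
        gr = layered_gene_pvalue(grp, alpha=alpha)
        rows.append(
            {
                "gene": gene,
                "stratum": stratum,
                "p_missense": gr.layers["missense"].p_layer if "missense" in gr.layers else np.nan,
                "p_ptv": gr.layers["PTV"].p_layer if "PTV" in gr.layers else np.nan,
                "p_ptv_miss": gr.layers["PTV+missense"].p_layer if "PTV+missense" in gr.layers else np.nan,
                "p_final": gr.p_final,
                "best_mask": gr.best_mask,
                "best_or": gr.best_or,
                "best_ci_low": gr.best_ci[0],
                "best_ci_high": gr.best_ci[1],
                "best_cmac": gr.best_cmac,
                "significant": gr.p_final < alpha,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    out.attrs["n_tests"] = len(groups)
    return out


def lambda90(p_values) -> float:
    """Genomic inflation factor at the 90th percentile of chi-square stats.

    Each p-value is transformed to its upper-tail chi-square(1) quantile;
    lambda90 is the ratio of the 90th percentile of those statistics to the
    90th percentile of the chi-square(1) distribution (~2.70554).
    """
    p = np.asarray(list(p_values), dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("lambda90 requires at least 100 p-values")
    stats = chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    return float(np.quantile(stats, 0.9) / _CHI2_90)


def sensitivity_recombine(
    mask_results: pd.DataFrame,
    freq_tiers=None,
    layers=None,
    alpha: float | None = None,
) -> GeneResult | None:
    """Re-run the layered combination on a mask subset for one gene+stratum.

    ``freq_tiers`` and/or ``layers`` restrict the mask set (e.g. rare-only:
    tiers {UR, R}; PTV-only: layers {PTV}).  Returns None (gene untestable)
    when the restriction leaves no masks.
    """
    if freq_tiers is None and layers is None:
        raise ValueError("subset specification is empty")
    sub = mask_results
    if freq_tiers is not None:
        sub = sub[sub["freq_tier"].isin(list(freq_tiers))]
    if layers is not None:
        wanted = set(layers)
        sub = sub[sub["annotation_group"].map(LAYER_OF_GROUP).isin(wanted)]
    if sub.empty:
        logger.info("sensitivity subset left no masks for %s", mask_results["gene"].iloc[0])
        return None
    return layered_gene_pvalue(sub.reset_index(drop=True), alpha=alpha)
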