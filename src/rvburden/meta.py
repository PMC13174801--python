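"""Fixed-effects meta-analysis with count-based saddlepoint tail correction.

Per-mask study results are combined by inverse-variance-weighted (IVW)
fixed-effects meta-analysis: weights w_s = 1/SE_s^2, pooled beta the
weighted mean, pooled SE = 1/sqrt(sum w_s), with Cochran's Q for
heterogeneity.  The pooled Z statistic is normal-referenced, which is
anti-conservative for rare burdens in unbalanced case-control studies.

The saddlepoint adjustment replaces that normal reference by the exact
null distribution of a count statistic.  Under the null each of a mask's
cmac_s carrier alleles in study s falls in a case independently with
probability phi_s (the study case fraction), so X_s ~ Binomial(cmac_s,
phi_s) and the per-study score is U_s = X_s - cmac_s*phi_s.  The combined
score T = sum_s lambda_s U_s uses lambda_s = zeta_s / sqrt(cmac_s phi_s
(1-phi_s)) with zeta_s the normalised IVW weights, which makes
T / sqrt(Var T) coincide with the IVW Z under the normal approximation;
the saddlepoint tail of T is therefore a pure tail correction of the IVW
p-value.  Tails use the Lugannani-Rice formula on the exact cumulant
generating function

    K(t) = sum_s cmac_s log(1 - phi_s + phi_s e^{lambda_s t}) - t sum_s lambda_s cmac_s phi_s.

Post-meta filters retain masks with total cMAC >= 20 contributed by at
least two studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, norm

__all__ = ["PerStudyCount", "MetaMaskResult", "ivw_meta", "spa_adjust", "meta_filter", "meta_analyze"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerStudyCount:
    """Per-study ingredients of the count-based saddlepoint null."""

    study_id: str
    cmac: int
    case_fraction: float
    weight: float  # IVW weight 1/SE^2


@dataclass
class MetaMaskResult:
    """Meta-analytic summary for one mask (gene x annotation x tier x stratum)."""

    beta_meta: float
    se_meta: float
    p_ivw: float
    q_stat: float
    q_df: int
    q_pvalue: float
    n_studies: int
    cmac_total: int
    per_study: tuple[PerStudyCount, ...]
    p_spa: float | None = None
    spa_converged: bool = True
    gene: str = ""
    annotation_group: str = ""
    freq_tier: str = ""
    stratum: str = "all"

    @property
    def z(self) -> float:
        return self.beta_meta / self.se_meta


def ivw_meta(results) -> MetaMaskResult:
    """Inverse-variance-weighted fixed-effects combination of study results.

    ``results`` is a sequence of objects/rows with ``beta``, ``se``,
    ``cmac``, ``n_cases``, ``n_referents`` and ``study_id`` fields.
    """
    rows = list(results)
    if not rows:
        raise ValueError("ivw_meta needs at least one study result")

    def get(r, name):
        return r[name] if isinstance(r, (dict, pd.Series)) else getattr(r, name)

    beta = np.array([get(r, "beta") for r in rows], float)
    se = np.array([get(r, "se") for r in rows], float)
    if np.any(se <= 0) or not np.all(np.isfinite(se)):
        raise ValueError("all standard errors must be finite and positive")
    w = 1.0 / se**2
    beta_meta = float(np.sum(w * beta) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    zval = beta_meta / se_meta
    p_ivw = float(2.0 * norm.sf(abs(zval)))
    q = float(np.sum(w * (beta - beta_meta) ** 2))
    q_df = len(rows) - 1
    q_p = float(chi2.sf(q, q_df)) if q_df > 0 else np.nan
    per_study = tuple(
        PerStudyCount(
            study_id=str(get(r, "study_id")),
            cmac=int(get(r, "cmac")),
            case_fraction=float(get(r, "n_cases") / (get(r, "n_cases") + get(r, "n_referents"))),
            weight=float(wi),
        )
        for r, wi in zip(rows, w)
    )
    first = rows[0]
    return MetaMaskResult(
        beta_meta=beta_meta,
        se_meta=se_meta,
        p_ivw=p_ivw,
        q_stat=q,
        q_df=q_df,
        q_pvalue=q_p,
        n_studies=len(rows),
        cmac_total=int(sum(ps.cmac for ps in per_study)),
        per_study=per_study,
        gene=str(get(first, "gene")) if _has(first, "gene") else "",
        annotation_group=str(get(first, "annotation_group")) if _has(first, "annotation_group") else "",
        freq_tier=str(get(first, "freq_tier")) if _has(first, "freq_tier") else "",
        stratum=str(get(first, "stratum")) if _has(first, "stratum") else "all",
    )


def _has(r, name) -> bool:
    if isinstance(r, (dict, pd.Series)):
        return name in r
    return hasattr(r, name)


# ---------------------------------------------------------------------------
# saddlepoint machinery
# ---------------------------------------------------------------------------


def _cgf(t: float, m: np.ndarray, phi: np.ndarray, lam: np.ndarray) -> float:
    return float(np.sum(m * np.log1p(phi * np.expm1(lam * t))) - t * np.sum(lam * m * phi))


def _cgf_d1(t: float, m: np.ndarray, phi: np.ndarray, lam: np.ndarray) -> float:
    e = np.exp(lam * t)
    return float(np.sum(m * phi * lam * e / (1.0 - phi + phi * e)) - np.sum(lam * m * phi))


def _cgf_d2(t: float, m: np.ndarray, phi: np.ndarray, lam: np.ndarray) -> float:
    e = np.exp(lam * t)
    denom = 1.0 - phi + phi * e
    return float(np.sum(m * lam**2 * phi * (1.0 - phi) * e / denom**2))


def _upper_tail(
    t_obs: float,
    m: np.ndarray,
    phi: np.ndarray,
    lam: np.ndarray,
    span: float | None = None,
) -> float:
    """P(T >= t_obs) by the Lugannani-Rice saddlepoint formula.

    When every study contributes the same score span (``span`` given), T is
    a lattice variable and the lattice form of the formula is used: the
    saddlepoint is taken at t_obs - span/2 and v carries the sinh
    correction (Daniels' second continuity correction), which recovers the
    atom mass at the observed count.  With incommensurate spans across
    studies the distribution of T is effectively continuous and the plain
    formula applies.
    """
    # support of T: each study contributes [-lam*m*phi, lam*m*(1-phi)] (signs flip with lam)
    per_hi = np.where(lam > 0, lam * m * (1.0 - phi), -lam * m * phi)
    per_lo = np.where(lam > 0, -lam * m * phi, lam * m * (1.0 - phi))
    sup, inf_ = float(per_hi.sum()), float(per_lo.sum())
    tol = 1e-9 * max(1.0, abs(sup), abs(inf_))
    if t_obs > sup + tol:
        return 0.0
    if t_obs <= inf_ + tol:
        return 1.0
    if t_obs >= sup - tol:
        # only the extreme atom remains
        atom = np.where(lam > 0, m * np.log(phi), m * np.log1p(-phi))
        return float(np.exp(atom.sum()))
    target = t_obs - 0.5 * span if span is not None else t_obs
    if target <= inf_:
        return 1.0
    f = lambda t: _cgf_d1(t, m, phi, lam) - target
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("saddlepoint bracket expansion failed")
    lo = -1.0
    while f(lo) > 0:
        lo *= 2.0
        if lo < -1e8:
            raise RuntimeError("saddlepoint bracket expansion failed")
    t_hat = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    sd = np.sqrt(_cgf_d2(0.0, m, phi, lam))
    if abs(t_hat) < 1e-6:
        return float(norm.sf(target / sd))
    w = np.sign(t_hat) * np.sqrt(2.0 * (t_hat * target - _cgf(t_hat, m, phi, lam)))
    if span is None:
        v = t_hat * np.sqrt(_cgf_d2(t_hat, m, phi, lam))
    else:
        v = (2.0 / span) * np.sinh(0.5 * t_hat * span) * np.sqrt(_cgf_d2(t_hat, m, phi, lam))
    return float(np.clip(norm.sf(w) + norm.pdf(w) * (1.0 / v - 1.0 / w), 0.0, 1.0))


def spa_pvalue(
    z: float,
    cmac: np.ndarray,
    case_fraction: np.ndarray,
    weights: np.ndarray,
) -> float:
    """Two-sided saddlepoint p-value matching a meta-analytic Z statistic.

    ``weights`` are IVW weights (any positive scale; they are normalised
    internally).  The observed score is placed at t_obs = z * sqrt(Var T)
    so that the normal approximation of T reproduces ``z`` exactly.
    """
    m = np.asarray(cmac, float)
    phi = np.asarray(case_fraction, float)
    zeta = np.asarray(weights, float)
    zeta = zeta / zeta.sum()
    v = m * phi * (1.0 - phi)
    if np.any(v <= 0):
        raise ValueError("every study needs cmac > 0 and case fraction in (0,1)")
    lam = zeta / np.sqrt(v)
    var_t = float(np.sum(zeta**2))
    t_obs = z * np.sqrt(var_t)
    # equal score spans across studies make T a lattice variable; the
    # lattice (continuity-corrected) tail applies when the observed value
    # sits on an atom, the plain formula when it falls between atoms
    span = None
    if np.allclose(lam, lam[0], rtol=1e-9):
        k = t_obs / lam[0] + float(np.sum(m * phi))
        if abs(k - round(k)) < 1e-6:
            span = float(lam[0])
    upper = _upper_tail(t_obs, m, phi, lam, span=span)
    lower = _upper_tail(-t_obs, m, phi, -lam, span=span)  # P(T <= t_obs) = P(-T >= -t_obs)
    return float(min(2.0 * min(upper, lower), 1.0))


def spa_adjust(meta: MetaMaskResult, threshold: float = 0.05, force: bool = False) -> MetaMaskResult:
    """Attach a saddlepoint-adjusted p-value to a meta result.

    Applied to masks reaching nominal IVW p below ``threshold`` (or always
    with ``force``).  On root-finding failure the IVW p is retained and the
    result flagged unadjusted.
    """
    if not force and meta.p_ivw >= threshold:
        return meta
    m = np.array([ps.cmac for ps in meta.per_study], float)
    phi = np.array([ps.case_fraction for ps in meta.per_study], float)
    w = np.array([ps.weight for ps in meta.per_study], float)
    try:
        meta.p_spa = spa_pvalue(meta.z, m, phi, w)
        meta.spa_converged = True
    except (RuntimeError, ValueError) as exc:
        logger.warning("SPA failed for %s/%s/%s: %s", meta.gene, meta.annotation_group, meta.freq_tier, exc)
        meta.p_spa = meta.p_ivw
        meta.spa_converged = False
    return meta


# ---------------------------------------------------------------------------
# scan-level drivers
# ---------------------------------------------------------------------------

_KEY = ["gene", "annotation_group", "freq_tier", "stratum"]


def meta_analyze(
    study_results: pd.DataFrame,
    spa: bool = True,
    spa_threshold: float = 0.05,
) -> pd.DataFrame:
    """IVW meta-analysis of a concatenated per-study result table.

    Groups rows by mask key (gene, annotation group, frequency tier,
    stratum), combines with :func:`ivw_meta`, and applies the saddlepoint
    adjustment to nominally significant masks.
    """
    records = []
    for key, grp in study_results.groupby(_KEY, sort=False):
        meta = ivw_meta([row for _, row in grp.iterrows()])
        if spa:
            meta = spa_adjust(meta, threshold=spa_threshold)
        records.append(
            {
                "gene": key[0],
                "annotation_group": key[1],
                "freq_tier": key[2],
                "stratum": key[3],
                "beta_meta": meta.beta_meta,
                "se_meta": meta.se_meta,
                "p_ivw": meta.p_ivw,
                "p_spa": meta.p_spa if meta.p_spa is not None else np.nan,
                "q_stat": meta.q_stat,
                "q_df": meta.q_df,
                "q_p": meta.q_pvalue,
                "n_studies": meta.n_studies,
                "cmac_total": meta.cmac_total,
            }
        )
    cols = _KEY + [
        "beta_meta", "se_meta", "p_ivw", "p_spa", "q_stat", "q_df", "q_p",
        "n_studies", "cmac_total",
    ]
    return pd.DataFrame(records, columns=cols)


def meta_filter(meta_results: pd.DataFrame, min_cmac: int = 20, min_studies: int = 2) -> pd.DataFrame:
    """Post-meta count filters: total cMAC and contributing-study minimums."""
    if meta_results.empty:
        return meta_results
    keep = (meta_results["cmac_total"] >= min_cmac) & (meta_results["n_studies"] >= min_studies)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("meta_filter: dropped %d of %d masks", dropped, len(meta_results))
    return meta_results.loc[keep].reset_index(drop=True)
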