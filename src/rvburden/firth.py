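"""Firth-penalized logistic regression for rare-variant burden tests.

The burden test regresses case status on a per-sample burden genotype
(carrier indicator by default) with covariate adjustment.  Maximum
likelihood estimates diverge under separation, which is routine at rare
carrier counts, so all tests maximise the Jeffreys-penalized log-likelihood

    l*(beta) = l(beta) + 1/2 log |I(beta)|,

which always has a finite maximiser and reduces small-sample bias.  Two
modes are provided:

* ``exact`` - the penalty uses the full design (intercept, covariates,
  burden) and all coefficients are penalized jointly;
* ``approximate`` - the covariate-only null model is fit once by ordinary
  maximum likelihood, its linear predictor is fixed as an offset, and the
  Firth fit involves only the intercept and the burden term.  This is the
  fast mode used for exome-wide scans; it agrees closely with the exact
  mode away from degenerate configurations.

The p-value is the penalized likelihood-ratio test of the burden
coefficient; the reported standard error is back-corrected from the
p-value as |beta| / z with z the corresponding normal quantile, so that
(beta, SE) reproduce the test when re-used downstream in meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .errors import DegeneratePredictorError, EstimationError
from .masks import MaskDefinition, build_burden_genotype

__all__ = ["AssociationResult", "firth_logistic", "run_study_scan"]

logger = logging.getLogger(__name__)

_MAX_ITER = 50
_TOL = 1e-8


@dataclass
class AssociationResult:
    """One burden association test in one study (and stratum)."""

    beta: float
    se: float
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    cmac: int
    n_carriers: int
    n_cases: int
    n_referents: int
    converged: bool
    gene: str = ""
    annotation_group: str = ""
    freq_tier: str = ""
    stratum: str = "all"
    study_id: str = ""


def _penalized_loglik(X: np.ndarray, y: np.ndarray, eta: np.ndarray) -> float:
    p = expit(eta)
    w = p * (1.0 - p)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    XtWX = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    free: np.ndarray,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> tuple[np.ndarray, float, bool, np.ndarray]:
    """Maximise the Jeffreys-penalized likelihood over ``free`` coefficients.

    The penalty uses the information matrix of the *full* design, so fixing
    a coefficient at zero yields the profile penalized likelihood used by
    the penalized LRT.  Returns (beta, penalized loglik, converged,
    covariance of free coefficients).
    """
    n, k = X.shape
    beta = np.zeros(k)
    eta = offset + X @ beta
    pll = _penalized_loglik(X, y, eta)
    free_idx = np.flatnonzero(free)
    converged = False
    cov_free = np.full((free_idx.size, free_idx.size), np.nan)
    for _ in range(max_iter):
        p = expit(eta)
        w = p * (1.0 - p)
        XtWX = (X * w[:, None]).T @ X
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise EstimationError("singular information matrix") from exc
        h = w * np.einsum("ij,jk,ik->i", X, XtWX_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        I_free = XtWX[np.ix_(free_idx, free_idx)]
        try:
            cov_free = np.linalg.inv(I_free)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular information matrix") from exc
        step = cov_free @ score[free_idx]
        if np.max(np.abs(score[free_idx])) < tol:
            converged = True
            break
        # step-halving to guarantee monotone penalized likelihood
        scale = 1.0
        for _ in range(25):
            cand = beta.copy()
            cand[free_idx] += scale * step
            eta_c = offset + X @ cand
            pll_c = _penalized_loglik(X, y, eta_c)
            if pll_c >= pll - 1e-12:
                beta, eta, pll = cand, eta_c, pll_c
                break
            scale *= 0.5
        else:
            break
    return beta, pll, converged, cov_free


def _fit_pair(X: np.ndarray, y: np.ndarray, offset: np.ndarray, burden_col: int):
    """Full and burden-constrained penalized fits; returns LRT ingredients."""
    k = X.shape[1]
    free_full = np.ones(k, bool)
    beta_full, pll_full, conv_full, cov_full = _firth_newton(X, y, offset, free_full)
    free_null = np.ones(k, bool)
    free_null[burden_col] = False
    _, pll_null, conv_null, _ = _firth_newton(X, y, offset, free_null)
    return beta_full, pll_full, pll_null, conv_full and conv_null, cov_full


def _result_from_fit(
    beta_b: float,
    pll_full: float,
    pll_null: float,
    wald_var: float,
    converged: bool,
    cmac: int,
    n_carriers: int,
    n_cases: int,
    n_referents: int,
) -> AssociationResult:
    lrt = max(2.0 * (pll_full - pll_null), 0.0)
    p = float(chi2.sf(lrt, 1)) if lrt > 0 else 1.0
    z = norm.isf(p / 2.0)
    if p < 1.0 and abs(beta_b) > 0 and np.isfinite(z) and z > 0:
        se = abs(beta_b) / z
    else:
        se = float(np.sqrt(wald_var)) if wald_var > 0 else np.nan
    half = 1.959963984540054 * se
    return AssociationResult(
        beta=float(beta_b),
        se=float(se),
        p_value=p,
        odds_ratio=float(np.exp(beta_b)),
        ci_low=float(np.exp(beta_b - half)),
        ci_high=float(np.exp(beta_b + half)),
        cmac=cmac,
        n_carriers=n_carriers,
        n_cases=n_cases,
        n_referents=n_referents,
        converged=bool(converged),
    )


def _ml_logistic(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Maximum-likelihood logistic fit of the covariate-only null model."""
    import statsmodels.api as sm

    try:
        fit = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise EstimationError("null model fit failed") from exc
    return np.asarray(fit.params)


def firth_logistic(
    burden: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    mode: str = "approximate",
    null_offset: np.ndarray | None = None,
    cmac: int | None = None,
) -> AssociationResult:
    """Firth-corrected logistic burden test.

    Parameters
    ----------
    burden
        Per-sample burden genotype (0/1 carrier indicator or allele count).
    phenotype
        Binary case status; both classes must be present.
    covariates
        Optional covariate matrix (no intercept column; one is added).
    mode
        ``"exact"`` penalizes all coefficients jointly; ``"approximate"``
        fits the covariate-only null by ML, fixes its linear predictor as an
        offset and applies the Firth fit to intercept + burden only.
    null_offset
        Pre-computed null linear predictor for the approximate mode (as
        produced once per study by :func:`run_study_scan`).
    """
    y = np.asarray(phenotype, dtype=float).ravel()
    b = np.asarray(burden, dtype=float).ravel()
    if y.min() == y.max():
        raise DegeneratePredictorError("phenotype has a single class")
    if b.min() == b.max():
        raise DegeneratePredictorError("burden genotype has no variation")
    n = y.size
    n_cases = int(y.sum())
    n_carriers = int((b >= 1).sum())
    if cmac is None:
        cmac = int(b.sum())

    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]

    if mode == "exact":
        X = np.column_stack([np.ones(n), C, b])
        offset = np.zeros(n)
        burden_col = X.shape[1] - 1
    elif mode == "approximate":
        if null_offset is None:
            Xnull = np.column_stack([np.ones(n), C])
            null_offset = Xnull @ _ml_logistic(Xnull, y)
        X = np.column_stack([np.ones(n), b])
        offset = np.asarray(null_offset, dtype=float)
        burden_col = 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    beta_full, pll_full, pll_null, converged, cov_full = _fit_pair(X, y, offset, burden_col)
    wald_var = cov_full[burden_col, burden_col] if np.isfinite(cov_full).all() else np.nan
    return _result_from_fit(
        beta_full[burden_col], pll_full, pll_null, wald_var, converged,
        cmac, n_carriers, n_cases, n - n_cases,
    )


# ---------------------------------------------------------------------------
# fast path: two-parameter (intercept + binary burden) Firth fit with offset
# ---------------------------------------------------------------------------


def _firth_burden_fast(
    carriers: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> tuple[float, float, float, bool, float]:
    """Analytic two-parameter Firth fit for a binary carrier burden.

    Exploits X = [1, carrier]: the information matrix, hat diagonals and
    modified score reduce to sums over all samples and over carriers,
    giving an O(n)-per-iteration fit.  Returns (beta_burden, penalized
    loglik full, penalized loglik at beta_burden=0, converged, wald var).
    """
    n = y.size
    car = carriers
    y_car = y[car]
    off_car = offset[car]

    def components(b0: float, b1: float):
        eta = offset + b0
        eta_car = off_car + b0 + b1
        p = expit(eta)
        p_car = expit(eta_car)
        w = p * (1.0 - p)
        w_car = p_car * (1.0 - p_car)
        S0 = float(w.sum() - w[car].sum() + w_car.sum())
        S1 = float(w_car.sum())
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        ll -= float(np.sum(y_car * eta[car] - np.logaddexp(0.0, eta[car])))
        ll += float(np.sum(y_car * eta_car - np.logaddexp(0.0, eta_car)))
        det = S1 * (S0 - S1)
        pll = ll + (0.5 * np.log(det) if det > 0 else -np.inf)
        return p, p_car, w, w_car, S0, S1, pll

    def score(p, p_car, w, w_car, S0, S1):
        # hat diagonals: w/(S0-S1) off carriers, w/S1 on carriers
        d_nc = S0 - S1
        resid = y - p
        adj = w * (0.5 - p) / d_nc
        U0 = float(resid.sum() - resid[car].sum()) + float(adj.sum() - adj[car].sum())
        resid_car = y_car - p_car
        adj_car = w_car * (0.5 - p_car) / S1
        U1 = float(resid_car.sum() + adj_car.sum())
        U0 += U1
        return U0, U1

    b0, b1 = 0.0, 0.0
    p, p_car, w, w_car, S0, S1, pll = components(b0, b1)
    converged = False
    for _ in range(max_iter):
        U0, U1 = score(p, p_car, w, w_car, S0, S1)
        if max(abs(U0), abs(U1)) < tol:
            converged = True
            break
        det = S1 * (S0 - S1)
        d0 = (U0 - U1) / (S0 - S1)
        d1 = (-S1 * U0 + S0 * U1) / det
        scale = 1.0
        for _ in range(25):
            cand = (b0 + scale * d0, b1 + scale * d1)
            comp = components(*cand)
            if comp[-1] >= pll - 1e-12:
                b0, b1 = cand
                p, p_car, w, w_car, S0, S1, pll = comp
                break
            scale *= 0.5
        else:
            break
    pll_full = pll
    wald_var = S0 / (S1 * (S0 - S1))

    # constrained fit: beta_burden = 0, penalty from the full 2x2 information
    c0 = 0.0
    _, _, _, _, _, _, pll0 = components(c0, 0.0)
    conv0 = False
    for _ in range(max_iter):
        pc, pcar, wc, wcar, S0c, S1c, pll0 = components(c0, 0.0)
        U0, _ = score(pc, pcar, wc, wcar, S0c, S1c)
        if abs(U0) < tol:
            conv0 = True
            break
        step = U0 / S0c
        scale = 1.0
        for _ in range(25):
            cand = c0 + scale * step
            comp = components(cand, 0.0)
            if comp[-1] >= pll0 - 1e-12:
                c0 = cand
                pll0 = comp[-1]
                break
            scale *= 0.5
        else:
            break
    return b1, pll_full, pll0, converged and conv0, wald_var


def run_study_scan(
    study,
    masks: list[MaskDefinition],
    covariate_columns: tuple[str, ...] | None = None,
    cmac_min: int = 10,
    carrier_min: int | None = None,
    mode: str = "approximate",
    coding: str = "carrier",
) -> pd.DataFrame:
    """Burden-test every mask of one study; returns a result table.

    Covariates default to age, sex and every PC column present.  Masks on
    chrX genes are tested in male-only and female-only strata; autosomal
    masks in the pooled sample.  Masks below the per-study count thresholds
    (cMAC, optionally carrier count) are dropped.
    """
    cov_df = study.covariates
    if covariate_columns is None:
        covariate_columns = tuple(
            c for c in cov_df.columns if c in ("age", "sex") or c.startswith("PC")
        )
    y_all = np.asarray(study.phenotype, dtype=float)
    if set(np.unique(y_all)) != {0.0, 1.0}:
        raise DegeneratePredictorError("phenotype must contain both cases and referents")

    chrom_of_gene = dict(
        zip(study.variant_table["gene"], study.variant_table["chrom"])
    )
    sexes = cov_df["sex"].to_numpy() if "sex" in cov_df.columns else np.zeros(len(cov_df), int)

    strata: dict[str, np.ndarray] = {"all": np.arange(study.n_samples)}
    if any(str(chrom_of_gene.get(m.gene)) == "chrX" for m in masks):
        strata["male"] = np.flatnonzero(sexes == 1)
        strata["female"] = np.flatnonzero(sexes == 0)

    offsets: dict[str, np.ndarray] = {}
    for name, rows in strata.items():
        cols = [c for c in covariate_columns if not (name in ("male", "female") and c == "sex")]
        Xn = np.column_stack([np.ones(rows.size)] + [cov_df[c].to_numpy(float)[rows] for c in cols])
        offsets[name] = Xn @ _ml_logistic(Xn, y_all[rows])

    records = []
    n_skipped = 0
    for mask in masks:
        on_x = str(chrom_of_gene.get(mask.gene)) == "chrX"
        for stratum in (("male", "female") if on_x else ("all",)):
            rows = strata[stratum]
            bg = build_burden_genotype(mask, study, coding=coding, sample_rows=rows)
            if bg.cmac < cmac_min or bg.n_carriers < 1:
                n_skipped += 1
                continue
            if carrier_min is not None and bg.n_carriers < carrier_min:
                n_skipped += 1
                continue
            y = y_all[rows]
            if y.min() == y.max():
                n_skipped += 1
                continue
            vec = bg.carrier_vector
            if bg.n_carriers == rows.size:
                n_skipped += 1
                continue
            if mode == "approximate" and coding == "carrier":
                car = vec >= 1
                b1, pllf, pll0, conv, wvar = _firth_burden_fast(car, y, offsets[stratum])
                res = _result_from_fit(
                    b1, pllf, pll0, wvar, conv, bg.cmac, bg.n_carriers,
                    int(y.sum()), int(rows.size - y.sum()),
                )
            else:
                cols = [c for c in covariate_columns if not (stratum in ("male", "female") and c == "sex")]
                C = np.column_stack([cov_df[c].to_numpy(float)[rows] for c in cols]) if cols else None
                res = firth_logistic(
                    vec, y, covariates=C, mode=mode,
                    null_offset=offsets[stratum] if mode == "approximate" else None,
                    cmac=bg.cmac,
                )
            res.gene = mask.gene
            res.annotation_group = mask.annotation_group
            res.freq_tier = mask.freq_tier
            res.stratum = stratum
            res.study_id = study.study_id
            records.append(res)
    logger.info(
        "%s: tested %d mask-strata, skipped %d below count thresholds",
        study.study_id, len(records), n_skipped,
    )
    cols = [
        "study_id", "gene", "annotation_group", "freq_tier", "stratum",
        "beta", "se", "p_value", "odds_ratio", "ci_low", "ci_high",
        "cmac", "n_carriers", "n_cases", "n_referents", "converged",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
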