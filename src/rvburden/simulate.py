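"""Synthetic multi-study case-control cohorts under a liability-threshold model.

The generator emulates the statistical structure a multi-study rare-variant
burden meta-analysis assumes: a shared catalogue of rare coding variants with
a log-uniform allele-frequency spectrum, an annotation class composition of
roughly one quarter synonymous, one half benign missense, 10-15% damaging
missense and under 5% protein-truncating variants, gene-concentrated per-allele
liability effects (PTV >= damaging missense > benign = synonymous = 0), and
several studies with differing case:control imbalance.

Disease status follows a liability-threshold model: each individual's latent
liability is the sum of per-allele genetic effects in causal genes, covariate
effects (age, sex, principal components) and standard normal noise; a sample
is a case when liability exceeds the threshold implied by the population
prevalence K.  Case-ascertained studies (case-control assemblies) are built
by rejection sampling cases up to the target count; population studies sample
individuals unconditionally.

Variants are simulated independently (no linkage disequilibrium) and every
study shares the variant catalogue and causal-gene truth while drawing its
own genotypes, covariates and phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from .errors import ConfigurationError

__all__ = [
    "StudySpec",
    "EffectModel",
    "CovariateModel",
    "SimulationConfig",
    "StudyDataset",
    "simulate_cohort",
    "simulate_multi_study",
    "simulate_gwas_annotations",
]

#: Annotation class labels in the order used by ``annotation_mix``.
ANNOTATION_CLASSES = ("synonymous", "benign_missense", "damaging_missense", "PTV")

#: Default class mix: the observed exome composition (~25% synonymous,
#: ~50% benign missense, 10-15% damaging missense, <5% PTV), normalised.
DEFAULT_ANNOTATION_MIX = (0.25 / 0.915, 0.50 / 0.915, 0.125 / 0.915, 0.04 / 0.915)


@dataclass(frozen=True)
class StudySpec:
    """Target composition of one study.

    For ascertained studies (case-control assemblies) cases are rejection
    sampled until ``n_cases`` is reached; otherwise ``n_cases + n_referents``
    individuals are drawn from the population and labelled by liability, so
    the realised case count fluctuates binomially around ``K * n``.
    """

    n_cases: int
    n_referents: int
    case_ascertainment: bool = False

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_referents


@dataclass(frozen=True)
class EffectModel:
    """Per-allele liability effects by annotation class, within causal genes.

    ``between_study_sd`` adds independent N(0, sd) per-study perturbations to
    each class effect; the default of zero gives homogeneous effects across
    studies.
    """

    ptv: float = 0.0
    damaging_missense: float = 0.0
    benign_missense: float = 0.0
    synonymous: float = 0.0
    between_study_sd: float = 0.0

    def by_class(self) -> np.ndarray:
        return np.array([self.synonymous, self.benign_missense, self.damaging_missense, self.ptv])


@dataclass(frozen=True)
class CovariateModel:
    """Liability effects of standardised age, sex (0/1) and ancestry PCs."""

    age_beta: float = 0.3
    sex_beta: float = 0.25
    pc_betas: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)

    @property
    def n_pcs(self) -> int:
        return len(self.pc_betas)

    @property
    def liability_variance(self) -> float:
        # age and PCs are standard normal; sex is Bernoulli(1/2), centred
        return self.age_beta**2 + 0.25 * self.sex_beta**2 + float(np.sum(np.square(self.pc_betas)))


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic multi-study cohort."""

    n_genes: int = 200
    n_causal_genes: int = 0
    variants_per_gene: float = 8.0
    freq_range: tuple[float, float] = (1e-6, 1e-2)  # log-uniform spectrum
    annotation_mix: tuple[float, float, float, float] = DEFAULT_ANNOTATION_MIX
    effect_model: EffectModel = EffectModel()
    prevalence: float = 0.05
    studies: tuple[StudySpec, ...] = (
        StudySpec(n_cases=500, n_referents=9500, case_ascertainment=False),
        StudySpec(n_cases=2000, n_referents=2000, case_ascertainment=True),
    )
    covariate_model: CovariateModel = CovariateModel()
    n_chrx_genes: int = 0
    ptv_flagged_prob: float = 0.1
    tool_call_prob: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.variants_per_gene <= 0:
            raise ConfigurationError("need at least one gene and a positive variant count")
        if not (0.0 < self.prevalence < 0.5):
            raise ConfigurationError("prevalence K must lie in (0, 0.5)")
        if abs(sum(self.annotation_mix) - 1.0) > 1e-9 or min(self.annotation_mix) < 0:
            raise ConfigurationError("annotation_mix must be non-negative and sum to 1")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("allele frequencies must lie in (0, 0.5]")
        if len(self.studies) < 1:
            raise ConfigurationError("at least one study must be specified")
        if any(s.n_cases <= 0 or s.n_referents <= 0 for s in self.studies):
            raise ConfigurationError("study sizes must be positive")
        if not (0 <= self.n_causal_genes <= self.n_genes):
            raise ConfigurationError("n_causal_genes must not exceed n_genes")
        if self.n_chrx_genes > self.n_genes:
            raise ConfigurationError("n_chrx_genes must not exceed n_genes")


@dataclass
class StudyDataset:
    """One simulated study: genotypes, phenotype, covariates, variant table."""

    study_id: str
    genotypes: sp.csc_matrix  # samples x variants, dosages 0/1/2 (chrX males 0/1)
    variant_ids: tuple[str, ...]
    phenotype: np.ndarray  # 0/1 disease status
    covariates: pd.DataFrame  # age, sex, PC1..PCk
    variant_table: pd.DataFrame  # annotation schema + in_sample_freq
    causal_genes: tuple[str, ...]
    seed: int

    _variant_index: pd.Index | None = field(default=None, repr=False)

    @property
    def variant_index(self) -> pd.Index:
        if self._variant_index is None:
            self._variant_index = pd.Index(self.variant_ids)
        return self._variant_index

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_samples


def _draw_variant_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Shared variant catalogue: gene, position, class, frequency, tool calls."""
    n_var_per_gene = 1 + rng.poisson(max(config.variants_per_gene - 1.0, 0.0), size=config.n_genes)
    n_total = int(n_var_per_gene.sum())
    gene_idx = np.repeat(np.arange(config.n_genes), n_var_per_gene)
    genes = np.array([f"GENE{i:05d}" for i in range(config.n_genes)])
    n_auto = config.n_genes - config.n_chrx_genes
    chroms = np.array(
        [f"chr{1 + (i % 22)}" for i in range(n_auto)] + ["chrX"] * config.n_chrx_genes
    )
    klass = rng.choice(len(ANNOTATION_CLASSES), size=n_total, p=np.asarray(config.annotation_mix))
    lo, hi = config.freq_range
    freq = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_total))

    is_mis_damaging = klass == 2
    calls = np.zeros((n_total, 4), dtype=bool)
    calls[is_mis_damaging] = rng.random((int(is_mis_damaging.sum()), 4)) < config.tool_call_prob
    # a damaging missense variant is, by construction, called by >= 1 tool
    none_called = is_mis_damaging & ~calls.any(axis=1)
    if none_called.any():
        forced = rng.integers(0, 4, size=int(none_called.sum()))
        calls[np.flatnonzero(none_called), forced] = True

    is_ptv = klass == 3
    flagged = np.zeros(n_total, dtype=bool)
    flagged[is_ptv] = rng.random(int(is_ptv.sum())) < config.ptv_flagged_prob

    pos = 1 + np.arange(n_total)
    consequence = np.where(is_ptv, "PTV", np.where(klass >= 1, "missense", "synonymous"))
    # synonymous and benign missense carry no damaging calls
    calls[klass <= 1] = False

    table = pd.DataFrame(
        {
            "variant_id": [f"{chroms[g]}:{p}:A:G" for g, p in zip(gene_idx, pos)],
            "gene": genes[gene_idx],
            "chrom": chroms[gene_idx],
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "consequence": consequence,
            "sim_class": np.array(ANNOTATION_CLASSES)[klass],
            "loftee_hc": is_ptv,
            "loftee_flagged": flagged,
            "revel_damaging": calls[:, 0],
            "am_damaging": calls[:, 1],
            "pai3d_damaging": calls[:, 2],
            "popeve_damaging": calls[:, 3],
            "true_freq": freq,
        }
    )
    # reference super-population frequencies: the max equals the true frequency
    table["freq_nfe"] = freq
    for popname in ("afr", "sas", "eas", "amr"):
        table[f"freq_{popname}"] = freq * rng.uniform(0.2, 1.0, size=n_total)
    return table


def _causal_effects(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[tuple[str, ...], np.ndarray]:
    """Pick causal genes and assign per-variant per-allele liability effects."""
    genes = truth["gene"].unique()
    causal = tuple(rng.choice(genes, size=config.n_causal_genes, replace=False)) if config.n_causal_genes else ()
    beta = np.zeros(len(truth))
    if causal:
        class_beta = dict(zip(ANNOTATION_CLASSES, config.effect_model.by_class()))
        in_causal = truth["gene"].isin(causal).to_numpy()
        beta[in_causal] = truth.loc[in_causal, "sim_class"].map(class_beta).to_numpy()
    return causal, beta


def _sample_distinct(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct sample indices out of n, efficient for k << n."""
    if k >= n:
        return rng.permutation(n)[:k]
    idx = np.unique(rng.integers(0, n, size=int(k * 1.3) + 8))
    while idx.size < k:
        idx = np.unique(np.concatenate([idx, rng.integers(0, n, size=k)]))
    return rng.permutation(idx)[:k]


def _draw_genotype_block(
    rng: np.random.Generator,
    n_samples: int,
    freqs: np.ndarray,
    haploid: np.ndarray | None = None,
) -> sp.csc_matrix:
    """Independent dosages per sample and variant: Binomial(2, p) (or (1, p))."""
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for j, p in enumerate(freqs):
        if haploid is not None and haploid[j]:
            n1 = rng.binomial(n_samples, p)
            n2 = 0
        else:
            q1, q2 = 2 * p * (1 - p), p * p
            n1, n2 = rng.multinomial(n_samples, [1 - q1 - q2, q1, q2])[1:]
        k = n1 + n2
        if k == 0:
            continue
        idx = _sample_distinct(rng, n_samples, k)
        rows.append(idx)
        cols.append(np.full(k, j, dtype=np.int32))
        d = np.ones(k, dtype=np.int8)
        d[n1:] = 2
        data.append(d)
    if rows:
        mat = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_samples, len(freqs)),
            dtype=np.int8,
        )
        return mat.tocsc()
    return sp.csc_matrix((n_samples, len(freqs)), dtype=np.int8)


def _draw_covariates(rng: np.random.Generator, n: int, cov: CovariateModel) -> pd.DataFrame:
    data = {"age": rng.normal(0.0, 1.0, n), "sex": rng.integers(0, 2, n).astype(np.int8)}
    for k in range(cov.n_pcs):
        data[f"PC{k + 1}"] = rng.normal(0.0, 1.0, n)
    return pd.DataFrame(data)


def _covariate_liability(cov_df: pd.DataFrame, cov: CovariateModel) -> np.ndarray:
    lia = cov.age_beta * cov_df["age"].to_numpy() + cov.sex_beta * (cov_df["sex"].to_numpy() - 0.5)
    for k, b in enumerate(cov.pc_betas):
        if b:
            lia = lia + b * cov_df[f"PC{k + 1}"].to_numpy()
    return lia


def _liability_threshold(config: SimulationConfig, beta: np.ndarray, freqs: np.ndarray) -> float:
    """Case threshold so that P(liability > tau) = K under a normal total."""
    genetic_var = float(np.sum(2 * freqs * (1 - freqs) * beta**2))
    total_sd = float(np.sqrt(1.0 + config.covariate_model.liability_variance + genetic_var))
    return norm.isf(config.prevalence) * total_sd


def simulate_cohort(
    config: SimulationConfig,
    study_index: int,
    _truth: pd.DataFrame | None = None,
    _causal: tuple[tuple[str, ...], np.ndarray] | None = None,
) -> StudyDataset:
    """Simulate one study of the configured multi-study design.

    The variant catalogue and causal-gene truth are deterministic functions of
    ``config.seed`` and shared across studies; genotype, covariate and
    phenotype draws are independent per study.
    """
    if study_index >= len(config.studies):
        raise ConfigurationError(f"study_index {study_index} out of range")
    ss = np.random.SeedSequence(config.seed)
    truth_seed, *study_seeds = ss.spawn(len(config.studies) + 1)
    if _truth is None or _causal is None:
        truth_rng = np.random.default_rng(truth_seed)
        _truth = _draw_variant_truth(config, truth_rng)
        _causal = _causal_effects(config, _truth, truth_rng)
    causal_genes, beta = _causal
    rng = np.random.default_rng(study_seeds[study_index])
    spec = config.studies[study_index]

    if config.effect_model.between_study_sd > 0 and causal_genes:
        jitter = rng.normal(0.0, config.effect_model.between_study_sd, size=beta.shape)
        beta = np.where(beta != 0.0, beta + jitter, beta)

    freqs = _truth["true_freq"].to_numpy()
    is_chrx = (_truth["chrom"] == "chrX").to_numpy()
    tau = _liability_threshold(config, beta, freqs)
    causal_cols = np.flatnonzero(beta != 0.0)

    if spec.case_ascertainment:
        geno, cov_df, pheno = _ascertained_draw(
            rng, config, spec, freqs, beta, causal_cols, is_chrx, tau
        )
    else:
        n = spec.n_total
        cov_df = _draw_covariates(rng, n, config.covariate_model)
        sexes = cov_df["sex"].to_numpy()
        geno = _draw_genotype_block(rng, n, freqs, haploid=None)
        if is_chrx.any():
            geno = _apply_male_haploidy(geno, is_chrx, sexes)
        g_lia = np.zeros(n)
        if causal_cols.size:
            g_lia = np.asarray(geno[:, causal_cols] @ beta[causal_cols]).ravel()
        lia = g_lia + _covariate_liability(cov_df, config.covariate_model) + rng.normal(0.0, 1.0, n)
        pheno = (lia > tau).astype(np.int8)

    table = _truth.copy()
    counts = np.asarray(geno.sum(axis=0)).ravel()
    denom = np.where(is_chrx, geno.shape[0] + (cov_df["sex"].to_numpy() == 0).sum(), 2.0 * geno.shape[0])
    table["in_sample_freq"] = counts / denom
    return StudyDataset(
        study_id=f"study{study_index}",
        genotypes=geno.tocsc(),
        variant_ids=tuple(table["variant_id"]),
        phenotype=pheno,
        covariates=cov_df,
        variant_table=table,
        causal_genes=causal_genes,
        seed=config.seed,
    )


def _apply_male_haploidy(geno: sp.csc_matrix, is_chrx: np.ndarray, sexes: np.ndarray) -> sp.csc_matrix:
    """Clip male dosages on chrX variants to 0/1."""
    geno = geno.tocsr()
    male_rows = np.flatnonzero(sexes == 1)
    sub = geno[male_rows][:, is_chrx]
    if sub.nnz:
        lil = geno.tolil()
        xcols = np.flatnonzero(is_chrx)
        dense = np.minimum(sub.toarray(), 1)
        for i, r in enumerate(male_rows):
            lil[r, xcols] = dense[i]
        geno = lil.tocsr()
    return geno.tocsc()


def _ascertained_draw(rng, config, spec, freqs, beta, causal_cols, is_chrx, tau):
    """Rejection-sample cases/referents to target counts.

    Liability depends only on causal-gene genotypes, so candidate batches draw
    those columns only; non-causal genotypes are drawn once for the selected
    samples.
    """
    need_cases, need_refs = spec.n_cases, spec.n_referents
    kept_cov: list[pd.DataFrame] = []
    kept_causal: list[np.ndarray] = []
    kept_pheno: list[np.ndarray] = []
    n_cases = n_refs = 0
    batch = max(int(spec.n_cases / max(config.prevalence, 1e-3)) // 4 + 1000, 2000)
    guard = 0
    while (n_cases < need_cases or n_refs < need_refs) and guard < 10_000:
        guard += 1
        cov_df = _draw_covariates(rng, batch, config.covariate_model)
        if causal_cols.size:
            sub = _draw_genotype_block(rng, batch, freqs[causal_cols]).toarray()
            if is_chrx[causal_cols].any():
                male = cov_df["sex"].to_numpy() == 1
                xc = is_chrx[causal_cols]
                sub[np.ix_(male, xc)] = np.minimum(sub[np.ix_(male, xc)], 1)
            g_lia = sub @ beta[causal_cols]
        else:
            sub = np.zeros((batch, 0), dtype=np.int8)
            g_lia = np.zeros(batch)
        lia = g_lia + _covariate_liability(cov_df, config.covariate_model) + rng.normal(0.0, 1.0, batch)
        case = lia > tau
        take_case = np.flatnonzero(case)[: need_cases - n_cases]
        take_ref = np.flatnonzero(~case)[: need_refs - n_refs]
        take = np.concatenate([take_case, take_ref])
        kept_cov.append(cov_df.iloc[take])
        kept_causal.append(sub[take])
        kept_pheno.append(case[take].astype(np.int8))
        n_cases += take_case.size
        n_refs += take_ref.size
    cov_df = pd.concat(kept_cov, ignore_index=True)
    pheno = np.concatenate(kept_pheno)
    causal_geno = np.vstack(kept_causal) if causal_cols.size else None
    n = len(pheno)
    null_cols = np.setdiff1d(np.arange(len(freqs)), causal_cols)
    geno_null = _draw_genotype_block(rng, n, freqs[null_cols])
    if causal_geno is not None and causal_cols.size:
        stacked = sp.hstack([geno_null, sp.csc_matrix(causal_geno)], format="csc")
        perm = np.argsort(np.concatenate([null_cols, causal_cols]))
        geno = stacked[:, perm]
    else:
        geno = geno_null
    if is_chrx.any():
        geno = _apply_male_haploidy(geno, is_chrx, cov_df["sex"].to_numpy())
    return geno, cov_df, pheno


def simulate_multi_study(config: SimulationConfig) -> list[StudyDataset]:
    """Simulate every configured study with shared variant truth."""
    ss = np.random.SeedSequence(config.seed)
    truth_seed = ss.spawn(len(config.studies) + 1)[0]
    truth_rng = np.random.default_rng(truth_seed)
    truth = _draw_variant_truth(config, truth_rng)
    causal = _causal_effects(config, truth, truth_rng)
    return [
        simulate_cohort(config, i, _truth=truth, _causal=causal)
        for i in range(len(config.studies))
    ]


def simulate_gwas_annotations(
    gene_truth: dict[str, bool] | pd.DataFrame,
    enrichment: float = 1.0,
    seed: int = 0,
    base_locus_prob: float = 0.15,
    base_evidence_prob: float = 0.25,
) -> pd.DataFrame:
    """Synthetic GWAS gene table with tunable causal-gene enrichment.

    ``gene_truth`` maps gene -> is-causal (or a frame with ``gene`` and
    ``causal`` columns).  Causal genes fall within a GWAS locus with odds
    ``enrichment``-fold those of null genes; prioritisation scores (0-5) for
    in-locus genes count successes of five evidence lines whose per-line odds
    are scaled the same way, so every score threshold carries the configured
    enrichment.  Genes outside loci always score 0.
    """
    if enrichment < 1.0:
        raise ConfigurationError("enrichment must be >= 1")
    if isinstance(gene_truth, pd.DataFrame):
        genes = gene_truth["gene"].to_numpy()
        causal = gene_truth["causal"].to_numpy(bool)
    else:
        genes = np.array(list(gene_truth))
        causal = np.array([gene_truth[g] for g in genes], dtype=bool)
    rng = np.random.default_rng(seed)

    def scaled(p0: float) -> float:
        odds = enrichment * p0 / (1 - p0)
        return odds / (1 + odds)

    p_locus = np.where(causal, scaled(base_locus_prob), base_locus_prob)
    in_locus = rng.random(len(genes)) < p_locus
    p_line = np.where(causal, scaled(base_evidence_prob), base_evidence_prob)
    score = rng.binomial(5, p_line)
    score[~in_locus] = 0
    return pd.DataFrame({"gene": genes, "in_locus": in_locus, "geneprio_score": score})
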