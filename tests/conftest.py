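import math

import numpy as np
import pandas as pd
import pytest

from rvburden import SimulationConfig, StudySpec, EffectModel, simulate_multi_study


def summary_sim(
    n_genes=5000, h2=0.02, frac_causal=0.05, n_samples=400_000, seed=0,
    concentrated_gene=None, bin_label="ultrarare.PTV",
):
    """Summary-statistic simulation with known burden heritability.

    Per-gene burden scores gamma are drawn from a realistic rare-variant
    range; causal genes share a common squared per-allele effect scaled so
    the total variance explained equals ``h2``.  alpha_hat = alpha + noise
    with se = 1/sqrt(n).  Optionally one gene carries a fixed fraction of
    the total heritability.
    """
    rng = np.random.default_rng(seed)
    gamma = 10 ** rng.uniform(-6, -4.5, n_genes)
    alpha2 = np.zeros(n_genes)
    causal = rng.choice(n_genes, int(frac_causal * n_genes), replace=False)
    h2_bulk = h2
    genes = np.array([f"G{i}" for i in range(n_genes)])
    if concentrated_gene is not None:
        name, frac = concentrated_gene
        h2_bulk = h2 * (1 - frac)
    if causal.size:
        tau = h2_bulk / gamma[causal].sum()  # common squared per-allele effect
        alpha2[causal] = tau * gamma[causal]
    if concentrated_gene is not None:
        name, frac = concentrated_gene
        j = int(np.flatnonzero(genes == name)[0])
        alpha2[j] = h2 * frac
    se = 1.0 / math.sqrt(n_samples)
    alpha = rng.choice([-1, 1], n_genes) * np.sqrt(alpha2)
    alpha_hat = alpha + rng.normal(0, se, n_genes)
    return pd.DataFrame({
        "gene": genes, "bin": bin_label, "gamma": gamma,
        "alpha_hat": alpha_hat, "se": se, "cmac": 100,
    })


def make_variant_frame(rows):
    """Variant annotation frame from compact tuples.

    Each row: (variant_id, gene, consequence, loftee_flagged,
    (revel, am, pai3d, popeve), freq).
    """
    recs = []
    for vid, gene, cons, flagged, calls, freq in rows:
        recs.append(
            dict(
                variant_id=vid, gene=gene, chrom="chr1", pos=len(recs) + 1,
                ref="A", alt="G", consequence=cons,
                loftee_hc=cons == "PTV", loftee_flagged=flagged,
                revel_damaging=bool(calls[0]), am_damaging=bool(calls[1]),
                pai3d_damaging=bool(calls[2]), popeve_damaging=bool(calls[3]),
                freq_nfe=freq,
            )
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def full_gene_variants():
    """A gene populated in every annotation class at an ultra-rare frequency."""
    return make_variant_frame(
        [
            ("v0", "G1", "PTV", False, (0, 0, 0, 0), 5e-7),
            ("v1", "G1", "PTV", True, (0, 0, 0, 0), 5e-7),
            ("v2", "G1", "missense", False, (1, 1, 1, 1), 5e-7),
            ("v3", "G1", "missense", False, (1, 0, 0, 0), 5e-7),
            ("v4", "G1", "missense", False, (0, 1, 0, 0), 5e-7),
            ("v5", "G1", "missense", False, (0, 0, 1, 0), 5e-7),
            ("v6", "G1", "missense", False, (0, 0, 0, 1), 5e-7),
            ("v7", "G1", "synonymous", False, (0, 0, 0, 0), 5e-7),
        ]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Two small studies with a handful of causal genes, for pipeline tests."""
    config = SimulationConfig(
        n_genes=60,
        n_causal_genes=8,
        variants_per_gene=10.0,
        effect_model=EffectModel(ptv=0.9, damaging_missense=0.6),
        freq_range=(3e-4, 5e-3),
        prevalence=0.1,
        studies=(
            StudySpec(n_cases=500, n_referents=4500, case_ascertainment=False),
            StudySpec(n_cases=1500, n_referents=1500, case_ascertainment=True),
        ),
        seed=42,
    )
    return config, simulate_multi_study(config)
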