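"""Variant mask construction for gene-based burden testing.

A *mask* pools the rare variants of one gene that satisfy an annotation
criterion (protein-truncating, predicted-damaging missense, or a union of
both) and a frequency criterion on the maximum population minor allele
frequency (MAF_max).  Twenty annotation groups crossed with three nested
frequency tiers give up to sixty masks per gene:

* two PTV groups: all high-confidence PTVs (``PTV``) and the stricter set
  without LOFTEE flags (``PTVnoflag``);
* six missense groups: one per prediction tool (REVEL, AlphaMissense,
  PrimateAI-3D, popEVE), plus variants called damaging by at least one
  (``miss1of4``) or at least three (``miss3of4``) of the four tools;
* the twelve pairwise unions of a PTV group with a missense group.

Frequency tiers are ultra-rare (``UR``, MAF_max < 1e-5), rare (``R``,
MAF_max < 1e-3) and rare+low-frequency (``RL``, MAF_max < 1e-2); the tiers
are nested (UR ⊆ R ⊆ RL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AnnotationError, DataConsistencyError

__all__ = [
    "ANNOTATION_GROUPS",
    "FREQ_TIERS",
    "LAYER_OF_GROUP",
    "MISSENSE_GROUPS",
    "PTV_GROUPS",
    "VariantRecord",
    "MaskDefinition",
    "BurdenGenotype",
    "fold_frequency",
    "compute_maf_max",
    "add_maf_max",
    "enumerate_masks",
    "enumerate_masks_all_genes",
    "build_burden_genotype",
]

#: Boolean annotation column behind each single-tool missense group.
MISSENSE_TOOL_COLUMNS = {
    "missREVEL": "revel_damaging",
    "missAM": "am_damaging",
    "missPAI3D": "pai3d_damaging",
    "missPopEVE": "popeve_damaging",
}

MISSENSE_GROUPS = tuple(MISSENSE_TOOL_COLUMNS) + ("miss1of4", "miss3of4")
PTV_GROUPS = ("PTV", "PTVnoflag")

#: The 20 annotation groups: 2 PTV + 6 missense + 12 PTV×missense unions.
ANNOTATION_GROUPS = (
    PTV_GROUPS
    + MISSENSE_GROUPS
    + tuple(f"{p}+{m}" for p in PTV_GROUPS for m in MISSENSE_GROUPS)
)

#: Frequency tiers as strict upper bounds on MAF_max, in nesting order.
FREQ_TIERS = {"UR": 1e-5, "R": 1e-3, "RL": 1e-2}

#: Cauchy combination layer of each annotation group.
LAYER_OF_GROUP = {
    g: ("PTV" if g in PTV_GROUPS else "missense" if g in MISSENSE_GROUPS else "PTV+missense")
    for g in ANNOTATION_GROUPS
}


@dataclass
class VariantRecord:
    """One annotated rare variant on a canonical transcript."""

    variant_id: str
    gene: str
    chrom: str
    consequence: str  # one of {"synonymous", "missense", "PTV"}
    loftee_flagged: bool = False
    damaging_calls: Mapping[str, bool] = field(default_factory=dict)
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    in_sample_freq: float | None = None

    def __post_init__(self) -> None:
        if self.consequence not in ("synonymous", "missense", "PTV"):
            raise AnnotationError(f"unknown consequence {self.consequence!r}")
        if self.consequence != "missense" and any(self.damaging_calls.values()):
            raise AnnotationError(
                f"{self.variant_id}: damaging tool calls are only meaningful for missense variants"
            )


@dataclass(frozen=True)
class MaskDefinition:
    """One (annotation group × frequency tier) variant pooling for a gene."""

    gene: str
    annotation_group: str
    freq_tier: str
    member_variants: tuple[str, ...]

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.gene, self.annotation_group, self.freq_tier)

    @property
    def layer(self) -> str:
        return LAYER_OF_GROUP[self.annotation_group]


@dataclass
class BurdenGenotype:
    """Per-sample burden coding of a mask within one study."""

    mask: MaskDefinition
    study_id: str
    carrier_vector: np.ndarray
    cmac: int
    n_carriers: int


def fold_frequency(freq: float | np.ndarray) -> float | np.ndarray:
    """Fold an allele frequency onto the minor allele, i.e. ``min(f, 1 - f)``."""
    return np.minimum(freq, 1.0 - np.asarray(freq))


def compute_maf_max(variant: VariantRecord, use_insample: bool = True) -> float:
    """Maximum minor allele frequency across reference populations and the study.

    Reference super-population frequencies and (optionally) the in-sample
    frequency are folded to minor-allele frequencies and the maximum is
    returned.  With no reference frequencies the in-sample frequency alone is
    used (the mode for cohorts analysed without external references).
    """
    sources = [fold_frequency(f) for f in variant.pop_freqs.values()]
    if use_insample and variant.in_sample_freq is not None:
        sources.append(fold_frequency(variant.in_sample_freq))
    if not sources:
        raise AnnotationError(f"{variant.variant_id}: no allele-frequency source available")
    return float(max(sources))


def _freq_columns(variants: pd.DataFrame) -> list[str]:
    return [c for c in variants.columns if c.startswith("freq_")]


def add_maf_max(variants: pd.DataFrame, use_insample: bool = True) -> pd.DataFrame:
    """Vectorised MAF_max over a variant table; adds/overwrites ``maf_max``.

    Population frequency columns are those named ``freq_*``; the in-sample
    frequency column is ``in_sample_freq`` when present.
    """
    cols = _freq_columns(variants)
    sources = []
    for c in cols:
        sources.append(fold_frequency(variants[c].to_numpy(float)))
    if use_insample and "in_sample_freq" in variants.columns:
        sources.append(fold_frequency(variants["in_sample_freq"].to_numpy(float)))
    if not sources:
        raise AnnotationError("variant table has no freq_* or in_sample_freq columns")
    out = variants.copy()
    out["maf_max"] = np.max(np.vstack(sources), axis=0)
    return out


def _group_membership(variants: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean membership of every variant in each of the 20 annotation groups."""
    cons = variants["consequence"].to_numpy()
    is_ptv = cons == "PTV"
    is_mis = cons == "missense"
    flagged = variants["loftee_flagged"].to_numpy(bool) if "loftee_flagged" in variants else np.zeros(len(variants), bool)

    calls = np.column_stack(
        [variants[c].to_numpy(bool) if c in variants else np.zeros(len(variants), bool)
         for c in MISSENSE_TOOL_COLUMNS.values()]
    )
    n_calls = calls.sum(axis=1)

    member: dict[str, np.ndarray] = {
        "PTV": is_ptv,
        "PTVnoflag": is_ptv & ~flagged,
        "miss1of4": is_mis & (n_calls >= 1),
        "miss3of4": is_mis & (n_calls >= 3),
    }
    for j, name in enumerate(MISSENSE_TOOL_COLUMNS):
        member[name] = is_mis & calls[:, j]
    for p in PTV_GROUPS:
        for m in MISSENSE_GROUPS:
            member[f"{p}+{m}"] = member[p] | member[m]
    return member


def enumerate_masks(
    variants: pd.DataFrame,
    tiers: Mapping[str, float] | None = None,
) -> list[MaskDefinition]:
    """Enumerate every non-empty (annotation group × tier) mask for one gene.

    ``variants`` must carry the annotation columns and ``maf_max`` and contain
    a single gene.  Synonymous variants never qualify for any group, so a
    gene with only synonymous variation yields an empty list.
    """
    genes = variants["gene"].unique()
    if len(genes) > 1:
        raise DataConsistencyError(f"enumerate_masks expects one gene, got {list(genes)}")
    if len(genes) == 0:
        return []
    return enumerate_masks_all_genes(variants, tiers=tiers)


def enumerate_masks_all_genes(
    variants: pd.DataFrame,
    tiers: Mapping[str, float] | None = None,
) -> list[MaskDefinition]:
    """Enumerate masks for every gene in an annotated variant table."""
    if tiers is None:
        tiers = FREQ_TIERS
    if "maf_max" not in variants.columns:
        variants = add_maf_max(variants)
    masks: list[MaskDefinition] = []
    ids_all = variants["variant_id"].to_numpy()
    maf = variants["maf_max"].to_numpy(float)
    membership = _group_membership(variants)
    gene_codes, gene_names = pd.factorize(variants["gene"].to_numpy())
    order = np.argsort(gene_codes, kind="stable")
    bounds = np.searchsorted(gene_codes[order], np.arange(len(gene_names) + 1))
    tier_ok = {t: maf < thr for t, thr in tiers.items()}
    for gi, gene in enumerate(gene_names):
        rows = order[bounds[gi]:bounds[gi + 1]]
        for group in ANNOTATION_GROUPS:
            in_group = membership[group][rows]
            if not in_group.any():
                continue
            grows = rows[in_group]
            parts = None
            if "+" in group:
                pg, mg = group.split("+")
                parts = (membership[pg], membership[mg])
            for tier in tiers:
                sel = grows[tier_ok[tier][grows]]
                if sel.size == 0:
                    continue
                if parts is not None:
                    # a union mask must draw from both components in this
                    # tier, otherwise it duplicates the single-class mask
                    if not (parts[0][sel].any() and parts[1][sel].any()):
                        continue
                masks.append(
                    MaskDefinition(
                        gene=str(gene),
                        annotation_group=group,
                        freq_tier=tier,
                        member_variants=tuple(ids_all[sel]),
                    )
                )
    return masks


def build_burden_genotype(
    mask: MaskDefinition,
    study,
    coding: str = "carrier",
    sample_rows: np.ndarray | None = None,
) -> BurdenGenotype:
    """Collapse a mask's member variants into a per-sample burden genotype.

    With carrier coding (the default) the burden is the 0/1 indicator of
    carrying at least one minor allele in any member variant; with sum
    coding it is the total minor allele count per sample.  ``cmac`` is
    always the cumulative minor allele count over members and samples.
    """
    if coding not in ("carrier", "sum"):
        raise ValueError(f"unknown burden coding {coding!r}")
    index = study.variant_index
    cols = index.get_indexer(list(mask.member_variants))
    if (cols < 0).any():
        missing = [v for v, c in zip(mask.member_variants, cols) if c < 0]
        raise DataConsistencyError(
            f"mask {mask.key} members absent from study {study.study_id}: {missing[:5]}"
        )
    sub = study.genotypes[:, cols]
    if sample_rows is not None:
        sub = sub[sample_rows, :]
    allele_sum = np.asarray(sub.sum(axis=1)).ravel()
    cmac = int(allele_sum.sum())
    if coding == "carrier":
        vec = (allele_sum >= 1).astype(np.int8)
    else:
        vec = allele_sum.astype(np.int32)
    n_carriers = int((allele_sum >= 1).sum())
    return BurdenGenotype(
        mask=mask,
        study_id=study.study_id,
        carrier_vector=vec,
        cmac=cmac,
        n_carriers=n_carriers,
    )


def masks_to_frame(masks: Iterable[MaskDefinition]) -> pd.DataFrame:
    """Tabular mask export: gene, group, tier, member count and id list."""
    rows = [
        {
            "gene": m.gene,
            "annotation_group": m.annotation_group,
            "freq_tier": m.freq_tier,
            "n_variants": len(m.member_variants),
            "variant_ids": ";".join(m.member_variants),
        }
        for m in masks
    ]
    return pd.DataFrame(rows, columns=["gene", "annotation_group", "freq_tier", "n_variants", "variant_ids"])
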