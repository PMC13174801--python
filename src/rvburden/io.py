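"""File formats: VCF and TSV genotypes, annotation tables, phenotypes, configs.

The interchange dialect is TSV (tab-separated, header row, UTF-8, '.'
decimal).  Genotypes move as VCF 4.2 (GT field, 1-based positions) or as a
dense TSV with one sample per row and one variant per column.  Variant keys
are ``chrom:pos:ref:alt`` strings.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .masks import fold_frequency

__all__ = [
    "write_vcf",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_annotations",
    "write_phenotypes",
    "read_phenotypes",
    "load_yaml_config",
]

logger = logging.getLogger(__name__)

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}

ANNOTATION_REQUIRED = [
    "variant_id", "gene", "chrom", "pos", "ref", "alt", "consequence",
    "loftee_hc", "loftee_flagged",
    "revel_damaging", "am_damaging", "pai3d_damaging", "popeve_damaging",
]

_BOOL_STRINGS = {
    "true": True, "false": False, "1": True, "0": False,
    "t": True, "f": False, "yes": True, "no": False,
}


def write_vcf(study, path) -> None:
    """Write a study's genotypes as a minimal VCF 4.2 text file."""
    path = Path(path)
    vt = study.variant_table
    dense = np.asarray(study.genotypes.todense(), dtype=np.int8)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=rvburden simulate seed={study.seed}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = [f"S{i:06d}" for i in range(study.n_samples)]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, (_, row) in enumerate(vt.iterrows()):
            gts = "\t".join(_GT_STRINGS[int(d)] for d in dense[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotypes(path, fmt: str | None = None):
    """Read a genotype matrix from VCF or TSV.

    Returns ``(matrix, variant_keys, sample_ids)`` with dosages 0/1/2 in an
    int8 sample x variant array.  Missing VCF genotypes are set to dosage 0
    with the count logged.  Variant keys are chrom:pos:ref:alt.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df.to_numpy(dtype=np.int8), list(df.columns), list(df.index.astype(str))
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    keys: list[str] = []
    n_missing = 0
    for v in vcf:
        gt = np.asarray(v.gt_types, dtype=np.int8)
        miss = gt == 3
        if miss.any():
            n_missing += int(miss.sum())
            gt = np.where(miss, 0, gt)
        cols.append(gt)
        alt = v.ALT[0] if v.ALT else "."
        keys.append(f"{v.CHROM}:{v.POS}:{v.REF}:{alt}")
    if n_missing:
        logger.warning("%s: %d missing genotypes treated as reference", path, n_missing)
    if not cols:
        logger.warning("%s: empty VCF body", path)
        return np.empty((len(samples), 0), dtype=np.int8), [], samples
    return np.column_stack(cols), keys, samples


def write_genotypes_tsv(study, path) -> None:
    """Dense TSV genotype export: rows samples, columns variant ids."""
    dense = np.asarray(study.genotypes.todense(), dtype=np.int8)
    df = pd.DataFrame(dense, columns=list(study.variant_ids))
    df.index = [f"S{i:06d}" for i in range(study.n_samples)]
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def _parse_bool_column(series: pd.Series, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    out = []
    bad: list[int] = []
    for i, v in enumerate(series):
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        elif isinstance(v, (int, np.integer)) and v in (0, 1):
            out.append(bool(v))
        else:
            key = str(v).strip().lower()
            if key in _BOOL_STRINGS:
                out.append(_BOOL_STRINGS[key])
            else:
                bad.append(i)
                out.append(False)
    if bad:
        raise SchemaError(f"column {name!r}: unparseable booleans at rows {bad[:10]}")
    return pd.Series(out, index=series.index)


def read_annotations(path) -> pd.DataFrame:
    """Read and validate a variant annotation table.

    Enforces the documented schema: required columns present, booleans
    strictly parseable, at least one ``freq_*`` column, frequencies folded
    to the minor allele (values above 0.5 are folded with a notice), and no
    damaging tool call on a non-missense variant.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation table missing columns: {missing}")
    freq_cols = [c for c in df.columns if c.startswith("freq_")]
    if not freq_cols:
        raise SchemaError("annotation table has no freq_* columns")
    for c in ("loftee_hc", "loftee_flagged", "revel_damaging", "am_damaging",
              "pai3d_damaging", "popeve_damaging"):
        df[c] = _parse_bool_column(df[c], c)
    bad_cons = ~df["consequence"].isin(["synonymous", "missense", "PTV"])
    if bad_cons.any():
        raise SchemaError(f"unknown consequence values at rows {list(df.index[bad_cons])[:10]}")
    calls = df[["revel_damaging", "am_damaging", "pai3d_damaging", "popeve_damaging"]].any(axis=1)
    offenders = (df["consequence"] != "missense") & calls
    if offenders.any():
        raise SchemaError(
            "damaging tool calls on non-missense variants at rows "
            f"{list(df.index[offenders])[:10]}"
        )
    for c in freq_cols:
        f = df[c].to_numpy(float)
        if np.any((f < 0) | (f > 1)):
            raise SchemaError(f"column {c}: frequencies must lie in [0, 1]")
        folded = f > 0.5
        if folded.any():
            logger.info("%s: folded %d frequencies above 0.5 to the minor allele", c, int(folded.sum()))
            df[c] = fold_frequency(f)
    return df


def write_phenotypes(study, path) -> None:
    df = study.covariates.copy()
    df.insert(0, "sample_id", [f"S{i:06d}" for i in range(study.n_samples)])
    df.insert(1, "af_status", study.phenotype)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "af_status"}
    if not required <= set(df.columns):
        raise SchemaError(f"phenotype table must have columns {sorted(required)}")
    if not set(df["af_status"].unique()) <= {0, 1}:
        raise SchemaError("af_status must be binary 0/1")
    return df


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("configuration file must be a YAML mapping")
    return cfg
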