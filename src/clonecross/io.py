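"""Readers and writers for genotype matrices and sample metadata.

Three input formats are supported: a plain samples x loci CSV of dosage
codes, the one-row-per-SNP DArT report dialect, and VCF (biallelic sites
only). All converge on the same :class:`~clonecross.matrix.GenotypeMatrix`
container; only the plain CSV is written back.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import (
    MISSING,
    GenotypeError,
    GenotypeMatrix,
    default_locus_meta,
    validate_sample_metadata,
)

# DArT one-row SNP report: genotype coding is 0 = homozygous reference,
# 1 = homozygous alternate, 2 = heterozygous, "-" = missing.
_DART_CODE_MAP = {"0": 0, "1": 2, "2": 1, "-": MISSING}
_DART_META_COLUMNS = {"CloneID": "fragment_id", "RepAvg": "reproducibility", "AvgDepth": "mean_read_depth"}
_DART_OPTIONAL_COLUMNS = ("AlleleID", "SnpPosition", "CallRate")


def read_genotype_csv(path: str | os.PathLike, missing_token: str = "NA") -> GenotypeMatrix:
    """Read a plain samples x loci CSV of dosage codes.

    Header row holds locus ids; first column holds sample ids. Cells must
    be ``0``, ``1``, ``2`` or *missing_token* — anything else is a hard
    error naming the offending cell, never a silent missing call.
    """
    df = pd.read_csv(path, dtype=str, index_col=0, keep_default_na=False)
    sample_ids = [str(s) for s in df.index]
    locus_ids = [str(l) for l in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise GenotypeError(f"{path}: duplicate sample ids")
    if len(set(locus_ids)) != len(locus_ids):
        raise GenotypeError(f"{path}: duplicate locus ids")
    calls = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy(dtype=str)
    code_map = {"0": 0, "1": 1, "2": 2, missing_token: MISSING}
    for (i, j), cell in np.ndenumerate(values):
        cell = cell.strip()
        try:
            calls[i, j] = code_map[cell]
        except KeyError:
            raise GenotypeError(
                f"{path}: unparseable genotype {cell!r} at sample "
                f"{sample_ids[i]!r}, locus {locus_ids[j]!r}"
            ) from None
    gm = GenotypeMatrix(sample_ids, locus_ids, calls)
    return gm.with_recomputed_call_rates()


def write_genotype_csv(
    gm: GenotypeMatrix, path: str | os.PathLike, missing_token: str = "NA"
) -> None:
    gm.to_frame(missing_token).to_csv(path, index_label="sample_id")


def write_locus_meta_csv(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    gm.locus_meta.to_csv(path, index_label="locus_id")


def read_dart_report(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a one-row-per-SNP DArT-style report.

    Required metadata columns: ``CloneID`` (fragment grouping primary SNPs
    with secondaries), ``RepAvg`` (reproducibility) and ``AvgDepth`` (mean
    read depth). Every remaining, non-recognised column is treated as a
    sample. Genotypes use the native DArT coding (0 hom-ref, 1 hom-alt,
    2 het, ``-`` missing) and are remapped to dosage codes.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _DART_META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise GenotypeError(f"{path}: DArT report lacks required columns: {missing_cols}")
    meta_cols = set(_DART_META_COLUMNS) | set(_DART_OPTIONAL_COLUMNS)
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise GenotypeError(f"{path}: no per-sample genotype columns found")

    if "AlleleID" in df.columns:
        locus_ids = [str(v) for v in df["AlleleID"]]
    else:
        locus_ids = [f"{cid}_{i}" for i, cid in enumerate(df["CloneID"])]

    calls = np.empty((len(sample_cols), len(df)), dtype=np.int8)
    raw = df[sample_cols].to_numpy(dtype=str)
    for (row, col), cell in np.ndenumerate(raw):
        cell = cell.strip()
        try:
            calls[col, row] = _DART_CODE_MAP[cell]
        except KeyError:
            raise GenotypeError(
                f"{path}: unparseable DArT genotype {cell!r} at sample "
                f"{sample_cols[col]!r}, locus {locus_ids[row]!r}"
            ) from None

    meta = pd.DataFrame(
        {
            "fragment_id": df["CloneID"].astype(str).to_numpy(),
            "reproducibility": df["RepAvg"].astype(float).to_numpy(),
            "mean_read_depth": df["AvgDepth"].astype(float).to_numpy(),
            "call_rate": np.ones(len(df)),
        },
        index=locus_ids,
    )
    gm = GenotypeMatrix(sample_cols, locus_ids, calls, meta)
    return gm.with_recomputed_call_rates()


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read biallelic sites from a VCF into dosage codes.

    Multi-allelic records are rejected with a hard error (the downstream
    statistics are defined for biallelic SNPs only); phase is ignored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split or drop it upstream"
            )
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = rec.gt_types
        codes = np.where(gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING)))
        locus_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
        rows.append(codes.astype(np.int8))
    if not rows:
        raise GenotypeError(f"{path}: VCF contains no variant records")
    calls = np.stack(rows, axis=1)
    gm = GenotypeMatrix(sample_ids, locus_ids, calls, default_locus_meta(locus_ids))
    return gm.with_recomputed_call_rates()


def read_sample_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a sample metadata CSV.

    Required columns: sample_id, species, group; optional patch, sex.
    """
    return validate_sample_metadata(pd.read_csv(path, dtype=str, keep_default_na=False))


def write_sample_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, index=False)
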