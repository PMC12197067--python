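"""Observed/expected heterozygosity and the inbreeding coefficient F_IS.

Conventions: per-locus observed heterozygosity is the heterozygote
fraction among non-missing calls; expected heterozygosity is 2p(1-p)
from the alt-allele frequency p, with the small-sample unbiased variant
multiplying by 2n/(2n-1). F_IS defaults to the ratio-of-means form
1 - mean(H_O)/mean(H_E); the mean-of-ratios form is also available
because popgen tools differ in this aggregation and the two can diverge
noticeably in small, structured groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeError, GenotypeMatrix
from .filtering import monomorphic_mask


@dataclass
class DiversityResult:
    """Group-level heterozygosity summary (Table-style row)."""

    group: str
    ho: float
    he: float
    uhe: float
    fis: float
    fis_mean_of_ratios: float
    n_individuals: int
    n_loci_used: int

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "HO": self.ho,
            "HE": self.he,
            "uHE": self.uhe,
            "FIS": self.fis,
            "FIS_mean_of_ratios": self.fis_mean_of_ratios,
            "n_individuals": self.n_individuals,
            "n_loci_used": self.n_loci_used,
        }


def _locus_mask(gm: GenotypeMatrix, polymorphic_only: bool) -> np.ndarray:
    if polymorphic_only:
        return ~monomorphic_mask(gm)
    return np.ones(gm.n_loci, dtype=bool)


def individual_ho(gm: GenotypeMatrix, sample_id: str) -> float:
    """Fraction of heterozygous calls among this sample's non-missing calls."""
    vec = gm.sample_vector(sample_id)
    called = vec != MISSING
    if not called.any():
        raise GenotypeError(f"sample {sample_id!r} has no non-missing calls")
    return float((vec[called] == 1).mean())


def per_locus_ho(gm: GenotypeMatrix, sample_ids: Sequence[str]) -> np.ndarray:
    """Heterozygote fraction among non-missing calls, per locus (NaN if none)."""
    calls = gm.calls_for(sample_ids)
    called = calls != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, (calls == 1).sum(axis=0) / np.maximum(n, 1), np.nan)


def group_ho(gm: GenotypeMatrix, sample_ids: Sequence[str], polymorphic_only: bool = True) -> float:
    """Mean over loci of the per-locus heterozygote fraction."""
    ho = per_locus_ho(gm, sample_ids)[_locus_mask(gm, polymorphic_only)]
    return float(np.nanmean(ho))


def allele_freq(gm: GenotypeMatrix, sample_ids: Sequence[str]) -> np.ndarray:
    """Per-locus alt-allele frequency p = (2*hom_alt + het) / (2*called)."""
    calls = gm.calls_for(sample_ids)
    called = calls != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)


def per_locus_he(
    gm: GenotypeMatrix, sample_ids: Sequence[str], unbiased: bool = False
) -> np.ndarray:
    p = allele_freq(gm, sample_ids)
    he = 2.0 * p * (1.0 - p)
    if unbiased:
        n = (gm.calls_for(sample_ids) != MISSING).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(n > 0, he * (2.0 * n) / np.maximum(2.0 * n - 1.0, 1.0), np.nan)
    return he


def group_he(
    gm: GenotypeMatrix,
    sample_ids: Sequence[str],
    unbiased: bool = False,
    polymorphic_only: bool = True,
) -> float:
    """Mean expected heterozygosity 2p(1-p) over loci (optionally unbiased)."""
    he = per_locus_he(gm, sample_ids, unbiased=unbiased)[_locus_mask(gm, polymorphic_only)]
    return float(np.nanmean(he))


def group_fis(
    gm: GenotypeMatrix,
    sample_ids: Sequence[str],
    method: str = "ratio_of_means",
    unbiased: bool = True,
    polymorphic_only: bool = True,
) -> float:
    """Inbreeding coefficient of the group.

    ``ratio_of_means``: 1 - mean(H_O)/mean(H_E_ref) over loci.
    ``mean_of_ratios``: mean over loci with h_e_ref > 0 of 1 - h_o/h_e_ref.
    Undefined (reference H_E of zero) is returned as NaN, never 0.
    """
    mask = _locus_mask(gm, polymorphic_only)
    ho = per_locus_ho(gm, sample_ids)[mask]
    he = per_locus_he(gm, sample_ids, unbiased=unbiased)[mask]
    ok = ~np.isnan(ho) & ~np.isnan(he)
    ho, he = ho[ok], he[ok]
    if method == "ratio_of_means":
        mean_he = he.mean() if he.size else np.nan
        if not mean_he or np.isnan(mean_he):
            return float("nan")
        return float(1.0 - ho.mean() / mean_he)
    if method == "mean_of_ratios":
        pos = he > 0
        if not pos.any():
            return float("nan")
        return float(np.mean(1.0 - ho[pos] / he[pos]))
    raise ValueError(f"unknown F_IS method {method!r}")


def group_diversity(
    gm: GenotypeMatrix,
    sample_ids: Sequence[str],
    group: str = "",
    polymorphic_only: bool = True,
) -> DiversityResult:
    mask = _locus_mask(gm, polymorphic_only)
    return DiversityResult(
        group=group,
        ho=group_ho(gm, sample_ids, polymorphic_only),
        he=group_he(gm, sample_ids, unbiased=False, polymorphic_only=polymorphic_only),
        uhe=group_he(gm, sample_ids, unbiased=True, polymorphic_only=polymorphic_only),
        fis=group_fis(gm, sample_ids, "ratio_of_means", polymorphic_only=polymorphic_only),
        fis_mean_of_ratios=group_fis(gm, sample_ids, "mean_of_ratios", polymorphic_only=polymorphic_only),
        n_individuals=len(list(sample_ids)),
        n_loci_used=int(mask.sum()),
    )


def diversity_table(
    gm: GenotypeMatrix, groups: dict[str, Sequence[str]], polymorphic_only: bool = True
) -> pd.DataFrame:
    """One diversity row per management group."""
    rows = [
        group_diversity(gm, ids, group=label, polymorphic_only=polymorphic_only).to_dict()
        for label, ids in groups.items()
    ]
    return pd.DataFrame(rows)


def individual_ho_table(gm: GenotypeMatrix, sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-individual observed heterozygosity (the per-genet bar-chart analogue)."""
    ids = list(sample_ids) if sample_ids is not None else list(gm.sample_ids)
    return pd.DataFrame(
        {"sample_id": ids, "HO": [individual_ho(gm, s) for s in ids]}
    )
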