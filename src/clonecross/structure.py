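"""Population differentiation (Weir–Cockerham F_ST) and PCoA.

F_ST uses the Weir & Cockerham (1984) theta estimator for two
populations: per-locus variance components a (among populations), b
(among individuals within populations) and c (within individuals) are
computed from per-population sample sizes, alt-allele frequencies and
observed heterozygote fractions, and the multilocus estimate is
sum(a) / sum(a + b + c) over loci where the denominator is defined.
Negative estimates are reported unclipped.

Because the study groups are tiny and unequal, pairwise F_ST is also
offered with subsampling to a common n per group (mean over iterations),
which removes sample-size bias at the cost of Monte-Carlo noise.

PCoA is classical metric multidimensional scaling on Euclidean distances
between mean-imputed, per-locus-centred dosage vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import MISSING, GenotypeError, GenotypeMatrix


@dataclass
class FstResult:
    """Subsampled pairwise F_ST between one pair of groups."""

    group_a: str
    group_b: str
    point_fst: float
    mean_fst: float
    iteration_values: np.ndarray
    n_undefined: int
    n_sub: int
    iterations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "point_fst": self.point_fst,
            "mean_fst": self.mean_fst,
            "n_undefined": self.n_undefined,
            "n_sub": self.n_sub,
            "iterations": self.iterations,
            "seed": self.seed,
        }


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    percent_variation: np.ndarray  # per retained axis, of total positive

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"axis_{i + 1}": self.coordinates[:, i] for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample_id": self.sample_ids, **cols})


def _pop_summaries(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n called, alt freq, het fraction) for one population."""
    called = calls != MISSING
    n = called.sum(axis=0).astype(float)
    alt = np.where(called, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, (calls == 1).sum(axis=0) / n, np.nan)
    return n, p, h


def wc_components(
    gm: GenotypeMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) for two populations.

    Loci where either population has fewer than one called individual, or
    where n_c degenerates (a population with all data missing), yield NaN
    components and are excluded by :func:`fst_wc`.
    """
    n1, p1, h1 = _pop_summaries(gm.calls_for(group_a))
    n2, p2, h2 = _pop_summaries(gm.calls_for(group_b))
    r = 2.0
    valid = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid & (nc > 0), a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def fst_wc(gm: GenotypeMatrix, group_a: Sequence[str], group_b: Sequence[str]) -> float:
    """Multilocus Weir–Cockerham theta between two groups of samples.

    Returns NaN when no locus yields a non-zero denominator (e.g. both
    groups identically monomorphic everywhere). Negative values are
    reported as-is.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 1 or len(group_b) < 1:
        raise GenotypeError("each group needs at least one sample")
    a, b, c = wc_components(gm, group_a, group_b)
    denom = a + b + c
    ok = ~np.isnan(denom) & (denom != 0)
    if not ok.any():
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


def fst_subsampled(
    gm: GenotypeMatrix,
    groups: dict[str, Sequence[str]],
    n_sub: int = 3,
    iterations: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], FstResult]:
    """Pairwise mean subsampled F_ST over all group pairs.

    Each iteration draws ``n_sub`` individuals per group without
    replacement (groups at or below ``n_sub`` are used whole) and computes
    WC84 theta; the mean is over defined iterations, with the undefined
    count reported rather than silently dropped.
    """
    if n_sub < 2:
        raise ValueError("n_sub must be at least 2")
    labels = list(groups)
    results: dict[tuple[str, str], FstResult] = {}
    for la, lb in combinations(labels, 2):
        ids_a = [str(s) for s in groups[la]]
        ids_b = [str(s) for s in groups[lb]]
        point = fst_wc(gm, ids_a, ids_b)
        # independent stream per pair so pair order cannot leak randomness
        rng = np.random.default_rng([seed, _stable_hash(la), _stable_hash(lb)])
        vals = np.empty(iterations)
        for it in range(iterations):
            sub_a = ids_a if len(ids_a) <= n_sub else list(rng.choice(ids_a, n_sub, replace=False))
            sub_b = ids_b if len(ids_b) <= n_sub else list(rng.choice(ids_b, n_sub, replace=False))
            vals[it] = fst_wc(gm, sub_a, sub_b)
        defined = vals[~np.isnan(vals)]
        results[(la, lb)] = FstResult(
            group_a=la,
            group_b=lb,
            point_fst=point,
            mean_fst=float(defined.mean()) if defined.size else float("nan"),
            iteration_values=vals,
            n_undefined=int(np.isnan(vals).sum()),
            n_sub=n_sub,
            iterations=iterations,
            seed=seed,
        )
    return results


def fst_matrix(results: dict[tuple[str, str], FstResult], order: Sequence[str]) -> pd.DataFrame:
    """Lower-triangle mean-F_ST matrix in the given group order."""
    mat = pd.DataFrame(np.nan, index=list(order), columns=list(order))
    for (la, lb), res in results.items():
        i, j = list(order).index(la), list(order).index(lb)
        if i < j:
            mat.iloc[j, i] = res.mean_fst
        else:
            mat.iloc[i, j] = res.mean_fst
    return mat


def _stable_hash(label: str) -> int:
    import zlib

    return zlib.crc32(label.encode("utf8"))


def impute_centred_dosages(gm: GenotypeMatrix, sample_ids: Sequence[str]) -> np.ndarray:
    """Mean-impute missing calls per locus, then centre each locus."""
    calls = gm.calls_for(sample_ids).astype(float)
    calls[calls == MISSING] = np.nan
    col_means = np.nanmean(calls, axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    filled = np.where(np.isnan(calls), col_means[None, :], calls)
    return filled - filled.mean(axis=0, keepdims=True)


def pcoa(gm: GenotypeMatrix, sample_ids: Sequence[str] | None = None, k: int = 2) -> PcoaResult:
    """Classical metric MDS on Euclidean dosage distances.

    Percent variation per axis is eigenvalue / sum(positive eigenvalues)
    x 100. With no positive eigenvalues (all samples identical) an empty
    result is returned with a warning.
    """
    ids = list(sample_ids) if sample_ids is not None else list(gm.sample_ids)
    x = impute_centred_dosages(gm, ids)
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    n = len(ids)
    j = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((gram + gram.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigvals[0]), 1.0) if n else 0.0
    pos = eigvals > tol
    if not pos.any():
        warnings.warn("all samples identical: PCoA has no positive eigenvalues")
        return PcoaResult(ids, np.zeros((n, 0)), np.array([]), np.array([]))
    eigvals = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(eigvals)[None, :]
    if k > eigvals.size:
        warnings.warn(
            f"requested {k} axes but only {eigvals.size} positive eigenvalues; truncating"
        )
        k = eigvals.size
    percent = eigvals / eigvals.sum() * 100.0
    return PcoaResult(ids, coords[:, :k], eigvals, percent[:k])
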