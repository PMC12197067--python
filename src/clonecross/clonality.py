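"""Clone (multilocus genotype) detection.

Samples of a clonal plant that belong to one genet differ only by
genotyping error, so clone-mates sit at a pairwise dissimilarity of
roughly twice the per-call error rate, far below the dissimilarity
between distinct genets. Clone calling is therefore complete-linkage
agglomerative clustering on the pairwise mismatch fraction, cut at a
threshold: complete linkage guarantees every within-genet pair is below
the threshold and prevents two true genets chaining through a noisy
intermediate sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import MISSING, GenotypeError, GenotypeMatrix

DEFAULT_THRESHOLD = 0.05
DEFAULT_MIN_SHARED = 50


class IncomparablePairError(GenotypeError):
    """Raised when clone calling needs a dissimilarity that cannot be computed."""


@dataclass
class CloneAssignment:
    """Partition of samples into genets with consensus genotypes."""

    sample_to_genet: dict[str, str]
    genet_members: dict[str, list[str]]
    consensus: dict[str, np.ndarray]
    threshold: float
    dissimilarity: pd.DataFrame

    @property
    def n_genets(self) -> int:
        return len(self.genet_members)

    def genets_of(self, sample_ids: Sequence[str]) -> set[str]:
        return {self.sample_to_genet[str(s)] for s in sample_ids}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_to_genet),
                "genet": list(self.sample_to_genet.values()),
            }
        )

    def consensus_matrix(self, locus_ids: Sequence[str]) -> GenotypeMatrix:
        """One consensus genotype row per genet, as a GenotypeMatrix."""
        genets = sorted(self.genet_members)
        calls = np.stack([self.consensus[g] for g in genets])
        return GenotypeMatrix(genets, list(locus_ids), calls).with_recomputed_call_rates()


def pairwise_dissimilarity(
    gm: GenotypeMatrix, a: str, b: str, min_shared: int = DEFAULT_MIN_SHARED
) -> float:
    """Fraction of loci called in both samples where the codes differ.

    Pairs sharing fewer than ``min_shared`` called loci are flagged
    incomparable (error), never reported as similarity 0.
    """
    va, vb = gm.sample_vector(a), gm.sample_vector(b)
    both = (va != MISSING) & (vb != MISSING)
    n = int(both.sum())
    if n < min_shared:
        raise IncomparablePairError(
            f"samples {a!r} and {b!r} share only {n} called loci (< {min_shared})"
        )
    return float((va[both] != vb[both]).mean())


def dissimilarity_matrix(
    gm: GenotypeMatrix,
    sample_ids: Sequence[str] | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> pd.DataFrame:
    """Symmetric mismatch-fraction matrix; incomparable pairs are NaN."""
    ids = list(sample_ids) if sample_ids is not None else list(gm.sample_ids)
    calls = gm.calls_for(ids)
    called = calls != MISSING
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        shared = both.sum(axis=1)
        diff = ((calls[i] != calls[i + 1 :]) & both).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(shared >= min_shared, diff / np.maximum(shared, 1), np.nan)
        out[i, i + 1 :] = d
        out[i + 1 :, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


def call_clones(
    gm: GenotypeMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    sample_ids: Sequence[str] | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> CloneAssignment:
    """Group samples into genets by complete-linkage clustering at ``threshold``.

    Deterministic given the input: genets are labelled G01, G02, ... in
    order of their lexicographically smallest member sample id. Any
    incomparable pair (too few shared loci) is a hard error naming it.
    """
    ids = sorted(sample_ids) if sample_ids is not None else sorted(gm.sample_ids)
    dist = dissimilarity_matrix(gm, ids, min_shared=min_shared)
    arr = dist.to_numpy()
    nan_pairs = np.argwhere(np.isnan(np.triu(arr, 1)))
    if nan_pairs.size:
        i, j = nan_pairs[0]
        raise IncomparablePairError(
            f"cannot cluster: samples {ids[i]!r} and {ids[j]!r} are incomparable "
            f"(fewer than {min_shared} shared called loci)"
        )
    if len(ids) == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(arr, checks=False), method="complete")
        labels = fcluster(z, t=threshold, criterion="distance")

    members: dict[int, list[str]] = {}
    for sid, lab in zip(ids, labels):
        members.setdefault(int(lab), []).append(sid)
    ordered = sorted(members.values(), key=lambda ms: min(ms))
    genet_members = {f"G{i + 1:02d}": sorted(ms) for i, ms in enumerate(ordered)}
    sample_to_genet = {s: g for g, ms in genet_members.items() for s in ms}
    consensus = {g: consensus_genotype(gm, ms) for g, ms in genet_members.items()}
    return CloneAssignment(
        sample_to_genet=sample_to_genet,
        genet_members=genet_members,
        consensus=consensus,
        threshold=threshold,
        dissimilarity=dist,
    )


def consensus_genotype(gm: GenotypeMatrix, member_ids: Sequence[str]) -> np.ndarray:
    """Per-locus majority code among non-missing member calls; ties -> MISSING."""
    calls = gm.calls_for(member_ids)
    counts = np.stack([(calls == code).sum(axis=0) for code in (0, 1, 2)])  # (3, n_loci)
    best = counts.max(axis=0)
    n_best = (counts == best[None, :]).sum(axis=0)
    winner = counts.argmax(axis=0)
    out = np.where((best > 0) & (n_best == 1), winner, MISSING)
    return out.astype(np.int8)


def genet_summary(assignment: CloneAssignment, sample_meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-genet member count and (if metadata given) patch/group makeup."""
    rows = []
    for genet, members in assignment.genet_members.items():
        row: dict = {"genet": genet, "n_members": len(members), "members": ";".join(members)}
        if sample_meta is not None:
            sub = sample_meta.loc[[m for m in members if m in sample_meta.index]]
            row["groups"] = ";".join(sorted(set(sub["group"]))) if len(sub) else ""
            row["patches"] = ";".join(sorted({p for p in sub["patch"] if p})) if len(sub) else ""
        rows.append(row)
    return pd.DataFrame(rows)
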