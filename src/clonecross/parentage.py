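"""Opposing-homozygote parentage exclusion.

A true parent transmits one allele to its offspring, so a locus where one
individual is homozygous reference and the other homozygous alternate is
impossible in a parent-offspring pair absent genotyping error. The
fraction of such "opposing homozygote" loci among loci called in both
individuals is therefore near zero for true parent-offspring (and clone)
pairs, modest within a species, and large between species — which makes
it a simple hybridisation test: seedlings are assigned to the candidate
parental group with the lowest mean violation rate.

The relation is symmetric, so results are reported for unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeError, GenotypeMatrix

DEFAULT_MIN_SHARED = 50


@dataclass
class ViolationResult:
    sample_a: str
    sample_b: str
    n_comparable: int
    n_violations: int

    @property
    def rate(self) -> float:
        return self.n_violations / self.n_comparable

    def to_dict(self) -> dict:
        return {
            "sample_a": self.sample_a,
            "sample_b": self.sample_b,
            "n_comparable": self.n_comparable,
            "n_violations": self.n_violations,
            "rate": self.rate,
        }


def violation_rate(
    gm: GenotypeMatrix, a: str, b: str, min_shared: int = DEFAULT_MIN_SHARED
) -> ViolationResult:
    """Opposing-homozygote rate between two samples.

    A violation is a locus where the two codes are {0, 2}; the rate is
    over loci non-missing in both. Fewer than ``min_shared`` comparable
    loci is a hard error (rates on a handful of loci are noise).
    """
    va, vb = gm.sample_vector(a), gm.sample_vector(b)
    both = (va != MISSING) & (vb != MISSING)
    n = int(both.sum())
    if n < min_shared:
        raise GenotypeError(
            f"samples {a!r} and {b!r} share only {n} called loci (< {min_shared})"
        )
    opposing = ((va == 0) & (vb == 2)) | ((va == 2) & (vb == 0))
    return ViolationResult(a, b, n, int((opposing & both).sum()))


def violation_matrix(
    gm: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_shared: int = DEFAULT_MIN_SHARED,
) -> pd.DataFrame:
    """All cross-pair violation results between two sample groups."""
    rows = []
    for a in group_a:
        for b in group_b:
            if str(a) == str(b):
                continue
            rows.append(violation_rate(gm, str(a), str(b), min_shared).to_dict())
    return pd.DataFrame(rows)


def mean_violation_rate(
    gm: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_shared: int = DEFAULT_MIN_SHARED,
) -> float:
    table = violation_matrix(gm, group_a, group_b, min_shared)
    return float(table["rate"].mean())


def assign_parental_group(
    gm: GenotypeMatrix,
    seedling_ids: Sequence[str],
    candidate_groups: dict[str, Sequence[str]],
    min_shared: int = DEFAULT_MIN_SHARED,
) -> pd.DataFrame:
    """Rank candidate parental groups by mean violation rate (ascending).

    The first-ranked group is the inferred parental group; ``margin`` is
    the distance to the next-best group's mean rate, reported so the
    exclusion is a quantified statement rather than a bare label.
    """
    if not candidate_groups:
        raise ValueError("no candidate groups given")
    rows = []
    for label, ids in candidate_groups.items():
        rows.append(
            {
                "candidate_group": label,
                "mean_violation_rate": mean_violation_rate(gm, seedling_ids, ids, min_shared),
                "n_candidates": len(list(ids)),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["mean_violation_rate", "candidate_group"], kind="stable", ignore_index=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    rates = table["mean_violation_rate"].to_numpy()
    table["margin_to_next"] = np.append(np.diff(rates), np.nan)
    return table
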