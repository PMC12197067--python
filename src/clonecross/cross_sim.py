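"""Mendelian cross simulation and breeding-pair ranking.

For a candidate parent pair, offspring genotypes are simulated locus by
locus under Mendelian inheritance of unlinked biallelic SNPs: each
parent contributes one allele (a heterozygote contributes reference or
alternate with probability 1/2), and a locus missing in either parent is
missing in the offspring — a management tool must never manufacture
genotype information. The mean observed heterozygosity over a small
brood (default 10 offspring, the species' approximate seed yield per
cross) scores the pair; ranking all permissible pairs (self-crosses and
known-same-sex pairs excluded — the species is dioecious) identifies the
crosses that best preserve diversity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeError

DEFAULT_N_OFFSPRING = 10


@dataclass
class CrossReport:
    """One simulated cross: parent pair, brood H_O values and their mean."""

    parent_a: str
    parent_b: str
    permissible: bool
    n_offspring: int
    offspring_ho: np.ndarray
    seed: int

    @property
    def mean_ho(self) -> float:
        return float(np.mean(self.offspring_ho)) if self.offspring_ho.size else float("nan")


@dataclass
class CrossMatrix:
    """All pairwise simulated crosses over a set of genets."""

    genets: list[str]
    mean_ho: pd.DataFrame  # square, NaN on diagonal and impermissible pairs
    reports: dict[tuple[str, str], CrossReport] = field(default_factory=dict)
    n_offspring: int = DEFAULT_N_OFFSPRING
    seed: int = 0


def _gametes(parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One transmitted allele per locus: 0 or 1 copies of the alt allele."""
    het = parent == 1
    allele = (parent == 2).astype(np.int8)
    allele[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return allele


def simulate_offspring(
    p1: np.ndarray, p2: np.ndarray, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Simulate ``n`` offspring dosage vectors from two parent vectors."""
    p1 = np.asarray(p1, dtype=np.int8)
    p2 = np.asarray(p2, dtype=np.int8)
    if p1.shape != p2.shape or p1.ndim != 1:
        raise GenotypeError("parent vectors must be 1-D and on identical locus sets")
    if n < 1:
        raise ValueError("at least one offspring must be simulated")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing = (p1 == MISSING) | (p2 == MISSING)
    out = np.empty((n, p1.size), dtype=np.int8)
    for i in range(n):
        out[i] = _gametes(p1, rng) + _gametes(p2, rng)
    out[:, missing] = MISSING
    return out


def offspring_ho(offspring: np.ndarray) -> np.ndarray:
    """Observed heterozygosity per offspring row, missing loci excluded."""
    called = offspring != MISSING
    n = called.sum(axis=1)
    if (n == 0).any():
        raise GenotypeError("an offspring has no called loci")
    return (offspring == 1).sum(axis=1) / n


def pair_seed(master_seed: int, genet_a: str, genet_b: str) -> list[int]:
    """Deterministic per-pair seed material from the master seed and the
    sorted pair ids, so adding a genet never perturbs other pairs."""
    a, b = sorted((str(genet_a), str(genet_b)))
    return [int(master_seed), zlib.crc32(a.encode()), zlib.crc32(b.encode())]


def cross_mean_ho(
    p1: np.ndarray,
    p2: np.ndarray,
    n: int = DEFAULT_N_OFFSPRING,
    seed: int | Sequence[int] = 0,
    parent_ids: tuple[str, str] = ("p1", "p2"),
    permissible: bool = True,
) -> CrossReport:
    """Simulate a brood and report per-offspring and mean H_O."""
    master = seed if isinstance(seed, int) else int(np.asarray(seed)[0])
    if not permissible:
        return CrossReport(parent_ids[0], parent_ids[1], False, 0, np.array([]), master)
    rng = np.random.default_rng(seed)
    brood = simulate_offspring(p1, p2, n, rng)
    return CrossReport(parent_ids[0], parent_ids[1], True, n, offspring_ho(brood), master)


def all_crosses(
    genotypes: Mapping[str, np.ndarray],
    sexes: Mapping[str, str] | None = None,
    n: int = DEFAULT_N_OFFSPRING,
    seed: int = 0,
) -> CrossMatrix:
    """Simulate every permissible unordered genet pair.

    Self-crosses are never simulated (dioecy), nor are pairs where both
    sexes are known and equal; unknown-sex genets pair with everyone.
    Per-pair RNG streams derive from (master seed, sorted pair ids).
    """
    genets = sorted(genotypes)
    sexes = dict(sexes or {})
    mat = pd.DataFrame(np.nan, index=genets, columns=genets)
    reports: dict[tuple[str, str], CrossReport] = {}
    for a, b in combinations(genets, 2):
        sa, sb = sexes.get(a, "unknown"), sexes.get(b, "unknown")
        permissible = not (sa == sb and sa in ("male", "female"))
        report = cross_mean_ho(
            genotypes[a],
            genotypes[b],
            n=n,
            seed=pair_seed(seed, a, b),
            parent_ids=(a, b),
            permissible=permissible,
        )
        reports[(a, b)] = report
        if permissible:
            mat.loc[a, b] = mat.loc[b, a] = report.mean_ho
    return CrossMatrix(genets=genets, mean_ho=mat, reports=reports, n_offspring=n, seed=seed)


def rank_pairs(cm: CrossMatrix, top: int | None = None) -> pd.DataFrame:
    """Simulated pairs sorted by mean offspring H_O, best first.

    Ties break on the sorted pair ids so the ranking is reproducible.
    """
    rows = [
        {"parent_a": a, "parent_b": b, "mean_offspring_ho": r.mean_ho}
        for (a, b), r in cm.reports.items()
        if r.permissible
    ]
    table = pd.DataFrame(rows).sort_values(
        ["mean_offspring_ho", "parent_a", "parent_b"],
        ascending=[False, True, True],
        kind="stable",
        ignore_index=True,
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table.head(top) if top is not None else table


def group_summary(cm: CrossMatrix, genet_groups: Mapping[str, str]) -> pd.DataFrame:
    """Mean of member-pair mean H_O for each unordered group pair."""
    acc: dict[tuple[str, str], list[float]] = {}
    for (a, b), r in cm.reports.items():
        if not r.permissible:
            continue
        ga, gb = sorted((genet_groups.get(a, "?"), genet_groups.get(b, "?")))
        acc.setdefault((ga, gb), []).append(r.mean_ho)
    rows = [
        {"group_a": ga, "group_b": gb, "mean_offspring_ho": float(np.mean(v)), "n_pairs": len(v)}
        for (ga, gb), v in sorted(acc.items())
    ]
    return pd.DataFrame(rows)
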