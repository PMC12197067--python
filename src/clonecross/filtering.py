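"""SNP quality-control cascade.

The cascade mirrors the standard reduced-representation QC sequence for
DArT-style SNP data, applied in a fixed, recorded order:

1. remove individuals with low call rate,
2. remove loci with low technical reproducibility,
3. remove loci with mean read depth outside an inclusive band,
4. remove loci with low call rate (recomputed on the retained samples),
5. remove monomorphic loci,
6. remove "secondaries" so each sequenced fragment keeps one SNP.

All thresholds are inclusive on the keep side: "below X" removes strictly
< X; the depth band keeps min <= depth <= max. Every step appends a row to
a :class:`FilterReport`, so retention is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeError, GenotypeMatrix


class FilterError(ValueError):
    """Raised when a filter step would empty the dataset."""


@dataclass
class FilterConfig:
    """Thresholds for one QC pass. Set a field to ``None`` to skip its step."""

    individual_call_rate: float | None = 0.25
    locus_reproducibility: float | None = 0.99
    read_depth_min: float | None = 5.0
    read_depth_max: float | None = 500.0
    locus_call_rate: float | None = 0.97
    remove_monomorphic: bool = True
    remove_secondaries: bool = True

    @classmethod
    def first_pass(cls) -> "FilterConfig":
        return cls(locus_call_rate=0.97)

    @classmethod
    def second_pass(cls) -> "FilterConfig":
        """Identical to the first pass except a relaxed locus call rate."""
        return cls(locus_call_rate=0.95)


@dataclass
class FilterStep:
    name: str
    threshold: str
    n_samples: int
    n_loci: int
    removed: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Ordered per-step retention log plus the final missing-data percent."""

    steps: list[FilterStep] = field(default_factory=list)
    final_missing_pct: float = 0.0

    def record(self, name: str, threshold: str, gm: GenotypeMatrix, removed: list[str]) -> None:
        self.steps.append(FilterStep(name, threshold, gm.n_samples, gm.n_loci, removed))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "step": s.name,
                "threshold": s.threshold,
                "samples_retained": s.n_samples,
                "loci_retained": s.n_loci,
                "n_removed": len(s.removed),
            }
            for s in self.steps
        ]
        return pd.DataFrame(rows)

    def removed_by_step(self) -> dict[str, list[str]]:
        return {s.name: list(s.removed) for s in self.steps}


def _keep_loci(gm: GenotypeMatrix, keep: np.ndarray, what: str) -> GenotypeMatrix:
    if not keep.any():
        raise FilterError(f"{what}: no loci would remain")
    loci = [l for l, k in zip(gm.locus_ids, keep) if k]
    return gm.subset(loci=loci)


def filter_individual_callrate(gm: GenotypeMatrix, min_rate: float) -> GenotypeMatrix:
    """Retain samples whose fraction of non-missing calls is >= min_rate."""
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must be in [0, 1]")
    keep = gm.sample_call_rates() >= min_rate
    if not keep.any():
        raise FilterError("individual call-rate filter would remove every sample")
    samples = [s for s, k in zip(gm.sample_ids, keep) if k]
    return gm.subset(samples=samples)


def filter_locus_reproducibility(gm: GenotypeMatrix, min_rep: float) -> GenotypeMatrix:
    keep = gm.locus_meta["reproducibility"].to_numpy(dtype=float) >= min_rep
    return _keep_loci(gm, keep, "reproducibility filter")


def filter_read_depth(gm: GenotypeMatrix, min_depth: float, max_depth: float) -> GenotypeMatrix:
    depth = gm.locus_meta["mean_read_depth"].to_numpy(dtype=float)
    keep = (depth >= min_depth) & (depth <= max_depth)
    return _keep_loci(gm, keep, "read-depth filter")


def filter_locus_callrate(gm: GenotypeMatrix, min_rate: float) -> GenotypeMatrix:
    """Retain loci by call rate recomputed over the *current* samples."""
    keep = gm.locus_call_rates() >= min_rate
    return _keep_loci(gm, keep, "locus call-rate filter")


def monomorphic_mask(gm: GenotypeMatrix) -> np.ndarray:
    """True where a locus shows at most one allele among non-missing calls.

    Entirely-missing loci count as monomorphic (they carry no information).
    """
    calls = gm.calls
    has_ref = ((calls == 0) | (calls == 1)).any(axis=0)
    has_alt = ((calls == 2) | (calls == 1)).any(axis=0)
    return ~(has_ref & has_alt)


def filter_monomorphic(gm: GenotypeMatrix) -> GenotypeMatrix:
    return _keep_loci(gm, ~monomorphic_mask(gm), "monomorphic filter")


def filter_secondaries(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep exactly one locus per sequenced fragment.

    Tie-break: highest current call rate, then highest reproducibility,
    then first in file order — deterministic and QC-sensible.
    """
    frag = gm.locus_meta["fragment_id"].to_numpy(dtype=str)
    call_rate = gm.locus_call_rates()
    rep = gm.locus_meta["reproducibility"].to_numpy(dtype=float)
    order = np.arange(gm.n_loci)
    best: dict[str, int] = {}
    for i in order:
        key = frag[i]
        if key not in best:
            best[key] = i
        else:
            j = best[key]
            if (call_rate[i], rep[i], -i) > (call_rate[j], rep[j], -j):
                best[key] = i
    keep = np.zeros(gm.n_loci, dtype=bool)
    keep[list(best.values())] = True
    return _keep_loci(gm, keep, "secondaries filter")


def run_cascade(gm: GenotypeMatrix, config: FilterConfig | None = None) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the full QC cascade in its fixed order and log every step."""
    cfg = config or FilterConfig.first_pass()
    report = FilterReport()
    report.record("input", "", gm, [])
    current = gm

    def step(name: str, threshold: str, fn: Callable[[GenotypeMatrix], GenotypeMatrix]) -> None:
        nonlocal current
        before_samples, before_loci = set(current.sample_ids), set(current.locus_ids)
        current = fn(current)
        removed = sorted((before_samples - set(current.sample_ids)) | (before_loci - set(current.locus_ids)))
        report.record(name, threshold, current, removed)

    if cfg.individual_call_rate is not None:
        step(
            "individual_call_rate",
            f">= {cfg.individual_call_rate}",
            lambda g: filter_individual_callrate(g, cfg.individual_call_rate),
        )
    if cfg.locus_reproducibility is not None:
        step(
            "locus_reproducibility",
            f">= {cfg.locus_reproducibility}",
            lambda g: filter_locus_reproducibility(g, cfg.locus_reproducibility),
        )
    if cfg.read_depth_min is not None or cfg.read_depth_max is not None:
        lo = cfg.read_depth_min if cfg.read_depth_min is not None else 0.0
        hi = cfg.read_depth_max if cfg.read_depth_max is not None else np.inf
        step("read_depth", f"[{lo}, {hi}]", lambda g: filter_read_depth(g, lo, hi))
    if cfg.locus_call_rate is not None:
        step(
            "locus_call_rate",
            f">= {cfg.locus_call_rate}",
            lambda g: filter_locus_callrate(g, cfg.locus_call_rate),
        )
    if cfg.remove_monomorphic:
        step("monomorphic", "polymorphic only", filter_monomorphic)
    if cfg.remove_secondaries:
        step("secondaries", "one SNP per fragment", filter_secondaries)

    report.final_missing_pct = current.missing_fraction() * 100.0
    return current, report
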