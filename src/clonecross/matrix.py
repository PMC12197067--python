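"""Core genotype containers.

Genotypes are stored as alt-allele dosage codes: 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, ``MISSING`` (-1) = no call.
The sentinel is never conflated with dosage 0, so allele-frequency and
cross arithmetic can mask it explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a failed / absent genotype call.
MISSING: int = -1

VALID_CODES = frozenset({MISSING, 0, 1, 2})

#: Columns every locus-metadata table carries.
LOCUS_META_COLUMNS = ("fragment_id", "reproducibility", "mean_read_depth", "call_rate")

SEXES = ("male", "female", "unknown")


class GenotypeError(ValueError):
    """Raised when genotype data violate the container contract."""


@dataclass
class GenotypeMatrix:
    """A samples x biallelic-loci dosage matrix with per-locus QC metadata.

    Parameters
    ----------
    sample_ids, locus_ids
        Unique, ordered identifiers for rows and columns of ``calls``.
    calls
        ``(n_samples, n_loci)`` integer array of codes in {-1, 0, 1, 2}.
    locus_meta
        One row per locus (indexed by locus id) with columns
        ``fragment_id``, ``reproducibility``, ``mean_read_depth`` and
        ``call_rate``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    locus_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.locus_meta is None:
            self.locus_meta = default_locus_meta(self.locus_ids)
        self.validate()

    # -- contract ---------------------------------------------------------

    def validate(self) -> None:
        if self.calls.ndim != 2:
            raise GenotypeError("calls must be a 2-D array")
        ns, nl = self.calls.shape
        if ns != len(self.sample_ids) or nl != len(self.locus_ids):
            raise GenotypeError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != ns:
            raise GenotypeError("duplicate sample ids")
        if len(set(self.locus_ids)) != nl:
            raise GenotypeError("duplicate locus ids")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid genotype code {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        meta = self.locus_meta
        missing_cols = [c for c in LOCUS_META_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise GenotypeError(f"locus_meta lacks columns: {missing_cols}")
        if list(meta.index) != self.locus_ids:
            raise GenotypeError("locus_meta index must equal locus_ids, in order")
        for col, lo, hi in (("reproducibility", 0.0, 1.0), ("call_rate", 0.0, 1.0)):
            vals = meta[col].to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < lo or np.nanmax(vals, initial=0.0) > hi:
                raise GenotypeError(f"locus_meta[{col!r}] outside [{lo}, {hi}]")
        if (meta["mean_read_depth"].to_numpy(dtype=float) < 0).any():
            raise GenotypeError("mean_read_depth must be non-negative")

    # -- basic views ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[str(s)] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise GenotypeError(f"unknown sample id {exc.args[0]!r}") from None

    def locus_indices(self, locus_ids: Iterable[str]) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.locus_ids)}
        try:
            return np.array([lookup[str(l)] for l in locus_ids], dtype=int)
        except KeyError as exc:
            raise GenotypeError(f"unknown locus id {exc.args[0]!r}") from None

    def calls_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Calls restricted to the given samples (rows in request order)."""
        return self.calls[self.sample_indices(sample_ids), :]

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_indices([sample_id])[0], :]

    # -- derived QC -------------------------------------------------------

    def locus_call_rates(self) -> np.ndarray:
        """Fraction of non-missing calls per locus over current samples."""
        if self.n_samples == 0:
            return np.zeros(self.n_loci)
        return (self.calls != MISSING).mean(axis=0)

    def sample_call_rates(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.zeros(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def missing_fraction(self) -> float:
        if self.calls.size == 0:
            return 0.0
        return float((self.calls == MISSING).mean())

    def with_recomputed_call_rates(self) -> "GenotypeMatrix":
        meta = self.locus_meta.copy()
        meta["call_rate"] = self.locus_call_rates()
        return GenotypeMatrix(self.sample_ids, self.locus_ids, self.calls, meta)

    # -- subsetting -------------------------------------------------------

    def subset(
        self,
        samples: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Restrict to the requested samples/loci, in request order.

        Locus metadata is carried over; per-locus call rate is recomputed
        on the retained samples (required for two-pass re-filtering).
        """
        sample_ids = list(self.sample_ids) if samples is None else [str(s) for s in samples]
        locus_ids = list(self.locus_ids) if loci is None else [str(l) for l in loci]
        si = self.sample_indices(sample_ids)
        li = self.locus_indices(locus_ids)
        calls = self.calls[np.ix_(si, li)]
        meta = self.locus_meta.iloc[li].copy()
        gm = GenotypeMatrix(sample_ids, locus_ids, calls, meta)
        return gm.with_recomputed_call_rates()

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids), list(self.locus_ids), self.calls.copy(), self.locus_meta.copy()
        )

    def to_frame(self, missing_token: str = "NA") -> pd.DataFrame:
        """Samples x loci DataFrame with the missing sentinel stringified."""
        df = pd.DataFrame(self.calls, index=self.sample_ids, columns=self.locus_ids, dtype=object)
        return df.where(df != MISSING, missing_token)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


def default_locus_meta(locus_ids: Sequence[str]) -> pd.DataFrame:
    """Permissive metadata (unique fragments, perfect QC) for plain matrices."""
    n = len(locus_ids)
    return pd.DataFrame(
        {
            "fragment_id": [f"frag_{l}" for l in locus_ids],
            "reproducibility": np.ones(n),
            "mean_read_depth": np.full(n, 50.0),
            "call_rate": np.ones(n),
        },
        index=list(locus_ids),
    )


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample-metadata table.

    Required columns: ``sample_id``, ``species``, ``group``; optional
    ``patch`` and ``sex`` (defaulting to ``unknown``). Returns a copy
    indexed by sample id.
    """
    required = ["sample_id", "species", "group"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise GenotypeError(f"sample metadata lacks required columns: {missing}")
    out = meta.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        dups = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise GenotypeError(f"duplicate sample ids in metadata: {dups}")
    if (out["group"].astype(str).str.len() == 0).any():
        raise GenotypeError("empty group label in sample metadata")
    if "patch" not in out.columns:
        out["patch"] = ""
    out["patch"] = out["patch"].fillna("")
    if "sex" not in out.columns:
        out["sex"] = "unknown"
    out["sex"] = out["sex"].fillna("unknown").astype(str)
    bad = ~out["sex"].isin(SEXES)
    if bad.any():
        raise GenotypeError(f"invalid sex values: {sorted(out.loc[bad, 'sex'].unique())}")
    return out.set_index("sample_id", drop=False)


def groups_from_metadata(meta: pd.DataFrame) -> dict[str, list[str]]:
    """Map each management-group label to its sample ids (metadata order)."""
    out: dict[str, list[str]] = {}
    for sid, grp in zip(meta["sample_id"], meta["group"]):
        out.setdefault(str(grp), []).append(str(sid))
    return out
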