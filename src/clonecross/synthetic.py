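"""Synthetic study-like datasets with fully known truth.

The generator emulates the structure of a minimal conservation
collection of a dioecious clonal plant:

* an in-situ population of 20 samples over four clonal patches
  (2/7/3/8 samples) realising 7 distinct genets,
* 12 ex-situ adult samples collapsing to 5 genets (one female, four
  male; two genets shared with the in-situ population),
* 7 F1 seedlings bred within the collection (female x male crosses),
* four divergent congener species (3+2+2+2 samples) simulated under the
  Balding-Nichols model at increasing divergence,
* per-call genotyping error, missing data, and locus QC metadata with a
  designed set of QC-failing loci so the filtering cascade has known
  work to do.

Population model: a two-level Balding-Nichols hierarchy. Marker
frequencies start at a genus-level ancestor (common alleles, as
reduced-representation markers are discovered as genus-level
polymorphisms); the target species drifts strongly from that ancestor
(F_species), which makes most loci near-fixed within the species — the
low within-species diversity characteristic of a relict population —
while congeners drift independently at their own divergences, giving
high and ladder-ordered between-species F_ST. Within the species, the
wild/male lineage drifts mildly (f_wild) and the extinct-source
(female) lineage more (f_source), so the single female genet is
genetically offset from the males — which is what makes F1 seedlings
more heterozygous than the adult group, the pattern the breeding
analysis feeds on. Everything emitted is traceable to a founder or a
pedigree entry in the returned :class:`SyntheticTruth`, and
regeneration from the same parameters and seed is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .cross_sim import simulate_offspring
from .matrix import MISSING, GenotypeMatrix, validate_sample_metadata

SPECIES_TARGET = "target"

#: management-group labels used in sample metadata
GROUP_WILD = "wild"
GROUP_EXSITU_ADULT = "exsitu_adult"
GROUP_SEEDLING = "seedling"


@dataclass
class SyntheticParams:
    """Generator knobs; defaults are the study-like conditions."""

    n_loci: int = 3000
    genus_maf: tuple[float, float] = (0.1, 0.5)  # genus-ancestor frequency band
    f_species: float = 0.85  # drift of the target species from the genus ancestor
    f_wild: float = 0.10  # drift of the wild/male lineage within the species
    f_source: float = 0.50  # drift of the extinct-source (female) lineage
    congener_divergence: Mapping[str, float] = field(
        default_factory=lambda: {
            "congener_A": 0.15,
            "congener_B": 0.5,
            "congener_C": 0.75,
            "congener_D": 0.95,
        }
    )
    congener_samples: Mapping[str, int] = field(
        default_factory=lambda: {
            "congener_A": 3,
            "congener_B": 2,
            "congener_C": 2,
            "congener_D": 2,
        }
    )
    n_seedlings: int = 7
    error_rate: float = 0.005  # per-call heterozygote dropout rate
    false_het_rate: float = 0.0005  # per-call homozygote -> false-het rate
    missing_rate: float = 0.01
    n_bad_reproducibility: int = 15
    n_bad_depth: int = 12
    n_high_missing: int = 10
    secondary_fraction: float = 0.08


@dataclass
class SyntheticTruth:
    """Everything needed to verify any downstream inference."""

    founder_genotypes: dict[str, np.ndarray]
    sample_to_genet: dict[str, str]
    pedigree: dict[str, tuple[str, str]]  # seedling genet -> (dam, sire)
    genet_sexes: dict[str, str]
    sample_species: dict[str, str]
    congener_divergence: dict[str, float]
    error_rate: float
    missing_rate: float
    seed: int
    params: SyntheticParams
    designed_bad_loci: dict[str, list[str]]  # step -> locus ids built to fail it

    def genets_in_group(self, sample_meta: pd.DataFrame, group: str) -> set[str]:
        ids = sample_meta.loc[sample_meta["group"] == group, "sample_id"]
        return {self.sample_to_genet[s] for s in ids}


def generate_base_frequencies(
    n_loci: int, maf_low: float, maf_high: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Alt frequencies uniform on [maf_low, maf_high], randomly symmetrised
    about 0.5 (so neither allele is systematically the minor one)."""
    if not 0.0 <= maf_low <= maf_high <= 0.5:
        raise ValueError("need 0 <= maf_low <= maf_high <= 0.5")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.uniform(maf_low, maf_high, size=n_loci)
    flip = rng.random(n_loci) < 0.5
    return np.where(flip, 1.0 - p, p)


def generate_congener_frequencies(
    base: np.ndarray, divergence: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Drifted frequencies under the Balding-Nichols model.

    Per locus: Beta(p(1-F)/F, (1-p)(1-F)/F) around ancestral frequency p.
    Loci fixed in the ancestor stay fixed; F -> 0 recovers the ancestor.
    """
    if not 0.0 < divergence < 1.0:
        raise ValueError("divergence must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = np.asarray(base, dtype=float)
    scale = (1.0 - divergence) / divergence
    out = base.copy()
    inner = (base > 0) & (base < 1)
    out[inner] = rng.beta(base[inner] * scale, (1.0 - base[inner]) * scale)
    return np.clip(out, 0.0, 1.0)


def hw_genotype(freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One multilocus genotype drawn under Hardy-Weinberg proportions."""
    return (rng.binomial(1, freqs) + rng.binomial(1, freqs)).astype(np.int8)


def apply_genotyping_error(
    calls: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
    false_het_rate: float | None = None,
) -> np.ndarray:
    """Dropout-dominated per-call miscode.

    Reduced-representation genotyping errs mostly by allelic dropout: a
    heterozygote loses one allele and is called homozygous (rate
    ``error_rate``, split evenly between the two homozygotes). The
    reverse miscall — a homozygote read as heterozygous — is an order of
    magnitude rarer (``false_het_rate``, default ``error_rate / 10``).
    Keeping false heterozygotes rare matters: they are what would turn
    genuinely monomorphic loci into spurious polymorphisms that survive
    the monomorphic filter and inflate clone-mate dissimilarity.
    """
    if false_het_rate is None:
        false_het_rate = error_rate / 10.0
    out = calls.copy()
    u = rng.random(out.shape)
    het = out == 1
    drop = het & (u < error_rate)
    out[drop] = np.where(rng.random(int(drop.sum())) < 0.5, 0, 2).astype(np.int8)
    false_het = (~het) & (out != MISSING) & (u < false_het_rate)
    out[false_het] = 1
    return out


def apply_missingness(calls: np.ndarray, missing_rate: float, rng: np.random.Generator) -> np.ndarray:
    out = calls.copy()
    out[rng.random(out.shape) < missing_rate] = MISSING
    return out


# ---------------------------------------------------------------------------
# study-like dataset
# ---------------------------------------------------------------------------

# in-situ sampling design: patch -> list of (sample id, genet id)
_PATCH_DESIGN: list[tuple[str, str, str]] = (
    [("A1", "A", "gi_A"), ("A2", "A", "gi_A")]
    + [(f"B{i}", "B", "gi_B") for i in range(1, 8)]
    + [("C1", "C", "gi_C13"), ("C2", "C", "gi_C2"), ("C3", "C", "gi_C13")]
    + [(f"D{i}", "D", "gi_D") for i in (1, 2, 4, 5, 6, 8)]
    + [("D3", "D", "gi_D3"), ("D7", "D", "gi_D7")]
)

# ex-situ adults: 12 samples -> 5 genets; gi_B and gi_D are the two genets
# shared with the in-situ population; gx_F is the single female genet.
_EXSITU_DESIGN: list[tuple[str, str]] = (
    [(f"EXF{i}", "gx_F") for i in range(1, 7)]
    + [("EXM7", "gx_M7"), ("EXM8", "gx_M8")]
    + [("EXM9a", "gi_D"), ("EXM9b", "gi_D")]
    + [("EXM10a", "gi_B"), ("EXM10b", "gi_B")]
)

_MALE_GENETS = ("gx_M7", "gx_M8", "gi_D", "gi_B")
_FEMALE_GENET = "gx_F"


def generate_study_like_dataset(
    params: SyntheticParams | None = None, seed: int = 0
) -> tuple[GenotypeMatrix, pd.DataFrame, SyntheticTruth]:
    """Emit (genotypes, sample metadata, truth) for one synthetic study.

    Defaults produce 48 samples: 20 in-situ (7 genets), 12 ex-situ adults
    (5 genets, one female), 7 seedlings and 9 congener samples.
    """
    p = params or SyntheticParams()
    if p.n_seedlings < 1:
        raise ValueError("need at least one seedling")
    rng = np.random.default_rng(seed)

    # genus-level ancestor -> target species -> within-species lineages
    ancestral = generate_base_frequencies(p.n_loci, *p.genus_maf, seed=rng)
    species_freqs = generate_congener_frequencies(ancestral, p.f_species, rng)
    wild_freqs = generate_congener_frequencies(species_freqs, p.f_wild, rng)
    source_freqs = generate_congener_frequencies(species_freqs, p.f_source, rng)

    # founder genotypes per genet
    founders: dict[str, np.ndarray] = {}
    genet_sexes: dict[str, str] = {}
    wild_genets = ["gi_A", "gi_B", "gi_C13", "gi_C2", "gi_D", "gi_D3", "gi_D7"]
    for g in wild_genets + ["gx_M7", "gx_M8"]:
        founders[g] = hw_genotype(wild_freqs, rng)
        genet_sexes[g] = "unknown"
    founders[_FEMALE_GENET] = hw_genotype(source_freqs, rng)
    genet_sexes[_FEMALE_GENET] = "female"
    for g in _MALE_GENETS:
        genet_sexes[g] = "male"

    # F1 seedlings: dam is the female genet, sire drawn among the males
    pedigree: dict[str, tuple[str, str]] = {}
    for i in range(1, p.n_seedlings + 1):
        sire = str(rng.choice(_MALE_GENETS))
        g = f"gs_S{i}"
        founders[g] = simulate_offspring(founders[_FEMALE_GENET], founders[sire], 1, rng)[0]
        pedigree[g] = (_FEMALE_GENET, sire)
        genet_sexes[g] = "unknown"

    # assemble samples
    sample_rows: list[dict] = []
    sample_to_genet: dict[str, str] = {}
    call_rows: list[np.ndarray] = []

    def emit(sid: str, genet: str, species: str, group: str, patch: str = "", sex: str = "unknown"):
        sample_rows.append(
            {"sample_id": sid, "species": species, "group": group, "patch": patch, "sex": sex}
        )
        sample_to_genet[sid] = genet
        call_rows.append(founders[genet])

    for sid, patch, genet in _PATCH_DESIGN:
        emit(sid, genet, SPECIES_TARGET, GROUP_WILD, patch=patch)
    for sid, genet in _EXSITU_DESIGN:
        sex = genet_sexes[genet] if genet in (_FEMALE_GENET, *_MALE_GENETS) else "unknown"
        emit(sid, genet, SPECIES_TARGET, GROUP_EXSITU_ADULT, sex=sex)
    for i in range(1, p.n_seedlings + 1):
        emit(f"SDL{i}", f"gs_S{i}", SPECIES_TARGET, GROUP_SEEDLING)

    sample_species = {r["sample_id"]: r["species"] for r in sample_rows}
    congener_freqs: dict[str, np.ndarray] = {}
    for species, div in p.congener_divergence.items():
        congener_freqs[species] = generate_congener_frequencies(ancestral, div, rng)
        for k in range(1, p.congener_samples.get(species, 0) + 1):
            sid = f"{species}_{k}"
            genet = f"g_{sid}"
            founders[genet] = hw_genotype(congener_freqs[species], rng)
            genet_sexes[genet] = "unknown"
            emit(sid, genet, species, species)
            sample_species[sid] = species

    calls = np.stack(call_rows)
    calls = apply_genotyping_error(calls, p.error_rate, rng, p.false_het_rate)
    calls = apply_missingness(calls, p.missing_rate, rng)

    # locus QC metadata with designed violations (disjoint locus sets)
    locus_ids = [f"L{j:04d}" for j in range(p.n_loci)]
    n_secondary = int(round(p.n_loci * p.secondary_fraction))
    n_designed = p.n_bad_reproducibility + p.n_bad_depth + p.n_high_missing + n_secondary
    designed = rng.choice(p.n_loci, size=n_designed, replace=False)
    bad_rep = designed[: p.n_bad_reproducibility]
    bad_depth = designed[p.n_bad_reproducibility : p.n_bad_reproducibility + p.n_bad_depth]
    high_missing = designed[
        p.n_bad_reproducibility + p.n_bad_depth : p.n_bad_reproducibility + p.n_bad_depth + p.n_high_missing
    ]
    secondary = designed[p.n_bad_reproducibility + p.n_bad_depth + p.n_high_missing :]

    reproducibility = rng.uniform(0.992, 1.0, p.n_loci)
    reproducibility[bad_rep] = rng.uniform(0.90, 0.985, bad_rep.size)
    depth = rng.uniform(10.0, 120.0, p.n_loci)
    half = bad_depth.size // 2
    depth[bad_depth[:half]] = rng.uniform(0.5, 4.5, half)
    depth[bad_depth[half:]] = rng.uniform(520.0, 900.0, bad_depth.size - half)

    # push designed high-missing loci below any realistic call-rate threshold
    for j in high_missing:
        k = max(2, int(np.ceil(0.10 * calls.shape[0])))
        rows = rng.choice(calls.shape[0], size=k, replace=False)
        calls[rows, j] = MISSING

    # secondaries: attach each designed secondary locus to another fragment
    fragment = np.array([f"frag{j:04d}" for j in range(p.n_loci)], dtype=object)
    primary_pool = np.setdiff1d(np.arange(p.n_loci), designed)
    partners = rng.choice(primary_pool, size=secondary.size, replace=False)
    for j, host in zip(secondary, partners):
        fragment[j] = fragment[host]

    meta = pd.DataFrame(
        {
            "fragment_id": fragment,
            "reproducibility": reproducibility,
            "mean_read_depth": depth,
            "call_rate": np.ones(p.n_loci),
        },
        index=locus_ids,
    )
    gm = GenotypeMatrix(
        [r["sample_id"] for r in sample_rows], locus_ids, calls, meta
    ).with_recomputed_call_rates()
    sample_meta = validate_sample_metadata(pd.DataFrame(sample_rows))

    designed_bad = {
        "locus_reproducibility": [locus_ids[j] for j in sorted(bad_rep)],
        "read_depth": [locus_ids[j] for j in sorted(bad_depth)],
        "locus_call_rate": [locus_ids[j] for j in sorted(high_missing)],
        "secondaries": [locus_ids[j] for j in sorted(secondary)],
    }
    truth = SyntheticTruth(
        founder_genotypes=founders,
        sample_to_genet=sample_to_genet,
        pedigree=pedigree,
        genet_sexes=genet_sexes,
        sample_species=sample_species,
        congener_divergence=dict(p.congener_divergence),
        error_rate=p.error_rate,
        missing_rate=p.missing_rate,
        seed=seed,
        params=p,
        designed_bad_loci=designed_bad,
    )
    return gm, sample_meta, truth


def expected_cascade_removals(gm: GenotypeMatrix, truth: SyntheticTruth) -> dict[str, set[str]]:
    """Independently re-derive which loci each cascade step should remove.

    Used as a cross-module consistency oracle against the filtering
    module: plain numpy checks in the cascade's fixed order, sharing no
    code with :mod:`clonecross.filtering` beyond the container.
    """
    p = truth.params
    meta = gm.locus_meta
    calls = gm.calls.copy()
    locus_ids = np.array(gm.locus_ids)

    removed: dict[str, set[str]] = {}
    alive = np.ones(len(locus_ids), dtype=bool)

    rep = meta["reproducibility"].to_numpy(float)
    hit = alive & (rep < 0.99)
    removed["locus_reproducibility"] = set(locus_ids[hit])
    alive &= ~hit

    depth = meta["mean_read_depth"].to_numpy(float)
    hit = alive & ((depth < 5.0) | (depth > 500.0))
    removed["read_depth"] = set(locus_ids[hit])
    alive &= ~hit

    call_rate = (calls != MISSING).mean(axis=0)
    hit = alive & (call_rate < 0.97)
    removed["locus_call_rate"] = set(locus_ids[hit])
    alive &= ~hit

    has_ref = ((calls == 0) | (calls == 1)).any(axis=0)
    has_alt = ((calls == 2) | (calls == 1)).any(axis=0)
    hit = alive & ~(has_ref & has_alt)
    removed["monomorphic"] = set(locus_ids[hit])
    alive &= ~hit

    frag = meta["fragment_id"].to_numpy(object)
    rep_arr = meta["reproducibility"].to_numpy(float)
    best: dict[object, int] = {}
    for j in np.flatnonzero(alive):
        key = frag[j]
        if key not in best or (call_rate[j], rep_arr[j], -j) > (
            call_rate[best[key]],
            rep_arr[best[key]],
            -best[key],
        ):
            best[key] = j
    keep = set(best.values())
    hit_idx = [j for j in np.flatnonzero(alive) if j not in keep]
    removed["secondaries"] = set(locus_ids[hit_idx])
    return removed
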