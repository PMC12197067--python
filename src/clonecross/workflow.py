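"""Config-driven orchestration of the full analysis.

The pipeline order follows the study design for a mixed collection that
may contain hybrids: first a QC pass and hybridisation screen across all
species (pairwise F_ST, PCoA, opposing-homozygote group means), then the
matrix is restricted to the target species and re-filtered (the "recall"
step), clones are collapsed to genets, and diversity, within-species
F_ST and the simulated-cross ranking are computed on genets. Every stage
writes its table and the config copy into the output directory; seeds
and retention counts are always logged.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import clonality, cross_sim, diversity, parentage, structure
from .filtering import FilterConfig, FilterReport, run_cascade
from .matrix import GenotypeMatrix, groups_from_metadata
from .synthetic import GROUP_EXSITU_ADULT, GROUP_SEEDLING, GROUP_WILD

logger = logging.getLogger("clonecross")


@dataclass
class RunConfig:
    """Everything a full run depends on besides the input data."""

    target_species: str = "target"
    seedling_group: str = GROUP_SEEDLING
    pass1: FilterConfig = field(default_factory=FilterConfig.first_pass)
    pass2: FilterConfig = field(default_factory=FilterConfig.second_pass)
    clone_threshold: float = clonality.DEFAULT_THRESHOLD
    min_shared_loci: int = clonality.DEFAULT_MIN_SHARED
    fst_n_sub: int = 3
    fst_iterations: int = 1000
    cross_n_offspring: int = 10
    seed: int = 0
    collapse_to_genets: bool = True
    run_crosses: bool = True
    output_dir: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        for key in ("pass1", "pass2"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = FilterConfig(**raw[key])
        return cls(**raw)


@dataclass
class AnalysisBundle:
    """All stage outputs of one full run."""

    pass1_report: FilterReport
    fst_all_species: pd.DataFrame
    pcoa_coordinates: pd.DataFrame
    pcoa_percent_variation: np.ndarray
    parentage_ranking: pd.DataFrame
    pass2_report: FilterReport
    filtered_target: GenotypeMatrix
    clones: clonality.CloneAssignment
    genet_summary: pd.DataFrame
    diversity_table: pd.DataFrame
    individual_ho: pd.DataFrame
    fst_within_species: pd.DataFrame
    cross_matrix: cross_sim.CrossMatrix | None
    cross_ranking: pd.DataFrame | None
    cross_group_summary: pd.DataFrame | None
    config: RunConfig


def genet_groups(
    clones: clonality.CloneAssignment, sample_meta: pd.DataFrame, seedling_group: str = GROUP_SEEDLING
) -> dict[str, list[str]]:
    """Map each management group to the genets with a member in it.

    A genet shared between the wild and the ex-situ collection belongs to
    both groups, matching how collection managers count genotypes.
    """
    out: dict[str, list[str]] = {}
    for genet, members in clones.genet_members.items():
        for grp in sorted(set(sample_meta.loc[members, "group"])):
            out.setdefault(grp, []).append(genet)
    return out


def genet_sexes_from_meta(
    clones: clonality.CloneAssignment, sample_meta: pd.DataFrame
) -> dict[str, str]:
    """Per-genet sex from member metadata; conflicting records -> unknown."""
    out: dict[str, str] = {}
    for genet, members in clones.genet_members.items():
        known = {s for s in sample_meta.loc[members, "sex"] if s in ("male", "female")}
        if len(known) == 1:
            out[genet] = known.pop()
        else:
            if len(known) > 1:
                logger.warning("genet %s has conflicting member sexes; treating as unknown", genet)
            out[genet] = "unknown"
    return out


def run_full_analysis(
    gm: GenotypeMatrix, sample_meta: pd.DataFrame, config: RunConfig | None = None
) -> AnalysisBundle:
    cfg = config or RunConfig()
    meta = sample_meta.set_index("sample_id", drop=False) if sample_meta.index.name != "sample_id" else sample_meta

    # ---- pass 1: QC across all species -------------------------------
    gm1, report1 = run_cascade(gm, cfg.pass1)
    logger.info(
        "pass-1 filter: %d samples, %d loci retained (%.2f%% missing)",
        gm1.n_samples, gm1.n_loci, report1.final_missing_pct,
    )
    meta1 = meta.loc[[s for s in gm1.sample_ids]]
    groups_all = groups_from_metadata(meta1)

    # ---- hybridisation screen ----------------------------------------
    fst_all = structure.fst_subsampled(
        gm1, groups_all, n_sub=cfg.fst_n_sub, iterations=cfg.fst_iterations, seed=cfg.seed
    )
    fst_all_mat = structure.fst_matrix(fst_all, list(groups_all))
    pcoa_res = structure.pcoa(gm1, gm1.sample_ids, k=2)
    candidate_groups = {
        g: ids for g, ids in groups_all.items() if g != cfg.seedling_group
    }
    seedling_ids = groups_all.get(cfg.seedling_group, [])
    if seedling_ids and candidate_groups:
        parent_rank = parentage.assign_parental_group(
            gm1, seedling_ids, candidate_groups, min_shared=cfg.min_shared_loci
        )
    else:
        parent_rank = pd.DataFrame()

    # ---- restrict to the target species and re-filter ----------------
    target_samples = [
        s for s in gm1.sample_ids if meta.loc[s, "species"] == cfg.target_species
    ]
    gm_target = gm.subset(samples=[s for s in gm.sample_ids if s in set(target_samples)])
    gm2, report2 = run_cascade(gm_target, cfg.pass2)
    logger.info(
        "pass-2 filter (target species): %d samples, %d loci (%.2f%% missing)",
        gm2.n_samples, gm2.n_loci, report2.final_missing_pct,
    )
    meta2 = meta.loc[[s for s in gm2.sample_ids]]

    # ---- clones -------------------------------------------------------
    clones = clonality.call_clones(
        gm2, threshold=cfg.clone_threshold, min_shared=cfg.min_shared_loci
    )
    summary = clonality.genet_summary(clones, meta2)
    logger.info("clone calling at %.3f: %d genets", cfg.clone_threshold, clones.n_genets)

    # ---- diversity on genets (or samples) -----------------------------
    if cfg.collapse_to_genets:
        gmat = clones.consensus_matrix(gm2.locus_ids)
        div_groups = genet_groups(clones, meta2, cfg.seedling_group)
    else:
        gmat = gm2
        div_groups = groups_from_metadata(meta2)
    div_table = diversity.diversity_table(gmat, div_groups)
    indiv_ho = diversity.individual_ho_table(gmat)

    # ---- within-species subsampled F_ST (on samples) -------------------
    fst_within = structure.fst_subsampled(
        gm2,
        groups_from_metadata(meta2),
        n_sub=cfg.fst_n_sub,
        iterations=cfg.fst_iterations,
        seed=cfg.seed,
    )
    fst_within_mat = structure.fst_matrix(fst_within, list(groups_from_metadata(meta2)))

    # ---- simulated crosses over genets ---------------------------------
    cross_mat = ranking = cross_groups = None
    if cfg.run_crosses:
        sexes = genet_sexes_from_meta(clones, meta2)
        genotypes = {g: clones.consensus[g] for g in clones.genet_members}
        cross_mat = cross_sim.all_crosses(
            genotypes, sexes, n=cfg.cross_n_offspring, seed=cfg.seed
        )
        ranking = cross_sim.rank_pairs(cross_mat)
        one_group = {
            g: ";".join(sorted({grp for grp, gs in genet_groups(clones, meta2).items() if g in gs}))
            for g in clones.genet_members
        }
        cross_groups = cross_sim.group_summary(cross_mat, one_group)
        logger.info("simulated %d permissible crosses", len(ranking))

    bundle = AnalysisBundle(
        pass1_report=report1,
        fst_all_species=fst_all_mat,
        pcoa_coordinates=pcoa_res.to_dataframe(),
        pcoa_percent_variation=pcoa_res.percent_variation,
        parentage_ranking=parent_rank,
        pass2_report=report2,
        filtered_target=gm2,
        clones=clones,
        genet_summary=summary,
        diversity_table=div_table,
        individual_ho=indiv_ho,
        fst_within_species=fst_within_mat,
        cross_matrix=cross_mat,
        cross_ranking=ranking,
        cross_group_summary=cross_groups,
        config=cfg,
    )
    if cfg.output_dir:
        write_bundle(bundle, Path(cfg.output_dir))
    return bundle


def write_bundle(bundle: AnalysisBundle, outdir: Path) -> None:
    """Write every stage table plus the config copy into ``outdir``."""
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(bundle.config.to_yaml())
    bundle.pass1_report.to_dataframe().to_csv(outdir / "filter_report_pass1.csv", index=False)
    bundle.pass2_report.to_dataframe().to_csv(outdir / "filter_report_pass2.csv", index=False)
    bundle.fst_all_species.to_csv(outdir / "fst_all_species.csv")
    bundle.fst_within_species.to_csv(outdir / "fst_within_species.csv")
    bundle.pcoa_coordinates.to_csv(outdir / "pcoa_coordinates.csv", index=False)
    pd.DataFrame(
        {"axis": np.arange(1, bundle.pcoa_percent_variation.size + 1),
         "percent_variation": bundle.pcoa_percent_variation}
    ).to_csv(outdir / "pcoa_percent_variation.csv", index=False)
    if len(bundle.parentage_ranking):
        bundle.parentage_ranking.to_csv(outdir / "parentage_group_ranking.csv", index=False)
    bundle.clones.to_dataframe().to_csv(outdir / "clone_assignment.csv", index=False)
    bundle.clones.dissimilarity.to_csv(outdir / "dissimilarity_matrix.csv")
    bundle.genet_summary.to_csv(outdir / "genet_summary.csv", index=False)
    bundle.diversity_table.to_csv(outdir / "diversity_by_group.csv", index=False)
    bundle.individual_ho.to_csv(outdir / "individual_ho.csv", index=False)
    if bundle.cross_matrix is not None:
        bundle.cross_matrix.mean_ho.to_csv(outdir / "cross_matrix.csv")
        bundle.cross_ranking.to_csv(outdir / "cross_ranking.csv", index=False)
        bundle.cross_group_summary.to_csv(outdir / "cross_group_summary.csv", index=False)


def save_cross_heatmap(cm: cross_sim.CrossMatrix, path: str) -> None:
    """Cosmetic heat-map of the cross matrix (mean offspring H_O)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    data = cm.mean_ho.to_numpy(dtype=float)
    im = ax.imshow(data, cmap="viridis")
    ax.set_xticks(range(len(cm.genets)), cm.genets, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cm.genets)), cm.genets, fontsize=7)
    fig.colorbar(im, ax=ax, label="mean offspring $H_O$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
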