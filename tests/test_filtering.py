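"""QC cascade: per-step boundaries and the full ordered pipeline."""

import numpy as np
import pandas as pd
import pytest

import clonecross as cc
from clonecross.filtering import (
    FilterConfig,
    FilterError,
    filter_individual_callrate,
    filter_locus_callrate,
    filter_locus_reproducibility,
    filter_monomorphic,
    filter_read_depth,
    filter_secondaries,
    monomorphic_mask,
    run_cascade,
)
from clonecross.matrix import MISSING

from conftest import make_gm

M = MISSING


def with_meta(gm, reproducibility=None, depth=None, fragments=None):
    meta = gm.locus_meta.copy()
    if reproducibility is not None:
        meta["reproducibility"] = reproducibility
    if depth is not None:
        meta["mean_read_depth"] = depth
    if fragments is not None:
        meta["fragment_id"] = fragments
    gm.locus_meta = meta
    gm.validate()
    return gm


@pytest.fixture
def cascade_fixture():
    """One designed violation per cascade step; 5 of 10 loci survive.

    badS fails the 25% individual call rate; L1 fails reproducibility,
    L2 the depth band, L3 the locus call rate (once badS is gone),
    L4 is monomorphic, and L5 loses the secondaries tie-break to L6.
    """
    calls = [
        # L0 L1 L2 L3 L4 L5 L6 L7 L8 L9
        [0, 0, 0, M, 0, 0, 1, 0, 1, 0],  # good1
        [1, 1, 1, 1, 0, 1, 0, 2, 1, 1],  # good2
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 2],  # good3
        [M, M, M, M, M, M, M, M, 0, 1],  # badS: call rate 0.2
    ]
    gm = make_gm(
        calls,
        sample_ids=["good1", "good2", "good3", "badS"],
        locus_ids=[f"L{j}" for j in range(10)],
    )
    rep = np.ones(10)
    rep[1] = 0.98
    rep[5] = 0.995
    depth = np.full(10.0, 50.0) if False else np.full(10, 50.0)
    depth[2] = 600.0
    frags = [f"f{j}" for j in range(10)]
    frags[5] = frags[6] = "fshared"
    return with_meta(gm, reproducibility=rep, depth=depth, fragments=frags)


class TestSingleSteps:
    def test_individual_callrate_boundaries(self):
        gm = make_gm([[0] * 10, [M] * 8 + [0, 0]], sample_ids=["full", "sparse"])
        kept = filter_individual_callrate(gm, 0.25)
        assert kept.sample_ids == ["full"]  # 0.20 < 0.25
        assert filter_individual_callrate(gm, 0.0).sample_ids == ["full", "sparse"]

    def test_individual_callrate_all_removed_is_error(self):
        gm = make_gm([[M, 0], [0, M]])
        with pytest.raises(FilterError):
            filter_individual_callrate(gm, 1.0)

    @pytest.mark.parametrize(
        "rep, kept", [(1.0, True), (0.99, True), (0.98, False)]
    )
    def test_reproducibility_strict_below(self, rep, kept):
        gm = with_meta(make_gm([[0], [1]]), reproducibility=[rep])
        if kept:
            assert filter_locus_reproducibility(gm, 0.99).n_loci == 1
        else:
            with pytest.raises(FilterError):
                filter_locus_reproducibility(gm, 0.99)

    def test_depth_boundary_triplet(self):
        gm = with_meta(
            make_gm([[0, 0, 0, 0], [1, 1, 1, 1]]), depth=[5.0, 501.0, 4.9, 500.0]
        )
        kept = filter_read_depth(gm, 5, 500)
        assert kept.locus_ids == ["L0", "L3"]

    def test_depth_hand_count(self):
        gm = with_meta(make_gm([[0] * 4, [1] * 4]), depth=[3, 5, 100, 600])
        assert filter_read_depth(gm, 5, 500).n_loci == 2

    def test_locus_callrate(self):
        # 20 samples, one missing call: 0.95 < 0.97 -> removed
        calls = np.ones((20, 2), dtype=np.int8)
        calls[0, 0] = M
        gm = make_gm(calls)
        assert filter_locus_callrate(gm, 0.97).locus_ids == ["L1"]
        assert filter_locus_callrate(gm, 0.0).n_loci == 2

    def test_monomorphic_definitions(self):
        gm = make_gm([[0, 0, M, 2], [0, 1, M, 2]])
        mask = monomorphic_mask(gm)
        # all-0 locus, all-missing locus and all-2 locus are monomorphic;
        # a single heterozygote shows both alleles
        assert mask.tolist() == [True, False, True, True]
        assert filter_monomorphic(gm).locus_ids == ["L1"]

    def test_secondaries_tiebreak_by_callrate(self):
        gm = with_meta(
            make_gm([[0, 0], [1, M]]), fragments=["f", "f"]
        )
        assert filter_secondaries(gm).locus_ids == ["L0"]  # call rate 1.0 beats 0.5

    def test_secondaries_unique_fragments_identity(self):
        gm = make_gm([[0, 1], [1, 0]])
        assert filter_secondaries(gm).locus_ids == ["L0", "L1"]


class TestCascade:
    def test_clean_data_is_identity(self):
        gm = make_gm([[0, 1], [1, 0], [2, 1]])
        out, report = run_cascade(gm, FilterConfig.first_pass())
        assert out == gm.with_recomputed_call_rates()
        assert [s.name for s in report.steps][1:] == [
            "individual_call_rate",
            "locus_reproducibility",
            "read_depth",
            "locus_call_rate",
            "monomorphic",
            "secondaries",
        ]

    def test_designed_fixture_exact_survivors(self, cascade_fixture):
        out, report = run_cascade(cascade_fixture, FilterConfig.first_pass())
        assert out.sample_ids == ["good1", "good2", "good3"]
        assert out.locus_ids == ["L0", "L6", "L7", "L8", "L9"]
        removed = report.removed_by_step()
        assert removed["individual_call_rate"] == ["badS"]
        assert removed["locus_reproducibility"] == ["L1"]
        assert removed["read_depth"] == ["L2"]
        assert removed["locus_call_rate"] == ["L3"]
        assert removed["monomorphic"] == ["L4"]
        assert removed["secondaries"] == ["L5"]

    def test_retention_is_monotone_and_counts_match(self, cascade_fixture):
        out, report = run_cascade(cascade_fixture)
        loci = [s.n_loci for s in report.steps]
        samples = [s.n_samples for s in report.steps]
        assert loci == sorted(loci, reverse=True)
        assert samples == sorted(samples, reverse=True)
        assert (report.steps[-1].n_samples, report.steps[-1].n_loci) == (
            out.n_samples,
            out.n_loci,
        )

    def test_determinism(self, cascade_fixture):
        out1, rep1 = run_cascade(cascade_fixture)
        out2, rep2 = run_cascade(cascade_fixture)
        assert out1 == out2
        assert rep1.to_dataframe().equals(rep2.to_dataframe())

    def test_second_pass_differs_only_in_locus_callrate(self):
        a, b = FilterConfig.first_pass(), FilterConfig.second_pass()
        diffs = {
            f for f in a.__dataclass_fields__ if getattr(a, f) != getattr(b, f)
        }
        assert diffs == {"locus_call_rate"}
        assert b.locus_call_rate == 0.95

    def test_disabling_a_step_never_shrinks_retention(self, cascade_fixture):
        full, _ = run_cascade(cascade_fixture, FilterConfig.first_pass())
        no_depth, _ = run_cascade(
            cascade_fixture,
            FilterConfig(read_depth_min=None, read_depth_max=None),
        )
        assert no_depth.n_loci >= full.n_loci

    def test_output_free_of_monomorphic_and_duplicate_fragments(self, study_pipeline):
        gm1 = study_pipeline["gm1"]
        assert not monomorphic_mask(gm1).any()
        assert gm1.locus_meta["fragment_id"].is_unique
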