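import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import clonecross as cc
from clonecross.matrix import groups_from_metadata

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_gm(calls, sample_ids=None, locus_ids=None, locus_meta=None):
    calls = np.asarray(calls, dtype=np.int8)
    ns, nl = calls.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(ns)]
    locus_ids = locus_ids or [f"L{j}" for j in range(nl)]
    return cc.GenotypeMatrix(sample_ids, locus_ids, calls, locus_meta)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study-like dataset, fixed seed."""
    return cc.generate_study_like_dataset(seed=1)


@pytest.fixture(scope="session")
def study_pipeline(study):
    """The study dataset taken through both QC passes and clone calling."""
    gm, sm, truth = study
    gm1, rep1 = cc.run_cascade(gm, cc.FilterConfig.first_pass())
    groups1 = groups_from_metadata(sm.loc[gm1.sample_ids])
    target = [s for s in gm1.sample_ids if sm.loc[s, "species"] == "target"]
    gm2, rep2 = cc.run_cascade(gm.subset(samples=target), cc.FilterConfig.second_pass())
    clones = cc.call_clones(gm2)
    return {
        "gm": gm,
        "sm": sm,
        "truth": truth,
        "gm1": gm1,
        "rep1": rep1,
        "groups1": groups1,
        "gm2": gm2,
        "rep2": rep2,
        "clones": clones,
    }
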