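"""Heterozygosity and inbreeding per management group, on genets.

Diversity is computed across distinct genotypes (one consensus genotype
per genet) so clonal over-sampling cannot inflate group statistics.
F1 seedlings are the most heterozygous group (their parents come from
the two diverged within-species lineages) and carry a negative F_IS
(heterozygote excess); the adult collection shows a positive F_IS
because pooling the diverged female with the males creates a Wahlund
deficit of heterozygotes.
"""

import clonecross as cc
from clonecross.workflow import genet_groups

gm, sample_meta, truth = cc.generate_study_like_dataset(seed=1)
target = sample_meta.loc[sample_meta["species"] == "target", "sample_id"].tolist()
gm2, _ = cc.run_cascade(gm.subset(samples=target), cc.FilterConfig.second_pass())
clones = cc.call_clones(gm2)

genet_matrix = clones.consensus_matrix(gm2.locus_ids)
groups = genet_groups(clones, sample_meta.loc[gm2.sample_ids])
table = cc.diversity_table(genet_matrix, groups)
print(table.round(3).to_string(index=False))
print("\nColumns: HO observed heterozygosity, HE = 2p(1-p), uHE its "
      "small-sample correction, FIS = 1 - mean(HO)/mean(uHE) "
      "(ratio-of-means; the mean-of-ratios variant is also reported).")

per_genet = cc.individual_ho_table(genet_matrix)
print("\nper-genet observed heterozygosity:")
print(per_genet.round(3).to_string(index=False))
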