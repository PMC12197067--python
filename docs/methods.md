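# Methods

This note documents the statistical models, defaults and design choices in
`clonecross`, and what the synthetic-data generator does and does not
emulate.

## Genotype representation

Genotypes are alt-allele dosage codes 0/1/2 with a distinct missing sentinel
(−1), never conflated with dosage 0. Reference/alternate orientation is taken
from the input file without re-polarisation: every statistic in the package
(heterozygosity, Weir–Cockerham θ, mismatch fractions, opposing-homozygote
rates, Mendelian crosses) is symmetric under relabelling the two alleles of
any locus, and the test suite asserts this invariance. VCF input is
restricted to biallelic records; multi-allelic records are a hard error
rather than being silently split, because every downstream statistic is
defined for biallelic SNPs. The DArT reader supports the one-row SNP report
dialect with native DArT genotype coding (0 = homozygous reference, 1 =
homozygous alternate, 2 = heterozygous, `-` = missing) and metadata columns
`CloneID`, `RepAvg`, `AvgDepth`; the two-row dialect is out of scope.

## QC cascade

Steps run in a fixed order — individual call rate, locus reproducibility,
read depth, locus call rate, monomorphic loci, secondaries — because order
changes results: locus call rates are recomputed over the *currently
retained* samples, which is what makes the two-pass "recall" workflow
(re-filtering after restricting to the target species) meaningful. All
thresholds are inclusive on the keep side: "below X" removes strictly < X,
and the depth band keeps min ≤ depth ≤ max. Entirely-missing loci count as
monomorphic (they carry no information). The secondaries step keeps one SNP
per sequenced fragment; the tie-break — highest current call rate, then
highest reproducibility, then first in input order — is not dictated by any
principle beyond determinism and preferring the better-genotyped marker.
Default thresholds are 0.25 / 0.99 / 5–500 / 0.97 (first pass) and the same
with locus call rate 0.95 (second pass).

## Clone detection

Ramets of one genet differ only by genotyping error, so the pairwise
mismatch fraction over co-called loci separates cleanly into a near-zero
within-genet mode and a much larger between-genet mode. Clone calling is
complete-linkage agglomerative clustering on that dissimilarity, cut at a
threshold (default 0.05). Complete linkage guarantees every within-genet
pair is below the threshold and prevents two true genets being chained
together through one noisy intermediate sample — the failure mode of single
linkage. Pairs sharing fewer than `min_shared` (default 50) co-called loci
are *incomparable*, and clustering refuses to run rather than treating them
as similar. Genet labels are assigned deterministically by each genet's
lexicographically smallest member. The consensus genotype per genet takes
the per-locus majority code; ties and all-missing loci become missing — a
consensus never invents a call.

The 0.05 default is calibrated against the error model below: expected
clone-mate dissimilarity is of order 2ε ≈ 0.01 with ε = 0.005, while
between-genet dissimilarity on a within-species polymorphic panel is ≳ 0.2.
Likelihood-based pedigree/clonality reconstruction (COLONY-style) is
deliberately out of scope: for clone detection the distance threshold is
sufficient and transparent, and parent–offspring screening is handled by the
opposing-homozygote statistic instead.

## Diversity statistics

Per-locus observed heterozygosity is the heterozygote fraction among
non-missing calls; group H_O is the mean over loci (the per-locus mean and
per-individual mean coincide on complete data). Expected heterozygosity is
2p(1−p) from the sample alt-allele frequency; the unbiased variant
multiplies by 2n/(2n−1) with n the called individuals at the locus — at the
genet-level group sizes here (5–7), that correction is material. F_IS is
reported in both aggregations, 1 − mean(H_O)/mean(H_E) (ratio of means,
the default, with unbiased H_E as reference) and the per-locus mean of
1 − h_o/h_e, because established toolchains disagree on this choice and the
two diverge noticeably in small structured groups; an undefined F_IS
(reference H_E of zero) is NaN, never 0. Loci monomorphic across the whole
input matrix are excluded from averaging for all groups alike, keeping group
comparisons on a common locus panel. Diversity in the pipeline is computed
across distinct genotypes (one consensus per genet), so clonal redundancy
cannot inflate group statistics; per-sample mode is available by flag.

## F_ST and PCoA

Between-group differentiation uses Weir & Cockerham's (1984) θ: per-locus
variance components a (among populations), b (among individuals within) and
c (within individuals) from per-population sample sizes, allele frequencies
and heterozygote fractions, combined as Σa / Σ(a+b+c) over loci with a
defined denominator. Negative estimates are reported unclipped — clipping
would bias means upward at near-zero differentiation. The implementation is
validated against an exact symbolic evaluation of the components on a
four-individual toy (θ = 2/3) and against fixation/copy limits.

Because group sizes range from 1 to 20, pairwise F_ST is also computed with
subsampling: each iteration draws n_sub (default 3) individuals per group
without replacement and the mean over defined iterations (default 1000) is
reported. Groups at or below n_sub are used whole. Iterations where θ is
undefined (monomorphic draws — common at n = 3) are excluded from the mean
and counted, never silently dropped. Per-pair RNG streams derive from the
master seed and the group labels, so results for one pair do not depend on
which other pairs are computed.

PCoA is classical metric MDS: missing dosages are mean-imputed per locus
(neutral to cluster placement), loci centred, Euclidean distances double-
centred and eigendecomposed. Per-axis percent variation is the eigenvalue
over the sum of positive eigenvalues; with no positive eigenvalue (all
samples identical) the result is empty with a warning. The implementation is
cross-checked in the tests against scikit-bio's independent PCoA.

## Parentage exclusion

A true parent transmits one allele per locus, so parent and offspring can
never be opposite homozygotes absent genotyping error. The violation rate is
the fraction of co-called loci with codes {0, 2}; it is symmetric (no
direction is assumed) and requires ≥ 50 comparable loci. Group-level
screening averages the rate over all seedling × candidate pairs and ranks
candidate groups ascending, reporting the margin to the next group; no
significance test is attached — the use is descriptive exclusion by rate
ordering, with the margins making the strength of exclusion explicit. The
hybrid-scenario test documents the method's limit: seedlings bred X × Y rank
*both* X and Y below an unrelated group, so the test excludes candidate
groups but cannot by itself distinguish a pure cross from a hybrid with one
parent in the implicated group.

## Cross simulation

Offspring are simulated per locus under Mendelian inheritance of unlinked
biallelic SNPs: each parent contributes one allele, heterozygotes contribute
either allele with probability 1/2, and a locus missing in either parent is
missing in the offspring — a management tool must never manufacture
genotype information. No linkage is modelled; no genetic map exists for such
species and the markers are sparse genome-wide SNPs. Broods default to 10
offspring, the approximate per-cross seed yield of the motivating system.
Pairs are scored by mean offspring H_O; expected values have closed forms
(0×2 → 1; identical homozygotes → 0; heterozygote × anything → 1/2) that
the tests verify distributionally. Self-crosses are never simulated (a
dioecious plant cannot self) and pairs known to be same-sex are excluded;
unknown-sex genets pair with everyone. Per-pair seeds derive from the master
seed and the sorted pair ids, so adding a genet to the collection leaves
every existing pair's simulated brood unchanged.

## Synthetic data generator

The generator emulates the structure of a minimal conservation collection:
20 in-situ samples in four clonal patches (2/7/3/8) realising 7 genets
(patch A one genet, B one, C two, D three with a 6+1+1 split); 12 ex-situ
adult samples realising 5 genets (6+2+2+1+1 members — one female genet,
four male, two genets shared with the wild population); 7 F1 seedlings bred
female × male within the collection; and four congener species (3+2+2+2
samples) at increasing divergence. Sexes are known for exactly 5 genets
(1 female, 4 male), so the 17 conspecific genets yield 130 permissible
crosses.

Allele frequencies follow a two-level Balding–Nichols hierarchy. A genus-
level ancestor carries common alleles (MAF uniform on [0.1, 0.5],
symmetrised), reflecting that reduced-representation markers are
ascertained as genus-level polymorphisms. The target species drifts from
that ancestor at F_species = 0.85, which makes most loci near-fixed within
the species — the low-diversity signature of a relict population — while
each congener drifts independently at its own divergence (0.15, 0.5, 0.75,
0.95), producing a monotone between-species F_ST ladder spanning roughly
0.5–0.9. Within the species, the wild/male lineage drifts mildly
(f_wild = 0.10) and the extinct-source lineage that contributed the single
female drifts more (f_source = 0.50): this is what separates the female
from the male cluster on PCoA axis 1, gives the adult group its positive
F_IS (a Wahlund effect from pooling the two lineages), and makes F1
seedlings more heterozygous than any adult group — the pattern the
breeding-pair ranking feeds on. A single-level model cannot reproduce the
F_ST ladder: pairwise θ between two populations is governed by the mean of
their divergences from the shared ancestor, so with a weakly drifted target
species it saturates near 0.5 regardless of the congener's divergence.

Genotyping error is dropout-dominated: a heterozygote loses one allele and
is called homozygous at rate ε = 0.005 per call, while the reverse
homozygote→heterozygote miscall is an order of magnitude rarer (0.0005).
This asymmetry matters structurally, not just cosmetically. False
heterozygotes are what turn genuinely monomorphic loci into spurious
within-species polymorphisms; those loci pass the monomorphic filter
*because* they carry an error, so a symmetric error model enriches the
clone-calling panel for errors and inflates clone-mate dissimilarity several
-fold (enough to split true genets at the 0.05 threshold). Dropout-dominated
error is also what DArT-style reproducibility scores indicate empirically.
Missing data are applied uniformly at 1% per call, with ten designed
high-missingness loci; 15 loci carry sub-threshold reproducibility, 12
out-of-band read depth, and 8% of loci are secondaries sharing a fragment
with another SNP, so the QC cascade has a known, independently re-derivable
set of work to do (`expected_cascade_removals` re-derives it with plain
numpy checks, sharing no code with the filtering module).

Default problem size is 3000 pre-QC loci, giving post-filter panels of
roughly 2300 (all species) and 500 (within species) — the same order as the
filtered panels the motivating workflow produces — while keeping the full
pipeline under ten seconds. What the generator does *not* emulate: linkage,
mutation, realistic coalescent demography, locus-specific missingness
correlated with depth, and the near-singleton frequency spectrum that can
push within-species heterozygosity of real relict populations far below
what a conditioned polymorphic panel shows here. Consequently, passing the
recovery suite demonstrates the pipeline's logic (clone partition recovery,
pedigree consistency, divergence ordering, heterosis of F1 seedlings), not
calibrated absolute values of H or F_IS for any particular real dataset.

## Numerical and degenerate-input conventions

Undefined statistics (F_IS with zero reference H_E, θ with no informative
locus, dissimilarity with too few shared loci) are NaN or hard errors, never
silently 0. Subsampled F_ST means are over defined iterations with the
undefined count reported. PCoA eigenvalues are thresholded at a
scale-relative machine tolerance before being declared positive. All
stochastic operations take explicit seeds; the workflow derives every
stage's stream from one master seed, and a re-run with the same config and
inputs is byte-identical.
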