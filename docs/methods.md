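# Methods

This note records the statistical definitions, the estimator calibrations and
the deliberate numerical choices behind `metapopdiv`, in the order the
pipeline applies them.

## Data model and cohort filters

Genotypes are biallelic SNP doses in {0, 1, 2} (count of the reference
allele), −1 for missing, read from PLINK-style text PED/MAP pairs. The
reference allele at each locus is the first allele label encountered in PED
file order; every downstream statistic is invariant to this choice (all are
symmetric in p and 1 − p), so the convention only affects the sign of the
internal dose coding.

Two cohort filters precede all analysis:

- **Minimum sample size** (default 6 diploids): subpopulations sampled below
  this are removed, because rarefaction to the global minimum copy count and
  frequency estimation both degenerate on tiny samples. The outgroup is
  exempt by default (it is a pooled reference, not an inference target).
- **Null-allele screen** (default FIS > 0.9 in any subpopulation): the
  within-subpopulation heterozygote deficit FIS = 1 − Ho/He flags loci where
  a non-amplifying (null) allele converts heterozygotes to apparent
  homozygotes. FIS is undefined (and never filtered on) at monomorphic or
  unobserved loci. Note that in very small subpopulations a locus with no
  observed heterozygote reaches FIS = 1 by chance alone, so the screen is
  conservative on small samples; this mirrors the screening practice the
  filter reproduces.

## Gene-diversity partition (HT = HS + DG)

Per subpopulation, HS_i is the mean over its observed loci of
1 − p² − (1 − p)². The Nei minimum distance between subpopulations i and j is
the mean over shared observed loci of ½ Σ_a (p_ia − p_ja)², which for
biallelic loci equals (p_i − p_j)². With n subpopulations and equal weights:

- HS = mean_i HS_i
- DG = (1/n²) Σ_ij D_ij over all *ordered* pairs including the zero diagonal
- HT = HS + DG

The n² normalization is what makes the partition exact: HT then equals the
gene diversity of the equal-weight pooled frequency vector p̄ = mean_i p_i,
an identity the test suite verifies to 1e-12 on 1,000 random instances.
Equal subpopulation weights (rather than census weights) are deliberate: the
analysis treats each subpopulation as one conservation unit.

## Allelic-richness partition (AT = AS + DA) and rarefaction

Allele counts are standardized by hypergeometric rarefaction to a common
number of gene copies g, chosen as the smallest per-subpopulation-per-locus
observed copy count (configurable override). The probability that an allele
with N_a of N copies is absent from a random g-copy sample is
Q = C(N − N_a, g) / C(N, g), computed in log-space via `gammaln` for
numerical safety; the expected rarefied allele count is Σ_a (1 − Q_a).

- AS_i = mean over usable loci of (expected rarefied count − 1)
- d_ij symmetrizes the directed expected counts of alleles present in i's
  g-sample and absent from j's: d_ij = ½ (v_ij + v_ji),
  v_ij = mean_loci Σ_a (1 − Q_ia) Q_ja
- DA = (1/n²) Σ_ij d_ij, AT = AS + DA
- Private richness P_i = mean_loci Σ_a (1 − Q_ia) Π_{j≠i} Q_ja (expected
  alleles seen only in i's sample), computed by a log-sum product with an
  exact fallback when some Q = 0.

All three rarefaction primitives are pinned against an exhaustive
subset-enumeration oracle (exact rational arithmetic, all configurations up
to N = 12) in the acceptance suite.

## Leave-one-out contributions

For target subpopulation k, all components are recomputed on the set minus k
and reported as signed percentages of the *full-set total*:
cHS_k = 100 (HS − HS₋ₖ)/HT, cDG_k = 100 (DG − DG₋ₖ)/HT,
cHT_k = cHS_k + cDG_k (exact), and likewise cAS/cDA/cAT over AT. Three
freezing rules keep removals comparable:

1. the outgroup is retained in every removal and is not a default target;
2. the rarefaction size g is frozen at its full-set value;
3. the usable-locus set is frozen at the full-set mask.

A homogeneous metapopulation yields exactly zero for every contribution.

## Effective size

### LD method

Within one subpopulation, r² is the squared Pearson correlation of genotype
doses over complete cases — the composite (Burrows-style) LD measure
appropriate for unphased genotypes. The mean r̂² over retained locus pairs
(MAF ≥ Pcrit = 0.05, recomputed within the subpopulation) estimates
drift LD plus a sampling term. Two small-sample corrections are applied,
both matched to this specific statistic:

- **Sampling null**: for independent loci, E[r²] = 1/(S − 1) exactly for the
  squared sample correlation of S observations (verified empirically in the
  calibration harness). Published constant sets of the quadratic-in-1/S form
  are retained in a single constants table (`LD_BIAS_CONSTANTS`) so
  alternative calibrations — e.g. those tuned to the Burrows Δ estimator,
  which have a larger leading term — can be swapped in and audited; the
  defaults are the Pearson-matched values (a₁ = 1 on 1/(S−1)).
- **Attenuation**: squared sample correlations shrink the population signal,
  E[r̂²] ≈ ρ²(1 − 2/(S − 1)) + 1/(S − 1), so the null-subtracted signal is
  divided by (1 − 2/(S − 1)) before inversion.

The drift signal is inverted by the unlinked-pair drift expectation
E[r²_drift] = 1/(3Ne), giving Ne = 1/(3 r²_drift); a non-positive signal
maps to Ne = +∞ (no detectable drift). The CI is a delete-one-individual
jackknife on the drift scale (±1.96 SE) transformed to Ne, so an interval
crossing zero yields an infinite upper bound. The jackknife freezes the
MAF-screened locus set at the full sample (re-screening per replicate would
make replicates incomparable) and is computed by rank-1 downdates of the
centered Gram matrix, which makes it O(individuals × loci²-free) rather than
a full recomputation per replicate.

Calibration: under an individual-based Wright–Fisher truth with S = Ne and
2,000 unlinked loci, 30 replicates per level, the median estimate is within
+11.0% / +4.2% / +1.1% of Ne = 25/50/100 with jackknife CI coverage
25/30, 30/30, 26/30. The recovery harness feeds the unlinked panel directly
to the estimator; LD pruning is *not* part of the harness, because on
unlinked data the r² > 0.2 cut truncates the upper tail of the drift
distribution and removes genuine signal (at S = 25 the threshold is only a
few SD above the mean pair r²). Pruning exists to enforce
quasi-independence on real, physically linked panels.

### Molecular-coancestry method

The identity-in-state kernel for a pair with doses x, y is
s = [xy + (2 − x)(2 − y)]/4. Per locus the unrelated-pair expectation is the
sample expected homozygosity h = p̂² + q̂², and the per-pair kinship is
k = (s − h)/(1 − h) on polymorphic loci, combined across loci with weights
w = 1 − h (upweighting balanced frequencies), which reduces to
Σ(s − h)/Σ(1 − h) over co-observed loci. The drift signal f1 is the mean
over all distinct pairs of the **positive part** of the weighted kinship,
and Ne = 1/(2 f1) (+∞ when f1 ≤ 0).

The positive-part reading is a deliberate design decision. The raw
all-pair mean is mathematically incapable of being positive: the kernel
satisfies Σ_ordered-pairs s = n²h per locus, which forces the all-pair
weighted mean to (Ho/2 − He)/((n − 1)He) ≤ 0 for every sample, i.e. the
naive mean estimates nothing. Restricting to the positive part recovers the
putative-sib logic of molecular-coancestry Ne estimators: unrelated samples
give f1 at a small noise floor (very large/infinite Ne), family-structured
samples give small finite Ne (two 10-member full-sib families → Ne ≈ 8),
and in drift simulations with family structure Ne(coancestry) ≤ Ne(LD) in
the majority of replicates. Its CI is a delete-one-locus jackknife,
computed by exact per-locus downdates of the kinship numerator and
denominator sums.

## PCA, sign classes, CMH and correlations

PCA mean-imputes missing doses per locus, centers by 2p̂ and scales by
√(2p̂(1 − p̂)), then uses SVD; component signs are fixed by making each
component's largest-magnitude loading positive, so results are fully
deterministic. Contribution signs (cHT, cAT) are cross-classified against
sample-size classes (schemes: <10, <20, or three-way) and tested with a
generalized R×C Cochran–Mantel–Haenszel statistic, Q = G'V⁻G with the
hypergeometric covariance per stratum; with a single stratum Q equals
(N − 1)/N times the Pearson chi-square (closed-form check: [[10,20],[20,10]]
→ 59/9 ≈ 6.5556, df 1). Correlations (Pearson and mid-rank Spearman)
exclude non-finite pairs (e.g. infinite Ne) pairwise and report the counts.

## Synthetic generators

- `simulate_metapopulation`: Balding–Nichols — per locus an ancestral
  frequency p₀ ~ U(0.05, 0.95), subpopulation frequencies
  Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) (variance exactly F·p₀(1−p₀)), binomial
  genotypes, optional admixed outgroup at the mean frequency, uniform
  missingness. The returned truth record (p₀, per-subpopulation
  frequencies) lets tests recompute expected quantities exactly. A
  frequency-variance moment estimator (`moment_fst`) recovers F = 0.2 within
  ±0.004 at the calibration design (3 × 100 diploids, 5,000 loci).
- `simulate_wright_fisher`: *individual-based* forward simulation — each
  offspring draws two uniform parents and one Bernoulli(dose/2) gamete per
  locus from each. Individual-based transmission matters: simulating loci
  as independent binomial frequency paths would produce zero inter-locus
  drift LD and no signal for the LD estimator. Selfing is allowed (true
  random union of gametes), so census = effective size by construction; the
  known O(1/N) bias of this idealization is far below the 20% recovery
  tolerance.
- `plant_private_allele` / `inject_null_allele_locus`: targeted effect
  generators for the sign tests (a private allele strictly increases the
  target's cAT; a null allele drives FIS → 1 and is caught by the filter).

Default problem sizes (6 subpopulations of 6–60 diploids, 1,000 loci;
recovery harness at 2,000 loci × 30 replicates) are this package's own
choices, sized so the full verification battery runs in ~2 minutes on one
CPU.

## Limitations

- Biallelic SNPs only; the rarefaction code paths are exact for two alleles
  per locus (the data model enforces this at parse time).
- Equal-weight (conservation-unit) averaging throughout; census-weighted
  partitions are out of scope.
- The LD-Ne calibration assumes unlinked or pruned-to-quasi-independence
  panels and random mating; physical linkage or admixture inflates r² and
  biases Ne downward.
- The coancestry method estimates the effective number of breeders from
  within-sample family structure; on structure-free samples it returns the
  noise floor (very large/infinite Ne) by design.
- Group-level pooled partitions are descriptive only: pooling changes copy
  counts, so pooled rarefaction is not comparable with subpopulation-level
  rarefaction.
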