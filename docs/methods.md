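# Methods

`msatpop` implements the population-genetic inference stack used to study
demographic histories of river-resident brown trout populations from
microsatellite genotypes: per-population diversity, two bottleneck tests,
differentiation and tree building, a structured-coalescent simulator, and an
approximate-Bayesian-computation (ABC) engine for dating divergences and
size changes.  This note records the models, the parameter choices, the
numerical decisions, and the limits of what the synthetic experiments show.

## Genotype model

Genotypes are diploid allele pairs at microsatellite loci, held as integers
in *repeat units* (fragment-size codes are floor-divided by the motif length
at ingest).  Missing data are whole-pair missing; every per-locus statistic
uses only the individuals genotyped at that locus (pairwise-available
policy, matching the standard desktop programs).  GENEPOP is the exchange
format; since plain GENEPOP carries no population names, the writer encodes
them as an identifier prefix (`<pop>:<ind>`) that the reader strips, which
makes `read(write(x)) == x` exact.

## Diversity statistics

* Allelic richness `A_R(g)` is the expected allele count in a random
  subsample of `2g` gene copies, computed from the exact hypergeometric
  form `sum_i [1 - C(G-G_i, 2g)/C(G, 2g)]`; `g` defaults to the smallest
  common sample so every population is comparable.
* `H_E = 1 - sum(p^2)` (uncorrected gene diversity; the `2n/(2n-1)`
  unbiased variant sits behind a flag because the two differ in the third
  decimal at these sample sizes), `H_O` = fraction of heterozygotes.
* Group comparisons permute whole populations between two groups (the
  population, not the individual, is the exchangeable unit) with the
  statistic `|difference of group means|`; p-values use the `+1`
  correction, and the exact enumeration replaces sampling when there are
  fewer distinct assignments than requested permutations.

## Bottleneck tests

**Heterozygosity excess.**  Shortly after a decline, rare alleles are lost
faster than gene diversity decays, so the observed per-locus gene diversity
exceeds its mutation-drift-equilibrium expectation *given the observed
allele count k*.  The equilibrium distribution of `H | k` is simulated on
coalescent genealogies under a two-phase mutation model (TPM: single repeat
steps with probability `p_s = 0.78`, otherwise geometric multi-step jumps
with mean 3.1).  Because `H | k` under stepwise mutation also depends on
`theta = 4*N_e*mu` (homoplasy), the default conditioning is
**theta-matched**: a multilocus theta is chosen so that the simulated
equilibrium expected allele count equals the mean observed allele count
across loci (all loci of one population share theta), and each locus is
then conditioned on its exact `k` by rejection, served from a pooled,
cached simulation (30,000 loci per (sample size, theta) pool).  A
constructive, theta-free variant (mutations dropped one at a time at
uniform points until `k` states exist) is available as
`method="sequential"`; it is simpler but measurably biased at moderate
diversity and is kept for reference.  Per-locus standardized differences
`D = (H_obs - mean)/SD` feed a one-tailed Wilcoxon signed-rank test for a
positive median (exact null for <= 25 informative loci).

*Calibration and its limits.*  On equilibrium datasets simulated at the
equilibrium configuration used throughout the bottleneck analyses
(`theta` uniform on [0.1, 0.2], i.e. pre-decline `N_e` of 50-100 at
`mu = 5e-4`), the empirical type-I error at `alpha = 0.05` is ~0.05.  At
much higher diversity (`theta >= 2`) the one-tailed test over-rejects
(0.15-0.18 observed): the conditional law of `H | k` is left-skewed, so
its median exceeds its mean and the signed-rank symmetry assumption fails.
This is a property of the published procedure itself; significant results
from very diverse populations should be read with that in mind.

**M-ratio.**  `M = k/(r+1)` per locus (`r` = allele-size range in repeat
units; monomorphic loci count as `M = 1` by convention), averaged over
loci.  The critical value `M_c` is the 5% quantile of mean M over 10,000
equilibrium datasets with `theta` drawn uniformly from [0.1, 0.2] under the
same TPM — at the study configuration (23 loci, 40 diploids) this
reproduces the published critical value near 0.87.

## Differentiation and trees

`F_ST` is Weir & Cockerham's theta, accumulated as ratios of summed
variance components over alleles and loci; pairwise significance permutes
individuals between the pair holding sample sizes fixed.  Distances use the
Cavalli-Sforza & Edwards chord distance
`d = (2/pi) * sqrt(2*(1 - sum_a sqrt(x_a y_a)))` averaged over loci.
Neighbor-joining is deterministic: smallest Q wins, ties broken by
lexicographic label order; negative branch lengths are clamped to zero with
the deficit moved to the sibling edge.  Bootstrap supports resample loci
with replacement and report, for each internal bipartition of the
full-data tree, the percentage of replicates containing it.

## Coalescent simulator

The simulator runs the structured coalescent backwards in time over named
demes with piecewise-constant sizes: within a deme of size `N`, `k`
lineages coalesce at rate `k(k-1)/2/(2N)` per generation (continuous-time
approximation of Wright-Fisher; adequate for `N >= 10`), and merge events
relocate lineages to ancestral demes.  Mutations are Poisson on branches;
each shifts the allele state by a signed generalized-stepwise jump
(single step with probability `p_s`, else `1 + Geometric` with mean
`delta_g`), reflecting at the bounds of a 40-state contiguous lattice
(root at the midpoint).  Per-locus rates are Gamma-distributed across loci
(shape 2) around the mean rate.  Validation includes the textbook pairwise
TMRCA (`2N`), KS-equivalence of a zero-aged split with panmixia, the
Ohta-Kimura closed form `H = 1 - 1/sqrt(1 + 8*N*mu)` for unbounded
single-step mutation, and a distributional cross-check of a two-epoch
demography against msprime.

## Packaged scenarios

Five lineages represent the population groups: clean, Red River,
Crowlas/Trevaylor, downstream Hayle, upstream Hayle.  The **selected
hypothesis** derives each metal lineage independently from the clean
lineage at a single time `t2`, with the within-Hayle split at `t1 < t2`;
each metal lineage carries a bottleneck: looking backwards, size `N` on
`[0, db)` and pre-decline size `N2` on `[db, t2)`.  Because the posterior
medians put `db` for the Hayle (180 generations) older than `t1` (38.9),
the recovery leg runs on the merged Hayle lineage: upstream size on
`[t1, db)`, then `N2` to `t2`; if a prior draw instead puts `db < t1`, the
size change applies inside both daughter lineages.  The **alternative
hypothesis** derives all five lineages — the Hayle pair not nested —
independently from an unsampled common ancestor at `t2` with no
bottlenecks.  (Merging metal lineages *into* the clean deme is
probabilistically identical to merging everything into a separate ancestor
of the same size, so the distinguishing features of the selected scenario
are the nested Hayle split and the bottleneck epochs; the alternative is
deliberately constructed without either.)

Priors are uniform: all sizes 10-10,000 diploids, `t2` 10-10,000 and `t1`
10-3,000 generations, bottleneck durations 10-300 generations, mean
mutation rate 1e-4 to 1e-3; constraints `t2 > t1` and `t2 > db` are
enforced by rejection.

## ABC engine

Summary statistics per population group (pooled): mean number of alleles,
mean gene diversity, mean M, and (for model checks) mean allele-size
variance; per group pair: `F_ST` and a mean classification index — the
mean over individuals of one group of the log10 multilocus genotype
likelihood under the other group's allele frequencies (unseen alleles get
a `1/(2n+1)` pseudo-count), symmetrized.  Statistics are normalized by
their median absolute deviation across the reference table.

* *Scenario choice*: retain the closest fraction of rows by Euclidean
  distance, fit a (ridge-stabilized) multinomial logistic regression of
  scenario identity on the statistics, and evaluate at the observed point.
* *Parameters*: local-linear regression adjustment of the retained draws
  on the statistic discrepancies; draws are logit-transformed onto their
  prior range first, so adjusted draws and the equal-tailed 95% intervals
  always honour the prior bounds.  "95% CI" is reported as the 2.5-97.5
  percentile interval of the adjusted draws.
* *Model check*: PCA of the normalized simulated statistics with the
  observed point tested against per-component 2.5-97.5 percentile bands.
* Times convert to years at 4 years/generation (present year 2010 for
  calendar labels).

## Synthetic data

`generate_study_like` emulates the study design — 15 populations in the 5
groups, per-population diploid counts of 27-49, 23 loci — under the
selected scenario at its posterior-median parameters, with each sampled
population as its own deme merging into its group lineage 10 generations
ago (the study reports no within-group split times; a shallow default
keeps same-group populations weakly differentiated).  The generator
reproduces the qualitative patterns (metal groups less diverse than clean;
Hayle lowest; depressed M after bottlenecks) with known ground truth for
recovery tests.  It does **not** emulate genotyping error, null alleles,
family structure (the study removed full sibs before analysis), selection,
or migration after splits — so passing tests demonstrate correctness of
the inference machinery under the model, not robustness to those
real-data complications.

## Problem sizes used by the packaged experiments

The desk-scale experiments use 5 demes x 20 diploids x 23 loci with 1,000
reference rows per scenario, retaining 10% of rows for scenario choice and
20% (200 rows) for parameter estimation; the type-I calibration uses 400
datasets of 30 diploids x 23 loci; the M-ratio critical value uses 10,000
simulated datasets.  These sizes are the package's own choice of
reproducible desk scale; the corresponding full-scale analysis (10^5-10^6
reference rows, 1% retention) is a matter of running the same code longer.

## Known limitations

* The heterozygosity-excess test's one-tailed Wilcoxon over-rejects at
  high diversity (see above).
* The classification index aligns individuals across loci by their
  position among genotyped individuals, which is exact for complete data
  and approximate when genotypes are missing.
* No migration between demes after splits; the scenarios cannot express
  gene flow, mirroring the hypotheses they implement.
* Pairwise `F_ST` can be slightly negative (the estimator is unbiased, not
  truncated); the tree-building path uses chord distances, not `F_ST`.
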