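# Methods

`ssrtrace` implements the statistical machinery used to trace the origin
and inter-island spread of an invasive plant from co-dominant
microsatellite (SSR) genotypes: null-allele-aware diversity and distance
statistics, a coalescent simulator with stepwise mutation, and an
approximate Bayesian computation (ABC) engine for colonization-scenario
choice. This note records the models, their assumptions, the defaults,
and the choices made where the design was genuinely open.

## Data model

A dataset is a diploid genotype matrix: individuals x loci, each cell an
unordered pair of integer allele sizes or a missing sentinel, with
population labels, optional sub-region labels, and optional coordinates.
Allele identity is the integer size on each locus's reported scale; sizes
differing by one unit are distinct alleles (no binning), because the
stepwise mutation model operates on integer repeat ladders. Mainland
sub-regions follow a half-open latitudinal banding: a 720-km north-south
transect is tiled into three 240-km bands `[a, b)` (a sample exactly on a
boundary falls in the southern band) crossed with three physiographic
axis labels, giving nine regions.

## Diversity statistics

* **Expected heterozygosity** is Nei's unbiased gene diversity
  `(n/(n-1)) (1 - sum p_i^2)` with `n` the gene count (twice the typed
  individuals); per-population He is the mean over loci with data.
* **F_IS** is `1 - Ho/He`. The multi-locus value uses the ratio of the
  mean Ho to the mean He rather than the mean of per-locus ratios; the
  ratio-of-means form reproduces the reconstruction of published
  per-population values and is less noisy at loci with small He.
* **Rarefied allelic richness** is the exact hypergeometric expectation
  of the number of distinct alleles in a subsample of `g` genes
  (`sum_i 1 - C(N - N_i, g)/C(N, g)`), averaged over loci; cells with
  fewer than `g` genes are excluded from the mean. The conventional
  standards are 160 genes for mainland-vs-island comparisons and 16 genes
  for comparisons among the small mainland regions. Rarefied private
  allelic richness multiplies, per allele, the probability of appearing
  in the focal subsample by the probability of being missed in every
  other population's subsample (a Kalinowski-style approximation that
  ignores the joint sampling of alleles within a locus).
* **Hardy-Weinberg tests** use the genotype chi-square statistic with a
  Monte-Carlo null built by re-pairing the observed gene copies at
  random (permutation conditional on allele counts; default 1000
  permutations). This matches the behavior of the common R
  implementations and stays calibrated with many rare alleles, where the
  asymptotic chi-square is not. **Linkage tests** permute one locus's
  genotypes across individuals and use the two-locus contingency
  chi-square.
* **Multiple testing** uses the Benjamini-Yekutieli step-up procedure
  (Benjamini-Hochberg inflated by the harmonic factor `c(m)`), valid
  under arbitrary dependence. Adjusted values are monotone in rank and
  capped at 1; the adjustment is not idempotent and is never re-applied.
* **He comparisons**: a two-sided permutation test of the mean-He
  difference that permutes individuals between two populations (999
  permutations by default; loci are kept intact, since He is a
  per-locus functional of allele frequencies), plus paired Wilcoxon
  signed-rank and Mood median tests over per-locus He vectors delegated
  to scipy.
* **Evanno delta-K** post-processes a table of clustering log-likelihood
  means and SDs over replicate runs:
  `dK(K) = |L(K+1) - 2L(K) + L(K-1)| / sd(K)`, undefined at the
  endpoints and wherever the SD is zero; the chosen cluster number is
  the argmax over defined values.

All permutation and Monte-Carlo procedures take an explicit seed
(default 20210417).

## Null alleles

A null allele fails to amplify: genotypes with one null copy type as
homozygotes for the visible allele and null homozygotes type as blanks.
Assuming Hardy-Weinberg proportions within each locus x population, an
EM algorithm estimates the visible-allele frequencies and the null
frequency beta. The default ("coestimate") variant lets blanks mix true
null homozygotes with a co-estimated locus-wide technical-failure rate;
an "ignore" variant drops blanks and conditions the likelihood on the
genotype being typed (implemented by augmenting the E-step with the
expected number of unobserved null homozygotes). Defaults: tolerance
1e-6 on the largest parameter change, at most 1000 iterations,
initialization at raw frequencies scaled by 0.9 with beta = 0.1. The
observed-data log-likelihood is non-decreasing across iterations (an EM
guarantee asserted in the tests).

Corrected statistics:

* **Corrected He / F_IS** recompute the unbiased He from the corrected
  frequency vector with the virtual null included as an ordinary allele
  class (the INA-style vector); when beta > 0 this raises He relative to
  the raw value. Renormalizing over the visible alleles alone would
  leave He essentially unchanged — masking inflates every visible
  allele's count proportionally — which is why the null class must stay
  in the vector.
* **ENA-corrected F_ST** computes Weir-Cockerham theta from the
  EM-corrected visible frequencies left on the full scale (summing to
  `1 - beta`), with the per-allele variance components of the null class
  excluded from the ratio-of-sums and heterozygosity taken at its HWE
  expectation. The uncorrected estimator is the standard genotypic
  Weir-Cockerham theta. A caveat our simulations made explicit: when
  null calls are independent noise, the genotypic theta is already
  nearly unbiased (visible allele counts inflate proportionally); the
  ENA correction earns its keep when the null is a heritable allele
  class whose frequency differs between populations through shared
  ancestry, which is how the correction is benchmarked.
* **Chord distance (D_CH)** uses the per-locus form
  `(2/pi) sqrt(2 (1 - sum_a sqrt(x_a y_a)))` averaged over shared loci
  (several scalings circulate in the literature; this one is pinned by
  the tests). With the INA flag the virtual null class participates as
  an ordinary allele; without it, frequencies are renormalized over
  visible alleles.

## Distances, trees, ordination, AMOVA, Mantel

* **Nei (1972) standard distance** `-ln(Jxy / sqrt(Jx Jy))` with gene
  identities summed over loci before the ratio.
* **Neighbor joining** (scikit-bio's Saitou-Nei implementation) with
  negative branch lengths clamped to zero and the deficit moved to the
  sibling edge; node support comes from resampling the loci (not
  individuals) with replacement, support being the percentage of
  replicate trees containing each bipartition of the reference tree.
* **PCoA** is classical metric scaling of the double-centered squared
  distances; negative eigenvalues are reported, never silently dropped.
  Individual-level distances encode each individual as its
  within-individual allele frequencies (0 / 0.5 / 1 per allele column),
  with missing loci mean-imputed within the individual's population so
  the Euclidean distance stays defined under missingness.
* **AMOVA** decomposes allele-indicator sums of squares into three
  levels (among populations / among individuals within populations /
  within individuals), with unequal-sample-size coefficients, missing
  calls skipped, and loci pooled by summing SS and df. Significance: the
  among-population component permutes individuals among populations; the
  among-individual component permutes gene copies among individuals
  within populations.
* **Mantel** uses Spearman rho over upper-triangle pairs with a
  one-sided (positive-association) permutation p-value, jointly
  permuting rows and columns of the second matrix; geographic distances
  are haversine great circles (R = 6371 km) between group centroids.

## Coalescent simulator

Demography is an event list over named populations: piecewise-constant
diploid sizes, merges (splits viewed forward in time), two-parent
admixtures with proportion `r`, and optional continuous per-lineage
migration (used for the mainland stepping-stone). Between events the
standard continuous-time approximation applies: `k` lineages in a
population of size `N` coalesce at rate `k(k-1)/2 / (2N)` per
generation. Scenario validation checks event consistency and that every
sampled population reaches a single ancestor before any simulation
starts. Mutation is strict single-step SMM: Poisson(mu x branch length)
mutations per branch, each +-1 repeat with probability 1/2, sizes never
clipped; alleles are repeat counts. Time is generations throughout;
absolute `N` and `mu` are primary, so mutation-scaled quantities are
derived, never inputs. One root seed feeds deterministic per-locus
streams (`SeedSequence((seed, locus))`), so adding loci never shifts the
randomness of earlier ones. Founder-flush introductions are encoded as
an instantaneous size drop to the founder size for a bottleneck duration
followed by the present size.

The simulator's closed-form anchors (tested): pairwise TMRCA mean `2N`;
total height `4N(1 - 1/n)`; SMM equilibrium He
`1 - 1/sqrt(1 + 8 N mu)`; between-population `(delta mu)^2 = 2 mu t`;
and agreement with msprime on a two-island migration model.

Time scaling: a mutation-scaled duration `D_g mu` divided by
`mu = 3.5e-4` per locus per generation gives generations (rounded), and
generations times the 2-year minimum generation time give a minimum age
in years.

## Scenario library

Three analysis stages are encoded as template sets sharing priors.
Structural time-order constraints live in per-template feasibility
predicates enforced by rejection at draw time. Priors default to wide
uniforms (times) and log-uniforms (sizes), with admixture proportions
uniform on [0, 1]; the shipped bounds are in `ssrtrace/scenarios.py` and
round-trip through a YAML schema. Only the topologies named in the
source analyses are pinned; the remaining members of the 16-scenario
stage-1 and 9-scenario stage-2 sets are systematic completions over the
allowed source relations (stage 1: four acyclic backbones for
(SCY, ISA/FLO) — including a dual mainland x SCY introduction for
ISA/FLO — crossed with four SCZ sources) and are flagged as
reconstructions. The final model chains Mainland -> SCY (t4) -> FLO
(t3) -> ISA (t2) with SCZ from SCY (t1), t4 > t3 > t2 > t1, and a
founder bottleneck at each introduction.

## ABC engine

Summary statistics per population (mean allele number, mean unbiased
gene diversity, mean allele-size variance), per pair (the same on the
pooled pair, Weir-Cockerham F_ST from frequencies with HWE
heterozygosity, shared-allele distance DAS computed by optimal
two-allele matching between cross-population individual pairs, and
Goldstein's `(delta mu)^2` as the squared difference of mean allele
sizes averaged over loci), and an admixture statistic per designated
trio: the least-squares coefficient `alpha` minimizing
`||f_adm - alpha f_P1 - (1 - alpha) f_P2||^2` over per-locus union
supports, clamped to [0, 1]. The statistic list is configurable; the
default includes every statistic class.

Rejection draws scenarios uniformly, parameters from the priors under
the feasibility constraints, simulates, and retains the closest 1% by
Euclidean distance on statistics standardized by the simulated pool's SD
(zero-variance statistics dropped with a warning). Scenario posterior
probabilities come from a multinomial logistic regression of the
scenario label on the standardized statistics centered at the observed
vector; the fitted probabilities at the observed point then come from
the intercepts alone. A mild ridge penalty keeps the fit defined under
quasi-separation (an earlier variant that first reduced the statistics
to linear-discriminant axes discarded discriminating information and
recovered the true scenario measurably less often); confidence
intervals propagate the intercept covariance (inverse Fisher
information at the fit) through the softmax. On failure the retained proportions with a
binomial CI are returned, flagged. Parameter posteriors use the
local-linear (Beaumont) adjustment on transformed scales — log for sizes
and times, logit for proportions — with residual shifting to the
observed point; adjusted draws violating the scenario's structural
constraints are dropped, and a singular regression falls back to the
unadjusted rejection posterior, flagged. Model checking simulates from
the posterior predictive and reports, per statistic, the fraction of
simulated values below the observed (a statistic "fits" in [0.05,
0.95]), the percentage of fitting statistics, and the observed point's
squared Mahalanobis distance in the leading principal components of the
simulated statistics.

Desk-scale budgets: the reference analyses here use 20,000 simulations
per table with samples of 10-15 diploids per population (the published
analyses used 0.9-1.6 million simulations at the full sample sizes; the
engine accepts any budget). Two properties of these experiments are
worth stating plainly. First, scenario recovery depends sharply on where
the truth sits in parameter space: with pseudo-observed parameters drawn
from the priors — the fully calibrated experiment — the true stage-2
topology attains the highest posterior probability in roughly 40-55% of
replicates (against an 11% chance floor over 9 scenarios), because many
prior draws are genuinely near-unidentifiable (mirror orderings of the
island chain when introduction times almost coincide, or founder
bottlenecks that erase the ordering signal). The headline recovery
experiment therefore fixes a reference parameter point in the
identifiable regime — Floreana colonized several hundred generations
before Isabela through a real bottleneck — where recovery runs around
70-75%; the acceptance script reports both rates. Second, an admixture
proportion is only estimable when the parent lineages are
differentiated and the admixed population is young; its recovery
experiment likewise fixes a reference point in that regime (parents
split ~1500 generations ago, admixed population founded 40 generations
ago), mirroring the wide credibility intervals the method produces
elsewhere.

## Synthetic data generator

`generate_study_like` emulates the study design: 376 diploids at 11
loci — Mainland 96 (regions 8/13/12/11/11/8/10/13/10), Isabela 95,
Santa Cruz 80, San Cristobal 94, Floreana 11. The mainland is a
five-deme 1-D stepping-stone along the latitudinal axis (deme size 8000,
nearest-neighbour migration 3e-4 per lineage per generation, demes
merging at ~8000 generations), with the nine regions mapped onto demes
by latitudinal position and given synthetic centroid coordinates. The
islands follow the final colonization model with introduction times at
the inferred point estimates (t4 = 1710, t3 = 211, t2 = 119, t1 = 34
generations) and island sizes (SCY 1000, FLO 150, ISA 1000, SCZ 5000;
founder sizes 5/30/100/10, 20-generation bottlenecks) chosen once so
that drift since each introduction reproduces the reported diversity
ordering (mainland He ~0.79 at SMM equilibrium; island He between ~0.15
and ~0.45; mainland allelic richness an order of magnitude above the
islands). Null alleles are overlaid post-simulation: a per-locus beta
drawn uniformly from [0, 0.33] masks each gene copy independently
(apparent homozygotes, blank null homozygotes), plus 2% random
missingness; the coalescent engine itself stays null-agnostic. Every
dataset ships with a truth record (seed, demography, per-locus x
population beta, missing rate, region-deme map) sufficient to score any
recovery experiment.

What the generator does *not* emulate: the real loci's allele-size
distributions and per-locus mutation-rate differences, selfing and
clonal reproduction (the high inbreeding the real survey shows beyond
its null-allele component), two-dimensional mainland geography, and any
second independent introduction to Isabela/Floreana. Tests passing on
synthetic data therefore demonstrate that the estimators recover known
truth under the stated model, not that the model captures every feature
of the real populations. A separate heritable-null masking helper
(`mask_heritable_null`) designates a real allele as the null, the regime
in which the uncorrected F_ST is biased and the ENA benchmark is run.

## Numerical choices and degenerate inputs

Monomorphic loci: He = 0, F_IS undefined (NaN, flagged); HWE/LD tests
return NA. A population with all calls missing at a locus is absent from
frequency tables, never zero-filled. beta = 1 cells are skipped in
corrected statistics. W&C theta on identical samples is slightly
negative by construction (unbiasedness), so "no differentiation" checks
use tolerances, not exact zeros. NJ negative branches are clamped with
length transfer. Permutation p-values use the `(exceed + 1)/(n + 1)`
convention. All stochastic procedures are seeded; seeds derived from a
root seed stay below 2^31.

## Known limitations

* The EM's technical-failure rate is weakly identified from blanks
  alone; with very high beta and few blanks the split between failure
  and null homozygosity leans on the homozygote excess.
* Rarefied private-allele richness treats loci and alleles as
  independent (Kalinowski's approximation).
* The ABC posterior-probability CIs are asymptotic; with few retained
  simulations per scenario they can be optimistic, and the proportion
  fallback is wider but cruder.
* The stage-1/stage-2 scenario completions are reconstructions; the
  original diagram files are not reproduced in the text the sets were
  derived from.
* Migration is constant in time and unaffected by size-change events
  (only merges retire migration routes).
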