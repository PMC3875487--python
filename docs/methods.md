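# Methods

This package re-implements, as a tested pipeline, the statistical toolkit of a
Holarctic mtDNA control-region phylogeography study: haplotype cataloguing on a
harmonized 318-bp alignment frame, per-region diversity and neutrality
statistics, distance-based population structure, mismatch-distribution
expansion inference, median-joining networks, and coalescent ABC model choice
among four post-glacial colonization scenarios. This note records the models,
the numerical choices, and the places where the design was genuinely open.

## Alignment frame and haplotype identity

All statistics operate on equal-length sequences over `{A,C,G,T,-,N}` with
1-based, inclusive coordinates. Two conventions matter downstream:

* **N is a wildcard.** Degraded (historic) material yields partial reads, so
  two sequences are the same haplotype iff they agree at every mutually non-N
  position; when a wildcard sequence joins a haplotype, the least-degraded
  representative is kept. A consequence, documented in
  `distance.pairwise_differences`, is that the triangle inequality can fail
  after pairwise wildcard masking.
* **Gaps are excluded by default.** Indels are not counted as variable sites
  or distance steps unless `gap_mode="fifth_state"` is selected. This split
  matters because a published per-region table can be internally consistent
  only if one of the differences between two haplotypes is an indel that the
  segregating-site count excludes but the molecular distance includes; both
  modes are first-class and the report states which was used.

Canonical haplotype ids are assigned in first-seen order; the cross-study
catalogue attaches `(study, label)` synonyms to canonical ids by exact
(N-tolerant) sequence match on the harmonized frame and records every merge.

## Diversity and neutrality statistics

* Nucleotide diversity π is the mean per-site pairwise difference over all
  n(n−1)/2 individual pairs; its standard deviation uses the total
  (no-recombination) variance `b1·π/L + b2·π²` with the usual
  `b1=(n+1)/(3(n−1))`, `b2=2(n²+n+3)/(9n(n−1))`.
* Haplotype diversity is Nei's unbiased `h=(n/(n−1))(1−Σp²)` with Nei's
  variance estimator.
* Rarefied haplotype richness at standardized size g is the hypergeometric
  expectation `Σ_h [1 − C(n−n_h,g)/C(n,g)]`; private-haplotype richness
  multiplies the focal presence probability by absence probabilities in every
  other sample, independent within samples. Rarefaction is standardized
  within era (defaults g=6 contemporary, g=5 historic, the smallest analyzed
  sample in each era); raw private counts are relative to all samples.
* Tajima's D uses the standard a1…e2 coefficients and is defined as 0 for
  invariant samples. Fu's Fs is `ln(S′/(1−S′))` with
  `S′ = Pr(K ≥ k_obs | θ = k̄)` under the Ewens sampling distribution,
  computed from unsigned Stirling numbers of the first kind in log space
  (stable beyond n = 1000; rows are cached per n).
* p-values are **lower-tail** simulation probabilities
  `Pr(stat_sim ≤ stat_obs)` with the (b+1)/(B+1) estimator and ties counted:
  strongly negative statistics (expansion-like) give small p, large positive
  ones give p near 1. The neutral null is a constant-size coalescent
  conditioned on θ̂_π (not on S). A sample with k̄ = 0 yields D = 0, p = 1 and
  a missing Fs.

Report rounding follows the survey-table precision: two decimals for h, D,
Fs; three for π.

## The internal coalescent sampler

Simulation p-values, the neutrality-test calibration and the mismatch
bootstrap consume on the order of 10^5–10^6 tiny replicates, so they use a
purpose-built infinite-sites Kingman sampler (`coalescent.simulate_sample`)
with piecewise-constant population size. It tracks, per replicate, exactly
S, k̄, the number of distinct sequence classes (via a crown/classes merge
argument rather than sequence materialisation) and, on request, the full
mismatch histogram (O(n²) leaf-depth merging). Time units set
E[pair coalescence] = 1 and mutations fall at θ/2 per lineage per unit time,
so E[pairwise differences] = θ. The sampler is cross-checked in the test
suite against Watterson/Ewens expectations and against msprime's branch-mode
diversity on the same θ.

The multi-population scenario simulator is msprime (see below); the two are
never substituted for one another.

## Population structure

AMOVA follows the classical sums-of-squared-deviations decomposition with
nucleotide-difference counts entering directly as squared Euclidean
distances. Variance components use the unequal-size coefficients
(n_c for two levels; n1, n2, n3 for three levels); negative components are
retained so weakly negative Φ values survive to the report. Singleton-group
partitions (every population its own group) set the among-populations-within
component to zero. Permutation schemes: individuals among populations
(Φ_ST), individuals among populations within groups (Φ_SC), whole
populations among groups (Φ_CT); p = (b+1)/(B+1), ties as exceedances. The
implementation is verified against an independent individual-level
brute-force computation on random instances.

SAMOVA maximizes Φ_CT over assignments of populations into K groups by
simulated annealing: Voronoi initialization around K random population
centroids (geography enters only here — no hard contiguity constraint),
single-population reassignment moves keeping groups nonempty, geometric
cooling (T0 = 0.05, factor 0.999), best of `n_init` restarts, first-found
best on ties. Exhaustive partition search confirms global optimality on
small instances in the tests.

Isolation by distance is a Mantel test of Rousset-linearized Φ_ST/(1−Φ_ST)
against ln great-circle (haversine) distance between user-supplied
population centroids, with populations under `min_n` (default 10) excluded
and Φ_ST = 1 pairs dropped with a warning (their transform is infinite).
The permutation p-value permutes population labels of the genetic matrix.

## Mismatch distribution and sudden expansion

The sudden-expansion expectation is

    F_i(τ,θ0,θ1) = F̂_i(θ1) + e^{−τ(θ1+1)/θ1} Σ_{j≤i} (τ^j/j!)[F̂_{i−j}(θ0) − F̂_{i−j}(θ1)]

with F̂ the equilibrium geometric form; the last difference class absorbs the
renormalized tail. The formula was verified against the coalescent sampler
(piecewise history `λ = θ0/θ1` before `t = τ/θ1`) to within Monte Carlo
error. Estimation minimizes the SSD between observed relative frequencies
(classes 0..max_obs+5, tail pooled) and the model over τ ∈ [0,30],
θ0 ∈ [0, θ̂_π], θ1 ∈ [θ̂_π, 10⁴], seeded on a coarse grid and polished with
penalized Nelder–Mead. The SSD and raggedness p-values are full parametric
bootstraps: each replicate is a coalescent sample of size n simulated under
the fitted history and **refitted**.

Known limitation: θ1 is weakly identified from single-locus mismatch data —
the SSD profile in θ1 is typically flat or monotone beyond a few multiples
of θ̂_π, so estimates often sit at the search boundary (the behaviour that
leads the field's standard software to print its θ1 cap). τ and the overall
fit quality (SSD, raggedness) are well behaved; θ1 point estimates should
not be interpreted quantitatively.

## Median-joining networks

The network construction iterates: (1) ε-relaxed minimum spanning network,
characterized via single-linkage cophenetic distances (an edge is kept iff
d(u,v) ≤ sl(u,v)+ε), which makes the network the union of all MSTs and
guarantees it contains an MST of the observed haplotypes; (2) quasi-median
(majority-consensus) vectors proposed from triples at least two of whose
links are in the network, accepted when their star connection cost is within
ε of the round's minimum (fully discordant columns branch, capped at 27
variants per triple); (3) pruning of median vectors with degree ≤ 2.
ε defaults to 0; ties break lexicographically for determinism. Gap and
wildcard handling follow the alignment conventions.

## Colonization scenarios and ABC

Five regional pools are modelled (northwest North America; central Arctic;
Manitoba/Ontario; historic Quebec/Labrador; eastern Eurasia), with four
competing histories: simultaneous radiation at the last glacial maximum;
Beringian incursion followed by simultaneous Holocene radiation in North
America; incursion followed by west-to-east stepping-stone colonization; and
two incursions with a stepping-stone tail. Histories are encoded as ordered
backward-in-time lineage merges and simulated with msprime (haploid,
single non-recombining 318-bp locus, HKY mutations with an exactly
row-normalized transition matrix — the stock constructor can drift a few ulp
above 1 and be rejected). Population sizes are parameterized on the census
(equal-sex) scale and simulated at Ne/2 for the maternal locus; generation
time is 4 years. An optional bottleneck reduces the Manitoba/Ontario pool's
Ne by 75% from 25 generations ago to the present.

Default priors (all overridable): Ne log-uniform [10^2.5, 10^3.2] per pool,
μ log-uniform [10^−5.5, 10^−5] per site per generation, κ uniform [2, 20],
LGM split time uniform [4500, 6500] generations, and the three ordered
Holocene split times drawn from disjoint windows [2400, 3000], [1450, 2050],
[500, 1100]. These ranges are a deliberate design choice with two goals:
(i) θ = Ne·μ·L stays in the low range a 318-bp carnivore control-region
survey actually shows (mean pairwise differences of a few substitutions),
and (ii) the gap between successive colonization steps spans several mtDNA
coalescent units of the prior-typical Ne, so lineage sorting completes
between steps and the four histories are statistically separable — with
wide, overlapping priors the stepping-stone and simultaneous-radiation
histories become observationally equivalent for a large share of draws and
no model-choice machinery can tell them apart.

Summary statistics (fixed, versioned layout shared bit-for-bit between
simulated and observed data): per pool the haplotype count, segregating
sites, mean pairwise differences and haplotype diversity; per pool pair the
two-level Φ_ST and mean between-pool differences. Model choice standardizes
the reference table by median absolute deviation (zero-spread columns
dropped with a warning), projects onto the linear discriminant axes
separating the scenarios, retains the closest `accept_fraction` (default 1%)
by Euclidean distance, and estimates posterior probabilities by
Epanechnikov-weighted multinomial logistic regression at the observed point;
plain rejection proportions are reported alongside and serve as the fallback
when the accepted set is single-class or the regression degenerates. Type
I/II errors come from pseudo-observed datasets classified against a shared
reference table.

Problem sizes: the engine-level recovery test runs at 10⁴ simulations per
scenario with 100 pseudo-observed datasets and reduced per-pool sample sizes
(30/20/20/10/15); the study-scale pooled sizes (497/150/85/13/60) are used
by the pipeline and CLI. Sample sizes affect cost, not the logic under test.

## Synthetic data

Deterministic fixtures encode configurations whose statistics are forced by
arithmetic (a 61+1 vs 108 two-region pair with two substitutions plus one
indel; a 5+1 six-individual sample; an eight-step haplotype pair; a star of
singletons) — their expected values appear frozen in the tests. The
study-shaped generator replays the survey design: a stepping-stone
simulation extended with Scandinavian and historic-Californian demes,
subsampled to the survey's 21 (region, era) samples totalling 983
individuals. Its fixed parameters (all pools Ne 800, ancestral 500,
μ = 3.5·10⁻⁶, κ = 10, splits 5500/2700/1750/800 generations) were chosen
once so the realized shape lands near the survey's (a few tens of
haplotypes, ~40 variable sites, dominant haplotype frequency 0.2–0.5);
realized counts are reported, not enforced — forcing exact counts would
require unbounded rejection sampling. What passing on this generator shows
is that the pipeline's machinery behaves correctly on data of the survey's
shape; it does not validate the biological conclusions on the real
(unpublished) sequences, which differ in base composition, site-rate
heterogeneity and the genealogy actually realized.

## Pipeline

`run_all` chains the stages and writes CSV/JSON/GraphML artifacts plus a
manifest with seeds, input checksums and stage wall times; every stage is a
pure function of (inputs, config, seeds), so reruns are bitwise identical
apart from the manifest's timings. Samples of size 1 are excluded from
per-sample statistics and structure analyses but kept in the pooled
mismatch/network stage. Historic and contemporary samples are separate
entries by default; `merge_eras` pools them by region.

## Degenerate inputs and tie-breaks (summary)

* n < 2: diversity and neutrality statistics are signalled as undefined.
* S = 0: D = 0 with p = 1; monomorphic samples report Fs as missing.
* Both samples monomorphic and identical: Φ_ST defined as 0, p = 1.
* Mantel: Φ_ST = 1 pairs excluded with a warning; nonpositive geographic
  distance between distinct sites raises.
* Annealing and MSN construction break ties deterministically
  (first-found / lexicographic).
* ABC: scenarios absent from the accepted set get probability 0 with a
  warning; degenerate regressions fall back to rejection proportions,
  flagged in the result object.
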