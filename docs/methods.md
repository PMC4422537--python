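# Methods

`germcore` implements the standard genebank workflow for building and
validating a core collection and a marker-diversity mini core from a
germplasm panel, together with the diversity statistics used to judge
them. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data can and cannot show.

## Data model

A panel is an ordered set of accessions (entries) with three aligned
views: passport data (country, region stratum), quantitative trait
descriptors, and dominant-scored SSR band profiles. Each band is treated
as one allele of its locus; for a predominantly selfing crop such as
mungbean, accessions are modelled as homozygous, carrying one band per
locus. Missing marker data is locus-level: a cell that cannot be scored
removes the accession from that locus only — it is never treated as
"band absent", because dominant scoring cannot distinguish absence from
amplification failure. Missing trait values are excluded pairwise and
never imputed.

## Diversity statistics

On allele (band) frequencies `p` at a locus:

- Shannon information index `I = -Σ p ln p` (natural logs throughout,
  the PopGene convention);
- Nei expected heterozygosity (gene diversity) `H_T = 1 - Σ p²`;
- polymorphism information content
  `PIC = 1 - Σ p² - Σ_{i<j} 2 p_i² p_j²`.

Allele counts are bands with nonzero frequency; a locus genotype is the
exact band pattern; the multilocus genotype count considers accessions
scored at every locus.

The trait-side Shannon–Weaver index bins each descriptor into `k`
equal-width classes and normalizes: `H' = (-Σ p ln p) / ln k`. Two
choices here are assumptions, not field facts: normalization by `ln k`
(without it, indices for descriptors with 10–15 classes could not share
the narrow range typical of published germplasm tables), and equal-width
bins over the *reference* (whole-collection) range, so that whole, core
and mini core are always compared on one shared class system. Default
class counts per descriptor: V040 11, V050 10, V120 15, V130 14,
V400 11, V510 11, V700 13, V770 14.

## Distances and clustering

- Standardized Euclidean (traits): each descriptor z-scored (sample SD,
  n−1) over the analyzed set; pairwise squared distances over shared
  non-missing descriptors rescaled by `K/K_obs` to stay comparable
  across pairs with unequal coverage.
- Jaccard (bands): `d = 1 - a/(a+b+c)` over band columns, loci missing
  in either accession deleted pairwise.
- Modified Rogers (bands): with per-locus allele indicator vectors `x`,
  `MR = sqrt( Σ_l Σ_b (x_i - x_j)² / (2m) )` over the `m` co-scored
  loci; fully distinct homozygotes are at distance 1.
- Group-level dissimilarity (e.g. by origin or trait class): the MR
  formula applied to the groups' pooled allele-frequency vectors. The
  between-group measure is a documented package choice; trait-class
  groupings are config-driven bin edges.

UPGMA (average linkage) is implemented directly so ties are broken
deterministically by the lexicographically smallest pair of cluster
labels. Merge heights are the average inter-cluster distances (not
halved), so the cophenetic distance of two leaves equals the merge
height of their lowest common ancestor; Newick export gives each child a
branch of `height(parent) − height(child)`, making leaf-to-leaf path
lengths twice the cophenetic value. The implementation is verified
against an independent brute-force reference on all small instances and
against scipy's average linkage.

## Core collection

`build_core` stratifies by passport region, clusters each stratum's
standardized trait vectors with UPGMA, cuts into flat clusters (fixed
height, or a target count defaulting to `max(2, stratum_size/50)`), and
draws `round_half_up(fraction × size)` accessions per cluster, minimum
one per nonempty cluster; singleton strata enter with probability
`fraction`. Everything is reproducible from one seed. An `exact_size`
option trims/pads uniformly at random to the global target.

A practical caveat established by simulation: with equal-width UPGMA
clusters, average linkage chains — most accessions fall into one large
cluster per stratum with outliers split off as small clusters — so the
stratification captures only a modest share of per-trait variance
(≈10% at the default cluster count, ≈60% at very fine cuts), and the
min-1 rule oversamples outlier singletons when cuts are fine. The
representativeness of a 20% core is therefore dominated by ordinary
sampling noise: at a panel size of 2,000 (core ≈ 410) the relative
standard error of a trait mean is CV × 4.4%, i.e. 1.1–1.3% for
high-CV descriptors such as plant height (CV ≈ 0.30) — and the maximum
relative mean difference across eight descriptors and several seeds
typically lands between 1.5% and 4%. Sub-1% agreement for every
descriptor should only be expected for substantially larger panels
(at 8,000 → 1,500 the standard errors halve) or low-CV trait sets;
the package reports the measured value rather than assuming it.

## Mini core

The optimizer maximizes
`w_mr · meanMR(S) + w_sh · I_pooled(S)/ln(B)` over subsets `S` of fixed
size (`round_half_up(target_fraction × n)`), where `meanMR` is the mean
pairwise Modified Rogers distance within the subset, `I_pooled` is the
Shannon information of band frequencies pooled over all loci jointly,
and `B` is the panel's total band count, so both terms live in [0, 1].
Defaults: `w_mr = 0.7`, `w_sh = 0.3`, fraction 0.2.

The search is a deliberately simple stochastic subset search: several
independent replicas start from random subsets; proposals swap one
selected accession for one unselected (uniformly); a move is accepted
when the objective does not decrease; periodically the worst replica
restarts from the global best. This is *not* a port of any published
optimizer's internals — the contract is the objective definition plus
"finds near-optimal subsets", verified by exhaustive enumeration on
small panels (n = 12, subset 3) and by dominance over random subsets.
The best-so-far objective is non-decreasing in the step budget.

Two baseline strategies used for validation: proportional random
sampling from marker-UPGMA clusters, and from geographic regions only.
On structured synthetic panels the optimizer retains at least as many
alleles as either baseline at equal size.

## Validation statistics

- Equality test: the Brown–Mood median test (pool, split at the pooled
  median, plain χ² on the 2×2 table, 1 df, no continuity correction).
  The published tables this mirrors label the test only as
  "equality (χ²)"; the median test is the interpretive choice and is
  the largest such assumption in the package.
- Homogeneity test: both samples binned into shared equal-width classes
  (edges from the reference collection); classes with expected count
  < 1 pooled into neighbors; χ² on the 2×k′ table, k′−1 df.
- Q-Q + KL: empirical quantiles on the interior 0.5% grid (199 points,
  linear interpolation); the two quantile vectors discretized into 20
  shared equal-width bins; plugin `KL(p‖q) = Σ p ln(p/q)` after
  symmetric add-one smoothing of counts (the estimator is undefined on
  empty q-bins; smoothing is the package's rule). KL is invariant under
  a common affine transform and zero exactly when the binned
  distributions coincide.
- Mantel test: Pearson r of the upper triangles; one-sided permutation
  p `(1 + #{r_perm ≥ r_obs})/(1 + n_perm)` under simultaneous
  row/column permutation (never exactly zero); two-sided option
  exposed.
- Correlation comparison: Fisher z per trait pair,
  `z = (z_a − z_b)/sqrt(1/(n_a−3) + 1/(n_b−3))`, two-sided normal p.

Both χ² tests hold their nominal 5% size within ±2 points under
same-distribution simulation (n = 500, 1000 replicates).

## Synthetic panels

The generator emulates a multi-region selfing-crop genebank panel:

- Trait defaults: per-descriptor (mean, variance) matching a large
  cultivated mungbean collection (e.g. V040 4.5/0.24 cm, V130
  40.5/149.75 cm, V770 37.5/87.24 g); normals truncated at zero
  (all descriptors are nonnegative quantities). Traits are independent
  within subpopulations by default; a correlation matrix can be
  supplied but no default is imposed because collection-level trait
  correlation structure is not published.
- Markers: 20 loci with 3–13 alleles each (uniform draw); per locus a
  shared base frequency vector from a flat Dirichlet.
- Structure: two latent subpopulations by default. Divergence follows
  the Balding–Nichols drift model: subpopulation frequencies drawn from
  `Dirichlet(p0 (1−d)/d)`, so `Var(p_s) = d·p0(1−p0)` and `d` acts as
  an F_ST. A mixture formulation (`(1−d)·p0 + d·Dirichlet`) was tried
  first and rejected: at d = 0.3 it separates subpopulations by only
  ~d² in squared frequency difference, far below what 20 loci can
  resolve, and top-split recovery stayed at chance. With the drift
  model, UPGMA on MR distances recovers ≥ 99% of assignments at
  d = 0.3 (n = 400). Default d = 0.4.
- Regions: sampled independently of subpopulation (genebank structure
  is typically not fully aligned with geography) from a plausible
  7-region world-collection mix centred on South/Southeast Asia; this
  mix is a package choice, as no region distribution is published.

What passing tests on synthetic panels do **not** show about real data:
real collections have correlated traits, region-confounded structure,
null alleles and multi-band profiles, and non-normal trait
distributions; the generator covers none of these by default, so the
simulation results certify the algorithms, not field performance.

## Numerical conventions

Sample variances use n−1. Per-cluster take counts use round-half-up.
Aggregates of the shipped reference tables are rounded half-up to the
printed decimals of those tables. Frequency vectors must sum to 1
within 1e-9. Permutation p-values live on the `k/(1+n_perm)` grid.
Stage seeds derive from `sha256(global_seed:stage) mod 2^31`.

## Problem sizes used in the shipped checks

Oracle equivalence runs exhaustively at n ≤ 7 (UPGMA) and n = 12
(subset search); calibration uses 1000 replicates of n = 500 samples;
representativeness uses five 2,000-accession panels; structure recovery
five 400-accession panels. These sizes give stable verdicts for each
property while keeping the default test run fast.
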