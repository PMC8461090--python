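# Methods

This note documents the models, parameters and numerical choices behind
the package, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the framework leaves room.

## 1. Data model and preprocessing

The central object is a samples × taxa table of nonnegative integer read
counts, joined to a rooted branch-length-bearing phylogeny over the taxa
and a per-sample metadata table (membrane type, surface character, flux,
sampling day, compartment, nucleic-acid type). Validation is strict:
integer counts, unique identifiers, exact string match between table taxa
and tree tips, and metadata levels restricted to the design's factor
enumerations.

**Rarefaction** subsamples every sample to an even depth (default 4,386
reads) *without replacement* — a multivariate-hypergeometric draw from
the sample's reads, matching physical subsampling of a sequencing
library. Samples below the target depth are dropped with a logged
warning, not an error, because a study typically retains the remaining
samples. Rarefaction is seeded; the expected post-rarefaction count of a
taxon equals depth × its pre-rarefaction proportion (tested against the
hypergeometric marginal over 1,000 seeded draws).

## 2. Diversity, ordination, inference

Alpha indices are the standard forms: observed richness; Shannon entropy
in nats (−Σ p ln p); Gini-Simpson (1 − Σ p²); and bias-corrected Chao1,
S_obs + F₁(F₁−1)/(2(F₂+1)), whose (F₂+1) denominator keeps the estimator
defined with no doubletons.

Beta diversity is Bray-Curtis on counts (scipy) and unweighted UniFrac on
presence/absence (scikit-bio); both live in [0, 1]. Ordination is
classical PCoA (eigendecomposition of the double-centred −½d² matrix;
axes with non-positive eigenvalues are dropped with a warning) and
nonmetric MDS minimising Kruskal stress-1 via SMACOF with isotonic
regression, best of 20 restarts with the first start taken from the PCoA
configuration. On distances exactly realizable in k dimensions NMDS
reaches stress < 10⁻⁴.

PERMANOVA is the one-way Anderson partition: with n samples in g groups,
SS_total = Σ_{i<j} d²_ij / n, SS_within summed per group, and
pseudo-F = (SS_between/(g−1))/(SS_within/(n−g)). The p-value counts
permuted statistics at least as large as the observed one, with the
observed included in numerator and denominator, so p ≥ 1/(n_perm+1) and
can never be zero. The implementation is seeded (numpy Generator) and is
cross-checked against scikit-bio's ADONIS statistic in the test suite.
Only one-way designs are supported; the study's factors are tested one at
a time. Note one consequence verified in the calibration runs: testing a
factor that is deliberately *balanced* across a strong structuring factor
(e.g. membrane type, balanced over sampling days, on the pooled distance
matrix) is extremely conservative, because the observed blocked labelling
is less dispersed than almost any permutation. Calibration quantities are
therefore measured within single days, where labels are exchangeable;
there the empirical type-I error at α = 0.05 is 4–5%.

## 3. The assembly-process framework

### Binning

Taxa are partitioned into phylogenetic bins by a greedy clade cut:
walking root-ward, the tree is cut into maximal clades whose within-clade
cophenetic diameter does not exceed `ds_cut`; clades below `bin_size_min`
(default 24; 6 in the small-simulation tests) are merged with the clade
at smallest mean inter-clade cophenetic distance, ties to the smaller bin
id. The classic fixed cut of 0.2 substitutions/site presumes a real 16S
tree's absolute branch-length scale. Synthetic trees here are
height-normalised, so by default `ds_cut` is resolved adaptively as the
0.65 quantile of the tree's tip-tip distance distribution, which yields a
few deep clades per tree; any fixed numeric value is honoured when the
distance units are meaningful. Bin membership is stored in tree-tip
order, making every downstream null draw invariant to the count table's
column order.

### Null models

**βNRI.** For one bin and one sample pair, βMPD is the abundance-weighted
mean pairwise phylogenetic distance between the two communities, weights
being the product of within-bin relative abundances (an unweighted,
presence-based variant is available behind a flag). The null shuffles
taxon identities among the bin's tips — implemented as a column
permutation of the weight matrix, the same permutation applied to both
samples — holding abundances fixed; `n_null` defaults to 1,000 (200 in
simulation tests). Shuffling is confined to the bin because bins are the
framework's unit of conserved niches; shuffling across bins would destroy
the signal under test. A null with zero spread (a star-like subtree,
where every shuffle preserves all distances) is flagged degenerate and
scored βNRI = 0, so classification falls through to the taxonomic null —
no phylogenetic signal is detectable there, so selection cannot be
claimed.

**RC.** Null bin communities preserve each sample's observed bin richness
and bin read total; taxa are drawn without replacement with probability
proportional to occupancy across samples (Gumbel top-k), and reads are
filled multinomially proportional to mean relative abundance. RC =
2·[(#null < obs + ½·#null = obs)/n_null − ½]. Null draws are generated
per sample and shared across that sample's pairs, which keeps the
ensemble consistent and the cost linear in samples rather than pairs.
Equality is resolved at 10⁻¹² tolerance. One structural property worth
knowing: a pair whose observed dissimilarity ties the Bray-Curtis ceiling
(fully disjoint supports) can draw nulls that are also disjoint, so RC
approaches +1 up to the tie share rather than exactly.

### Classification and aggregation

Classification is a pure function of (βNRI, RC): βNRI beyond ±1.96 gives
heterogeneous (+) or homogeneous (−) selection; otherwise RC beyond
±0.95 gives dispersal limitation (+) or homogenizing dispersal (−);
otherwise drift. Boundary equality falls to the stochastic side. Note the
sign convention: positive βNRI = more dissimilar than null =
heterogeneous selection; this is the standard usage and matches the
interpretation of homogeneous selection as the outcome of identical
environmental conditions.

Pair-bins where the bin is absent from either sample carry no measurable
turnover signal; they are dropped and the remaining bins' weights (mean
of the bin's relative abundance in the two samples) renormalised. Group
fractions are unweighted means over within-group pairs only;
between-group pairs are computed only on request, since the appropriate
pairing scheme is design-dependent. DNA and cDNA datasets are always
processed as separate runs.

## 4. The synthetic-data generator

The generator's role is to produce communities whose true assembly regime
is known, under conditions matching the study design: ~480 taxa, samples
rarefied to 4,386 reads, groups of ten biofilm samples per sampling day,
MLSS as the regional pool.

**Trees** are pure-birth (Yule) ultrametric trees rescaled to height 1,
so cophenetic distances share one scale across simulations. **Niche
traits** evolve by Brownian motion along the tree (rate `trait_sigma`,
default 1 per unit height). Because the framework *assumes*
phylogenetically conserved niches, the selection regimes require the
realized trait field to carry a minimum phylogenetic signal — Pearson
correlation ≥ 0.2 between cophenetic distance and squared trait
difference, redrawing the Brownian field (up to 30 draws) otherwise.
About a quarter of unconditioned draws fail this floor: a single BM
realization can leave the deep clades unseparated in trait space, which
would contradict the conserved-niche assumption the simulated regime is
supposed to embody.

**Regional pool** abundances are log-normal with σ = 0.3. This is more
even than a typical amplicon rank-abundance curve (σ ≈ 1), and the choice
is deliberate: at desk scale (hundreds of taxa, 10³ reads) a σ = 1 pool
concentrates within-bin weight on one or two taxa whose placement is
random with respect to phylogeny, drowning the within-bin
abundance-clustering signal that βNRI measures. The cost is that
simulated communities are richer and more even than real ones (observed
richness can reach the full taxon count at depth 4,386; Shannon ≈ 4.5–6).

**Selection regimes** multiply the pool by a Gaussian fitness filter
exp(−s·(trait − optimum)²) and draw reads multinomially.

- *Homogeneous selection* (HoS, default s = 8): one shared optimum,
  anchored at the niche of the most distinct mid-sized clade (the
  "guild", 10–30% of taxa) and placed one guild-trait-SD outward of the
  guild mean. Two facts motivate the anchoring. First, an environment
  generically resembles the niche of some coherent guild (the
  early-coloniser taxa of an MBR biofilm, for instance), not the abstract
  community-wide trait centroid. Second, a centroid optimum is the one
  point where the filter has zero gradient exactly where community weight
  concentrates — with the flat filter top inside the dominant bin, the
  within-bin clustering signal vanishes and homogeneous selection becomes
  undetectable by construction; the guild-edge optimum keeps a fitness
  gradient across the guild's own clade.
- *Heterogeneous selection* (HeS, default s = 1.5, n_env = 2): divergent
  optima spanning ±2 SD of the tip-trait distribution, samples assigned
  round-robin. The broader niche is deliberate: overdispersion (positive
  βNRI) is power-limited because ultrametric distances are bounded above
  by twice the tree height, and very narrow filters concentrate each
  community on a handful of taxa, inflating the shuffle-null's spread.
  For the same reason the between-environment βNRI rises with s only over
  the weak-to-moderate range and saturates (then declines) beyond it —
  the monotonicity test covers the range where the relationship holds.

**Dispersal/drift regimes** run Wright-Fisher drift of a local community
of J = 10·depth individuals for 50 generations, founded from the pool,
with per-generation immigration m from the pool.

- *Drift* (DR, m = 0.3): local fluctuation around the pool; communities
  resemble independent random assemblies, which is precisely the RC
  null's own generative process, so RC sits mid-band.
- *Dispersal limitation* (DL, m = 0): persistent communities drifting
  apart — shared membership, diverging dominance — which exceeds the null
  ensemble's spread (RC → +1).
- *Homogenizing dispersal* (HD) is a mass-effects landscape: a connected
  core of patches (80% of samples) shares one realized community state,
  founded through a 0.4·depth-colonist bottleneck so the state is patchy
  relative to the pool, while the remaining patches drift in isolation.
  The isolated minority matters: the RC null is built from the focal
  sample set's own occupancy and mean abundance, so a *perfectly*
  homogeneous sample set is statistically indistinguishable from random
  assembly (RC ≈ 0 — correctly reported as drift). Mass effects are only
  detectable against regional heterogeneity, which is also the
  ecologically standard picture of a dispersal-dominated landscape.

**The study-shaped generator** lays these regimes on the experimental
design: 5 membrane types × {flux, no-flux} × days {1, 10, 20, 30} biofilm
samples plus MLSS per day, for DNA and cDNA (44 samples each). Membrane
type and flux never enter the sampling probabilities — the design's null
factors. Sampling day drives both the optimum (succession along the niche
axis away from the early-coloniser guild) and the regime: days 1/10
strong selection (truth HoS), day 20 weaker shifted selection with weak
drift (HoS+DR), day 30 pure pool plus strong independent drift (DR+DL).
The day-30 base is the *unfiltered* pool because any residual filter
leaves enough phylogenetic clustering to read as selection. cDNA sees a
slightly displaced optimum (0.1 SD), emulating an activity-weighted view
of the same community. Read totals are log-normal (median ≈ 8,000)
clipped to [1,392, 18,070], so a few samples per study fall below the
4,386-read rarefaction depth and exercise the dropping path.

**What the generator does not emulate:** sequencing error and chimeras
(simulation starts at taxon abundances), taxonomy, realistic
rank-abundance skew (see pool σ above), phylogenetic uncertainty (the
true tree is used for inference), biological replicates with shared
history, or any coupling between membrane chemistry and community
composition. Passing tests therefore demonstrate that the inference
machinery recovers known regimes under favourable, assumption-true
conditions — not that it would resolve them in noisier real data.

## 5. Problem sizes and runtime

The validation suite runs the five-regime recovery at 200 taxa, 10
samples, 1,000 reads/sample, 200 null randomizations, minimum bin size 6,
20 replicates per regime (modal-process recovery 85–100%), and the
study-trend check at 480 taxa and depth 4,386 over 10 study replicates ×
2 datasets. These sizes keep the full suite around a minute on one CPU
while leaving the recovery margins wide; `n_null` = 1,000 (the reporting
default) changes βNRI by less than the null-mean standard error relative
to 200 (tested).

## 6. Known limitations

- Group-level fractions average within-group pairs; alternative pairing
  schemes (all pairs involving a day, between-day pairs) are possible and
  exposed, but not the default.
- Selection detection depends on within-bin trait variance; with very
  fine bins (many taxa per bin ≪ trait correlation scale) homogeneous
  selection degrades to homogenizing-dispersal or drift calls. The
  adaptive bin cut mitigates but cannot remove this scale dependence.
- The HeS/HoS thresholds (±1.96) and RC thresholds (±0.95) are the
  conventional ones and are not calibrated per dataset.
- PERMANOVA is one-way; blocked or stratified permutation is out of
  scope, with the conservatism consequence described in §2.
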