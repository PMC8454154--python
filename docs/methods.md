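# Methods

This note records the models implemented in `trophoweb`, the assumptions
behind them, the defaults that matter, and what the synthetic-data tests do
and do not demonstrate.

## Preprocessing

The global pipeline applies two filters before any analysis, in this order:
OTUs with fewer than 100 reads summed over *all* samples (soils and animals
alike) are removed; then every sample is subsampled **without replacement**
(multivariate hypergeometric, seeded) to a common depth of 13,551 reads,
discarding samples below that depth. "Presence" everywhere downstream means
at least one read in the post-rarefaction table. Rarefaction without
replacement was chosen over with-replacement resampling because it is the
convention of the standard amplicon toolchains and never inflates a count
above its observed value.

## Additive diversity partitioning

For a nested hierarchy (individual samples within groups within …), define
the mean Shannon diversity of the pooled communities at each level, with
uniform unit weights. α is the mean per-sample diversity, each β the
difference between consecutive levels' means, and γ the diversity of the
fully pooled community. The components telescope, so α + Σβ = γ holds to
machine precision for any input — the suite asserts 1e−9.

Significance is a label-permutation test: the component at level ℓ is
recomputed under random reassignment of level-(ℓ−1) units to their level-ℓ
parents (999 permutations by default, p = (1 + #{perm ≥ obs})/(1 + n)).
The top component (γ minus the coarsest mean) has a single parent, so its
null instead reshuffles the children of the coarsest grouping, which
perturbs that mean while γ stays fixed. α itself is the permutation-
invariant baseline and carries no p-value. Calibration was checked by
simulation: under a structureless null the rejection rate at 0.05 is
0.049 (1000 replicates).

The Shannon log base defaults to e and is configurable; none of the
downstream conclusions depend on the base.

## Distances, ordination, PERMANOVA

UniFrac distances (unweighted: unshared branch length over total;
weighted: branch-length-weighted abundance differences, normalized variant
by default so values lie in [0, 1]) are computed through scikit-bio and
verified in the suite against independent branch-walk summations on small
trees. PCoA is classical metric scaling: double-center −½D², take the
eigendecomposition, keep positive eigenpairs; negative eigenvalues are
reported, excluded from the explained-variance denominator, and never
silently corrected.

PERMANOVA uses Anderson's pseudo-F on squared distances with seeded label
permutations, or exhaustive enumeration of all distinct label arrangements
when requested (the suite checks the enumerated p against an independent
re-derivation). Pairwise PERMANOVA adjusts p-values by Benjamini–Hochberg
by default (configurable to Bonferroni or none) and assigns compact letters
by the insertion method: groups sharing a letter are not significantly
different at the chosen α.

## Enterotyping

Each host group's samples (never pooled across groups) are clustered on
genus-level relative-abundance profiles. OTUs without a resolved genus are
pooled under `unclassified_<deepest resolved rank>` so dark-matter reads
are retained. The distance is the Jensen–Shannon distance (square root of
the base-2 divergence, bounded by 1); clustering is PAM (greedy BUILD +
steepest-descent SWAP, deterministic with lowest-index tie-breaks). The
number of clusters maximizes the Calinski–Harabasz index computed directly
from the distance matrix via the pairwise-distance identity for sums of
squares, over k = 2…10; mean silhouette width is reported alongside.
Cluster labels follow `<group initial>_<driver genus>`, the driver being
the genus with the highest mean relative abundance in the cluster.

## Sloan neutral community model

Inputs are per-OTU mean relative abundance p and occurrence frequency f
from a rarefied table (equal depths are enforced; N is the rarefaction
depth, so Nm = depth · m). Under neutral drift with migration m, the local
relative abundance of an OTU follows Beta(Nm·p, Nm·(1−p)).

Two prediction curves are implemented:

* `predict_frequency` — the continuous threshold form
  f̂ = 1 − BetaCDF(d; Nm·p, Nm·(1−p)) with detection limit d (default one
  read, d = 1/N), verified against numerical quadrature;
* `detect_probability` — the exact discrete form
  f̂ = 1 − B(a, b+N)/B(a, b), the beta-binomial zero-class complement,
  i.e. the probability that at least one of N reads hits the OTU.

`fit_sloan` fits m by bounded 1-D least squares and **defaults to the
discrete form**. The reason is empirical and reproducible with the
package's own generator: under exact Dirichlet-multinomial data
(Nm ∈ {200, 1000, 5000}, N = 10,000, 500 samples) the continuous threshold
fit overestimates Nm by 17–37 % because the hard threshold at d misstates
the smooth one-read detection curve, whereas the discrete form recovers Nm
within ~1 %. The continuous fit remains available via `model="beta-cdf"`
for comparability with the classical implementation.

OTUs are classified against a Wilson 95 % score band (stable at extreme
frequencies) around the prediction evaluated at the realized number of
samples; the fit is compared with the zero-parameter binomial null
f_bin = 1 − (1−p)^N via Gaussian least-squares AIC, n·ln(SSE/n) + 2k with
k = 1 (neutral) vs k = 0 (binomial), with an ε floor guarding the
perfect-fit SSE = 0 edge case. Note that because pool abundances are
estimated from the same samples, the fraction of OTUs inside the 95 % band
is ≈ 0.90 at Nm = 1000 rather than the nominal 0.95, and lower at small
Nm where the latent variance inflates the abundance-estimation noise; this
is a property of the method, not a defect of the fit.

Each group is fitted on its own samples only; soil is fitted separately.

## Trophic levels

δ¹⁵N follows the standard per-mil definition against atmospheric N₂;
adjusted values subtract the site's litter δ¹⁵N so positions are comparable
across sites. Levels are integer bins of width 3.4 ‰ —
TL = 1 + ⌊(δ − δ_min)/3.4⌋ — anchored at the observed minimum, with a
boundary tolerance of 5 % of the bin width absorbed into the top bin, so a
range that overshoots an integral number of bins by a sliver (e.g.
−0.25…16.79 ‰, a 0.04 ‰ overshoot past five bins) does not open a new
level. Assignments are translation-invariant and monotone in δ.
Regressions use the continuous adjusted δ¹⁵N as the predictor (ordinary
least squares, two-sided slope test); integer levels serve only for
grouped summaries.

## Unique taxa

An OTU is unique to a faunal group when it is detected in at least one
sample of the group and in **no** soil sample at any site — a single soil
read disqualifies it everywhere, and the suite asserts this absolutely.
The dominance filter keeps OTUs whose maximum per-sample relative
abundance and detection prevalence both *strictly* exceed their thresholds
(default 0.3 % and 70 %); the two conditions commute. Shared-OTU structure
is reported as the full Venn partition for up to six groups. The trophic
trend statistic is the Spearman correlation of per-sample unique counts
against trophic level.

## Dark-matter networks

Counts are aggregated to a rank (class, family or genus); a node is
unknown when its rank label is one of the unknown/unassigned/ambiguous/
uncultured/NA markers (case-insensitive). Unknown labels are kept distinct
per OTU rather than pooled into one mega-node. The association estimator
is CLR (pseudocount 0.5 on zeros) followed by Pearson correlation with an
absolute threshold of 0.35, behind a pluggable interface — a sparse
inverse-covariance estimator can be swapped in without touching the
downstream comparison, which is estimator-agnostic. Taxa below 20 %
prevalence are dropped before estimation; under independent taxa the edge
density stays below 2 % at the default threshold.

Centralities are computed on the binarized graph: degree, shortest-path
betweenness (fraction of all pairs' shortest paths), and harmonic
closeness normalized by n−1 — harmonic because node deletion disconnects
graphs, where classical closeness is undefined. Hub scores are the
principal adjacency eigenvector by power iteration (tolerance 1e−10, max
1000 iterations), max-normalized; on an undirected graph HITS hub and
authority scores coincide with this vector.

The removal experiment compares Original, Without-Unknown (all flagged
nodes deleted), and B = 100 bootstrap networks each deleting the same
number of uniformly random nodes. Two comparisons are reported:

* pooled two-sided Wilcoxon rank-sum tests between node-value
  distributions per metric, with metrics size-normalized (degree by n−1)
  so networks of different sizes are comparable — this mirrors the
  conventional reporting but is conservative under the null because pooled
  bootstrap values are dependent;
* a Monte-Carlo exceedance p: the rank of the Without-Unknown network's
  mean centrality among the B bootstrap means. When the flags are
  exchangeable with random nodes this p is uniform by construction
  (verified: rejection 0.047 at nominal 0.05 over 1000 null replicates),
  so it is the statistic used for calibration claims.

Node values pooled across bootstrap replicates are unpaired; a paired test
is impossible because deleted nodes have no counterpart.

## The synthetic-data generator

`simulate_foodweb_dataset` emulates the study design: six sites, farmland
and forest, five replicate faunal samples per group × site × landuse plus
five soil samples per site × landuse, a shared lognormal source pool
(σ = 1.5), and raw read depths of 15,000 (above the 13,551 rarefaction
target). Communities are Dirichlet-multinomial draws — soil from the
shared pool with Nm = 3000, each faunal group from a group-biased pool
with its configured Nm. Defaults follow the ordering
collembolan 4026 > predatory mite 2103 > earthworm 1802 >
oribatid mite 1369 > potworm 999 > nematode 667.

Planted structure, and the design choices behind it:

* **Unique taxa.** Each group's unique OTUs carry zero concentration in
  every soil pool, so their absence from soil is a hard guarantee. Their
  pool mass (8 % per group, lognormal weights) plus a read floor (each
  unique OTU receives at least 120 reads study-wide, capped at twice its
  natural expectation, by transferring single reads from dominant OTUs of
  randomly chosen samples of its own group) ensures every planted unique
  survives the 100-read global filter — unique taxa are post-filter
  observables by definition, so ground truth and operational definition
  coincide exactly. A matching floor guarantees every shared OTU is
  detected in at least one soil sample. Unique counts are required to be
  nondecreasing in trophic level.
* **Diversity gradient.** The host-filter tilt (lognormal perturbation of
  the shared pool per group) weakens with trophic level (σ = 0.3 at the
  top level, +0.3 per level below), reflecting generalist predators
  integrating over many prey microbiomes; this plants the positive
  diversity-versus-trophic-level gradient with known sign.
* **δ¹⁵N.** Adjusted values are (TL − 1)·3.4 ‰ plus Gaussian noise of
  sd 0.8 ‰ — small enough that planted levels are recoverable (≥ 90 %
  reassignment at the default design), large enough that boundary
  misassignments occur. Litter baselines are site-specific draws from
  U(−2, 4) ‰.
* **Enterotypes.** Each group has 2–3 planted enterotypes; an enterotype
  fixes its driver genus at 30 % of the pool mass, making the driver
  dominant by construction (that is what an enterotype is) and the planted
  partition recoverable with ARI ≥ 0.9.
* **Dark matter.** A configurable fraction (default 30 %) of OTUs get
  unknown markers at the class and genus ranks.
* The phylogeny is a seeded random binary tree with exponential branch
  lengths over all OTUs.

What the generator does **not** emulate: sequencing error, chimeras, PCR
and copy-number bias, overdispersion beyond the Dirichlet, phylogenetic
signal in ecological niches (the tree is independent of the abundance
structure, so UniFrac results on synthetic data are structurally similar
to non-phylogenetic distances), temporal variation, and taxon-specific
detection biases. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery, not that real soil-fauna data
would yield these effect sizes.

## Problem sizes

The test suite and acceptance script run reduced designs chosen as the
package's own defaults for desk-scale validation: the shared fixture uses
three sites × five individuals (210 samples, 640 OTUs, 3,000 reads);
neutral-model recovery uses 500 samples over 1000-OTU pools at N = 10,000;
calibration suites use 200 replicates with 19–39 permutations/replicates,
which preserves the nominal 0.05 level exactly by the discreteness of the
permutation p-value. The analysis drivers run the full 420-sample design.

## Known limitations

* The Sloan fit treats pool abundances as known; their estimation noise
  widens the empirical spread of occurrence frequencies relative to the
  Wilson band (see above).
* Compact letter displays use the insertion heuristic, which can use more
  letters than the minimal clique cover in pathological significance
  patterns.
* PAM is exact steepest-descent SWAP, O(k·n²) per iteration; for very
  large per-group sample counts a subsampled variant would be needed.
* The pooled Wilcoxon comparison in the network experiment should be read
  qualitatively; calibrated inference uses the Monte-Carlo exceedance p.
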