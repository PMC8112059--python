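# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic data does and does not emulate, and the
choices made where the design was genuinely open.

## STARR-seq activity model and enhancer calling

Counts are modelled as negative binomial in the mean–dispersion
parameterisation, var = μ + αμ². Normalisation uses median-of-ratios
size factors (the factor for a sample is the median, over regions with
all-positive counts, of that sample's count divided by the region's
geometric mean). The DHT-vs-EtOH contrast is a Wald test on
LFC = log2(μ̂_DHT + 1) − log2(μ̂_EtOH + 1) on the normalised scale, with
a per-region method-of-moments dispersion and a delta-method standard
error.

Numerical choices worth knowing:

- **Dispersion pooling.** α is estimated per region from within-group
  variances, pooled across all replicate groups of the experiment
  (plasmid, RNA-EtOH, RNA-DHT) because the NB dispersion is shared
  across conditions. With three replicates per group this gives 6
  degrees of freedom rather than 4, which matters for power at
  multiple-testing-corrected thresholds. No cross-region (trend or
  prior) shrinkage is applied: the estimate stays a per-region moment
  estimate, floored at 1e-8.
- **t reference.** The Wald statistic is referred to a t distribution
  with the dispersion estimate's degrees of freedom. With 3-replicate
  moment dispersions a normal reference is strongly anticonservative
  (observed null rejection ≈0.13 at α = 0.05 in calibration
  simulations); the t reference restores the nominal rate.
- **Pseudocount 1** on the normalised scale in every LFC, so zero
  counts never produce infinities. Regions with identical counts
  everywhere get LFC = 0 and p = 1 exactly.
- **Plasmid-normalised LFC** per condition is
  log2(mean normalised RNA + 1) − log2(mean normalised plasmid + 1),
  i.e. replicate-mean based rather than per-replicate ratios.

Classification applies the three published rules in order with strict
inequalities (inducible: LFC > 1 and BH-adjusted p < 0.05; constitutive:
both plasmid-normalised LFCs > 1 and DHT/EtOH LFC < 1; inactive: both
plasmid-normalised LFCs < 1) and assigns **ambiguous** to anything that
satisfies none — the three rules are not exhaustive, and silent
fall-through to a named class would misreport borderline regions.
Classification is a pure function of the statistics table and the
threshold object.

Tissue-score enrichment between classes z-transforms scores per sample
(removing total-signal differences), takes the per-region median z
across samples, and compares classes with a two-sided Mann-Whitney test,
BH-corrected across comparisons.

## CRE interaction network

Loop anchors are mapped to every region interval they intersect and
every DEG TSS whose ±5 kb window they intersect (0-based half-open
arithmetic throughout); each labelled anchor pair becomes one
deduplicated undirected edge. Only TSSs of differentially expressed
genes become nodes. A loop whose two ends map to the same node is kept
as a self-edge and counts once.

Class-level statistics: relative density D = 2·E_obs/(V(V+1)) over the
whole graph (the V(V+1) denominator admits self-pairs, applied uniformly
to every node type); expected maximum edges E_max = V(V+1)/2 within a
class (combinations with repetition, so self-pairs are counted) and
V·U across two classes; interaction frequency IF = E_obs/(D·E_max). A
graph with D = 0 yields IF = NaN rather than an error. Centrality
(degree, betweenness with the standard 2/((n−1)(n−2)) normalisation) is
computed on the largest connected component only, with size ties broken
by the smallest lexicographic node id for determinism.

Distances from regions to the nearest up-regulated-gene TSS are 0 for a
TSS inside the region and the absolute gap otherwise, floored into
100-bp bins, and summarised per class as an ECDF. Distances are
unsigned and strand-agnostic.

## DeltaCon co-accessibility comparison

Condition-specific graphs keep pairs with co-accessibility score
strictly greater than 0.1 as unweighted edges (scores are thresholded,
not used as weights); isolated nodes stay in the graph so both
conditions share one node set. The affinity matrix is
S = (I + ε²D − εA)⁻¹ with ε = 1/(1 + max degree) computed **once from
the union of both graphs' degrees**, so the two S matrices of a
comparison share ε and their distance is meaningful. The system matrix
is strictly diagonally dominant for this ε, so the solve cannot be
singular; a singular matrix raises rather than being regularised
silently. Dense solves are used throughout (the column-wise
linear-system form and the dense inverse agree to 1e-8 by construction;
the solver is the same code path at every size).

The distance is RootED, d = √ΣΣ(√s₁ᵢⱼ − √s₂ᵢⱼ)²; tiny negative
affinities that can arise numerically are clipped to 0 with a warning
before the square root. A node's impact w is that distance restricted to
its affinity row if any incident edge differs between the two graphs
(symmetric difference of incident edge sets nonempty), and exactly 0
otherwise. Class-level summaries use two-sided Mann-Whitney tests with
BH correction; a comparison where every impact ties (e.g. all zero)
reports p = 1 instead of failing.

## Occupancy features and the ensemble classifier

Per factor, the SES cutoff is the pooled score maximising
F_control(x) − F_observed(x), ties resolved to the smallest score; a
non-positive maximal gap flags "no specific binding". The sigmoid
midpoint m is the median of scores strictly above the cutoff and the
scale is s = (m − cutoff)/ln 9, which anchors occupancy(cutoff) = 0.1
and occupancy(m) = 0.5 — the published transform names both quantities
but not the scale, and this choice pins each to a fixed occupancy.
m = cutoff degenerates to a step function via a tiny floor on s. The
region-level feature is the maximum occupancy over the 750-bp window
(15 bins at 50-bp resolution when profiles are supplied). Missing raw
scores become occupancy 0 and are flagged in a mask: zero-imputation
makes missingness bias toward under-calling, the transparent failure
mode.

Training balances classes by pooling 500 randomly sampled inactive
regions with all constitutive and all inducible regions, then splits
80/20 stratified by class (floor(0.8·n) per class to training). Each
base estimator draws at most 50 class-stratified rows without
replacement and 5 factors, and fits an L1-penalised multinomial
logistic regression (scikit-learn saga solver, penalty 0.1 on
standardised features, tolerance 1e-6). The aggregated weight of a
factor for a class is the mean over the base estimators that sampled
that factor — not a zero-diluted mean over all estimators, which would
conflate sampling probability with effect size — and factors never
sampled are flagged. The published ensemble uses 100 000 base
estimators, which is the function default; the analysis scripts and the
validation runs use 2000, where aggregated weights are already stable
(doubling the count changes them by a few percent).

Binding energy for (factor, class) is the aggregated weight times the
factor's mean occupancy over regions of that class, on the natural
[0, 1] occupancy scale; pairwise differentials (antisymmetric by
construction) rank class-predictive factors. Down-sampled evaluation
refits the ensemble on factor subsets against the same seeded split and
reports inducible-vs-inactive ROC AUC.

Row subsets are drawn without replacement: the published description is
ambiguous between bootstrap resampling and plain subsampling, and
without-replacement stratified draws guarantee every class appears in
every 50-row fit.

## Synthetic data: what it emulates and what it does not

The generators produce region-level inputs with the statistical
structure the analysis assumes, on a single synthetic contig ("chrS",
auto-sized, intervals ≥500 bp placed by rejection sampling):

- **Design groups and classes.** 4139 clinical ARBS at planted
  proportions 0.069/0.112/0.819 (largest-remainder integer allocation),
  2783 ARE-motif-only regions and 500 positive controls with class
  "none" (neutral and fourfold-active respectively).
- **Counts.** NB counts (dispersion 0.05) at baseline mean 200 with
  log-normal (σ = 0.2) library sizes, recorded in the truth object.
  Inducible regions have DHT/EtOH ratio fc_induced = 4 and DHT
  RNA/plasmid ≥ fc_active; constitutive regions fc_active = 4 in both
  conditions; inactive regions ratio 1.
- **Occupancy.** Gamma(2, 1) null scores; the informative factors
  (default 5 of 90) add 3 null SDs at inducible regions; matched
  control scores come from the null; 10% of observed entries are
  masked missing.
- **Loops.** Each region initiates Poisson loops (rate 1, ×3 for
  inducible); partner regions are chosen proportionally to their own
  rate so the realised mean degree ratio equals the planted multiplier;
  30% of loops target TSS anchors, biased (0.7) toward up-DEG TSSs for
  inducible initiators.
- **Co-accessibility.** Uniform(0, 0.2) base scores shared between
  conditions; pairs touching an inducible region gain +0.3 under DHT
  (clipped to [0, 1]).

Every generator is deterministic under a fixed seed, with independent
streams per stage, so regenerating one input does not perturb another.

Not emulated: read-level data (alignment, fragments, peak calling),
single-cell sparsity, real-genome coordinates or sequence composition,
correlated occupancy between factors, distance-dependent looping.
Passing tests therefore demonstrate that the statistical machinery
recovers planted effects of realistic magnitude under the assumed noise
models — not that those models capture every property of the real
assays.

## Problem sizes used in validation

The test suite and the acceptance script run the stages at: 2000
regions for calling recovery and null calibration (4000 null regions
for the raw-test calibration check), 4139 regions / 90 factors / 2000
base estimators for the classifier (20 seeded repetitions for the
energy-ranking check), 200 regions × 200 seeds per condition for the
network power/type-I pair, and 450 regions (150 per class) for the
DeltaCon impact comparison. These sizes give the comparisons enough
resolution that the planted effects are far from their decision
boundaries while a full run stays a desk-scale computation.

## Known limitations

- The NB Wald test is calibrated but slightly conservative at 3
  replicates (observed null rejection ≈0.045 at α = 0.05); DESeq2-style
  dispersion shrinkage would gain power at the cost of cross-region
  coupling, and is intentionally not replicated.
- The ambiguous class absorbs regions the published three rules do not
  cover; its size is a useful diagnostic (it grows when effects sit
  near thresholds) but has no published counterpart.
- Binding energies mix a standardised-scale weight with a natural-scale
  occupancy mean, as the published definition prescribes; energies are
  comparable across factors only through the shared standardisation.
- DeltaCon impact is attributed only to nodes with altered incident
  edges; second-order affinity changes at untouched neighbours are
  measurable but deliberately reported as 0 per the rule.
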