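# Methods

This note documents the models, conventions and numerical choices behind
`invasionscape`, what the synthetic study system does and does not emulate,
and the design decisions taken where the problem left the design open.

## Coordinates and units

All spatial computation runs in planar metres. Geographic input (WGS84
degrees) is projected once at read time with a local equirectangular
projection about a reference point (x = R·cos φ₀·Δλ, y = R·Δφ, R =
6 371 000 m). For study extents of a few tens of kilometres the metric
distortion is of order (extent/R)², far below the 1-km occupancy buffers and
200-m thinning radii that consume these coordinates; the projection inverts
exactly, and full CRS support is deliberately out of scope. Genotypes are
held as alternate-allele counts 0/1/2 with −1 for missing; every surface
(posterior density, hit scores, resistance, diversity) shares one raster
convention (lower-left origin, row 0 at the top, ESRI ASCII on disk).

## Geographic profiling

Thinned occurrence records x₁…xₙ are modelled as i.i.d. draws from a
Dirichlet-process mixture: partition prior CRP(α), component k a bivariate
Normal(μ_k, σ²I) with a *single shared σ* (the species' dispersal scale —
one posterior σ is what the method reports), μ_k uniform over the record
bounding box plus a guard band. Defaults, with rationale:

- **α = 1** (CRP concentration). The expected number of occupied components
  grows as α·log n; α = 1 is the conventional weakly-informative choice and
  is exposed as a parameter for sensitivity analysis.
- **Guard band 10 km** around the bounding box, so sources just outside the
  sampled extent remain representable without inflating the uniform prior's
  volume (which would penalise new components).
- **σ prior**: an inverse-gamma on σ², parameterised on the km scale by a
  mean, variance and shape of the implied σ distribution. The triple is
  over-determined (two free inverse-gamma parameters); the implementation
  takes the shape as the inverse-gamma shape α₀, solves the scale β₀ so that
  E[σ] matches the requested mean, and logs the achieved variance with a
  warning when it differs from the requested one. With the default
  (mean 5 km, shape 1.5) the achieved variance is ≈14.3 km².
- **Sampler**: Gibbs sweeps with auxiliary-component reallocation (m = 3
  fresh uniform proposals per record) for the non-conjugate uniform mean
  prior; conjugate Normal updates for μ_k truncated to the frame (rejection
  with clipping fallback); conjugate inverse-gamma update for σ² pooling
  all records (posterior shape α₀ + n for n 2-D points). Records are
  processed in id order, so the posterior is independent of input order and
  bit-reproducible under a seed; chains use independently spawned RNG
  streams.

Outputs: the posterior distribution of the occupied-component count (its
mode is the reported source count, but the full distribution is always
emitted because any single-number decision rule is a convention); posterior
σ samples per chain with the Gelman–Rubin R̂ = √(((n−1)/n·W + B/n)/W);
a posterior source-intensity surface (occupied means binned per cell plus
the CRP's α/(n+α) unseen-source mass spread uniformly); and hit scores.

The **hit score** of a cell is (number of cells with strictly higher density
+ half the tied cells) / total cells — the fraction of the area searched
before reaching that cell when searching in decreasing density order. Tie
averaging makes the uniform surface score exactly 0.5 everywhere.

Temporal information enters only through thinning (records after the cutoff
year are presumed dispersal-dominated, and only the earliest record within
the deduplication radius is kept); the likelihood itself ignores observation
chronology.

## Occupancy and expansion speed

The extent of occupancy for year y is the area of the union of 1-km discs
(64-segment polygons; the inscribed-polygon deficit is 0.16%, bounded in
tests by a Monte-Carlo rejection oracle) around all records dated ≤ y —
colonised ponds are assumed to stay colonised, so the series is monotone.
The reported speed convention E = √(C/π) converts an area to an
equivalent-circle radius but leaves ambiguous whether C is the cumulative
area or its yearly increment. Both readings are always computed:
radius-difference E_y = r_y − r_{y−1} (default — the only reading that is
dimensionally a front speed for a steadily growing range) and
increment-radius E_y = √(ΔC_y/π). The output flags which is the default so
downstream users can compare.

## Population-genetic estimators

- **He** uses the small-sample correction 2p(1−p)·2n/(2n−1); **F_IS** is
  1 − ΣHo/ΣHe over polymorphic loci (ratio of multilocus sums, the
  hierfstat convention; per-locus averaging of ratios would weight loci
  differently and is not exposed). Monomorphic loci are excluded from F_IS
  (0/0 indeterminate) but count as zeros in distance sums.
- **Pairwise F_ST** is Weir–Cockerham θ with the usual a/b/c variance
  components, combined across loci as a ratio of sums. Negative estimates
  are reported as computed. Note the estimator's finite-sample correction
  means two *identical* samples score slightly negative; its defining
  property — zero expectation over independent samples from one pool — is
  what the tests assert.
- **AMOVA** partitions squared Euclidean genotype distances (pairwise
  missingness rescaled by L/L_shared) into among/within-cluster components;
  Φ_ST = σ²_a/(σ²_a+σ²_w); significance by permuting individuals across
  clusters with the add-one convention p = (1+#{Φ_perm ≥ Φ})/(n_perm+1).
  All permutation p-values in the package use add-one, so p is never 0.
- **PCoA** mean-imputes missing calls per locus (the stated convention for
  this analysis), then double-centres squared Euclidean distances and
  eigendecomposes; axes with positive eigenvalues are returned with
  percent variance.
- **Mantel** correlates upper-triangle entries under simultaneous
  row/column permutation of the second matrix, one-sided for positive
  association. Cross-checked against scikit-bio's implementation in tests.

## Admixture clustering

The sampler implements the admixture model with uncorrelated allele
frequencies: Beta(1,1) priors on cluster frequencies, Dirichlet(1,…,1) on
individual admixture, and latent cluster assignments per allele copy,
all Gibbs-updated in vectorised sweeps. The mean ln-likelihood over sampled
iterations feeds the Evanno table (L', |L''|, ΔK = |L''|/SD over replicate
runs); the best K is the interior argmax of ΔK, or *indeterminate* when the
curvature is zero. Replicate runs are consolidated by aligning cluster
labels to the first run (exhaustive permutation search, K ≤ 8, maximising
summed column correlation) and averaging.

Hierarchical application: localities are assigned to a cluster when their
individuals' mean q ≥ 0.6 (averaging after consolidation), and each cluster
with at least two assigned localities is re-analysed for substructure.
Because ΔK cannot point at K = 1, a level where fewer than half the
localities are assignable at the threshold is declared unstructured and the
recursion stops — without this guard, pure noise would always produce
spurious substructure. The full-scale iteration counts (10,000 burn-in /
100,000 sampling) remain the CLI defaults; tests and the reproduction
script use reduced counts (hundreds of sweeps, ≤ 500 loci) at which the
sampler demonstrably separates origins differentiated at F_ST ≥ 0.1.

## Kinship and directional migration

**Wang (2002) relatedness.** At each locus a pair of diploid genotypes falls
into similarity classes — identical; three alleles shared; exactly one
allele shared (impossible at biallelic loci); none shared — whose
probabilities are linear in φ (one allele pair identical by descent) and Δ
(both pairs IBD), with coefficients that are polynomials in the frequency
moments a₂, a₃, a₄. The implementation computes those moments either from
known frequencies or from sample counts with falling-factorial (unbiased)
estimators, weights loci by 1/(2a₂−a₃), and solves the three moment
equations for (φ, Δ) by least squares; r = φ/2 + Δ. On pedigree
simulations this recovers 0 for unrelated, ≈0.5 for full sibs, and ≈0.5 for
parent–offspring (it estimates r, not the k-coefficients). Pairs sharing
fewer than 20 informative loci are flagged unreliable. Full-sib filtering
removes one random member (seeded, logged) of each same-locality pair at
r ≥ 0.5 until none remains; cross-locality pairs at r ≥ 0.35 are reported
as candidate recent-dispersal edges.

**Directional relative migration.** For an ordered locality pair (a, b) a
hypothetical pool averages their allele frequencies; the rate into b derives
from b's differentiation from that pool, converted to a migration estimate
from two-population G_ST and Jost's D (D = 2(H_T−H_S)/(1−H_S)). The exact
combination of the two statistics used by existing tools is not uniquely
documented, so the package uses the geometric mean of the island-model
estimates Nm_x = (1−x)/(4x) for x ∈ {G_ST, D} — a symmetric, monotone
combination; since the matrix is finally divided by its maximum (rates in
(0, 1]), the choice affects scale, not ordering. Summaries per locality:
mean incoming rate I, mean outgoing rate E, ratio R_I/E (undefined at
E = 0). Cluster comparisons use the Mann–Whitney U test, exact for combined
n ≤ 20 without ties and tie-corrected asymptotic otherwise; the
distance-to-source regression is OLS with per-locality Cook's distances so
influential localities can be identified and re-fitted without them.

## Resistance and diversity surfaces

The IBD trend is fitted by least squares as genetic = a + b·log(1+d) over
individual pairs within d_max (2/5/10 km are the conventional scales); the
log form gives the monotone, concave distance decay expected of
isolation-by-distance with a single transform, and is pluggable. Residuals
are rescaled to [−1, 1] by the maximum absolute residual (a numerically
perfect fit is left at zero rather than amplifying noise). Each pair's
residual is spread along the straight segment between the two individuals;
a cell's resistance is the mean residual of segments intersecting it (exact
box–segment geometry, validated against a supersampling oracle). The null
for a cell crossed by n_c segments resamples n_c residuals from the full
pool without replacement; cells above the 1−α/2 quantile are barriers,
below α/2 corridors, with α = 0.05 split across tails. The null depends
only on n_c, so its RNG stream is keyed on (seed, n_c) — classifications
are then exactly invariant to the order pairs are supplied in.

The diversity surface pools individuals within a window×window block of
cells, and where at least `rarefaction_n` individuals are available
estimates Ho as the mean over 100 seeded draws of that many individuals
(repeated-draw rarefaction, because per-locus pooling under missingness has
no clean closed form; a block with exactly `rarefaction_n` individuals
reduces to their direct Ho). Undefined cells are filled by ordinary kriging
with an exponential variogram fitted to the binned empirical semivariogram
(nugget 0, so defined cells are honoured exactly); a failed variogram fit
falls back to inverse-distance weighting with a logged flag. Interpolated
Ho and geoprofile hit scores are compared at the localities by Pearson
correlation (t = r√((n−2)/(1−r²))): a significantly negative correlation
(diversity declining away from sources) is the serial-founder-effect
signature; its absence is evidence for long-distance dispersal or multiple
introductions.

## The synthetic study system

`simulate_invasion` grows an occupied-pond set from point sources with
staggered introduction years: each pond founds Poisson(0.7) new ponds per
year at bivariate-normal displacements (σ_true per year), with probability
`ldd_rate` drawn from the same kernel scaled ×5 (a crude long-distance
tail, sufficient to break serial founder structure), rejected and redrawn
when the displacement crosses the barrier polyline, and each pond is
detected each year with probability `detection_prob`. `simulate_genotypes`
draws two founder allele pools at a target F_ST under the Balding–Nichols
model (ancestral frequencies Uniform(0.1, 0.9)), seeds demes along a 1-D
river axis from their origin's pool (or sequentially through
founder-size-2–4 bottlenecks in serial-founder mode), runs Wright–Fisher
drift (deme size N = 50 — large enough for stable frequencies, small
enough for visible drift at test scale) with nearest-neighbour migration
reduced across one barrier, and samples whole clutches sharing two parents
so true full-sib sets are known.

What this does **not** emulate: real observation effort gradients and
spatial reporting bias, bullfrog-like stage structure and fecundity,
selection, linkage, genotyping error, and coalescent-scale history.
Passing tests therefore demonstrate that the estimators recover the
generating process they assume, not that field data meet those
assumptions.

## Problem sizes and determinism

The test suite and the reproduction script run everything at desk scale by
choice: geoprofile chains of a few hundred burn-in and samples on 50–150
records recover planted source counts and cover σ_true at the nominal 95%
rate; admixture runs of a few hundred sweeps on ≤ 500 loci separate origins
at F_ST ≥ 0.1; resistance grids are of order 30×30 cells with hundreds of
resamples. Every stochastic component takes an explicit seed (spawned
SeedSequence streams per chain/dataset); reruns are bit-identical, and the
pipeline refuses configs without a seed.

## Known limitations

- The DPM reports *regions of early record density* as sources; secondary
  introductions inside an already-occupied area are not distinguishable
  from local spread, and record clouds from long-running invasions violate
  the static-source likelihood (hence the temporal cutoff).
- Directional migration rates are relative; they order locality pairs but
  have no absolute migrant-count interpretation.
- Kriging assumes second-order stationarity of the diversity field; strong
  anisotropy along a river axis is not modelled.
- The Mann–Whitney exact path is limited to combined n ≤ 20 without ties.
- Evanno's ΔK cannot select K = 1; the unstructured-level guard is a
  pragmatic stopping rule, not a posterior model probability.
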