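# invasionscape

Reconstruct the history and dynamics of a multi-source biological invasion by
combining two independent data streams: dated point **occurrence records**
(citizen-science sightings) and **SNP genotypes** sampled across the invaded
range. The package was built around pond-breeding amphibian invasions along a
river valley — many small localities strung along a 1-D river axis, dispersal
barriers such as canals, and a poorly documented introduction history — but
every component is generic.

## Who it is for

Invasion biologists and landscape geneticists who have (1) a CSV of verified
occurrence records, (2) a VCF (or 0/1/2 CSV) of biallelic SNPs with a
locality assignment per individual, and (3) locality coordinates, and who
want to answer: *how many places did the spread start from, how fast is the
range expanding, and how is gene flow structured across the landscape?*

## What it computes

**From occurrences**

- *Geographic profiling* (`invasionscape.geoprofile`): occurrence records are
  modelled as draws from a Dirichlet-process mixture of bivariate normal
  sources — component means are candidate source locations, the shared
  standard deviation σ is the dispersal kernel scale, and the Chinese
  restaurant process prior leaves the number of sources unbounded. A Gibbs
  sampler (auxiliary-component reallocation, conjugate mean and
  inverse-gamma σ² updates) yields the posterior over the source count k,
  posterior σ samples with Gelman–Rubin convergence checks, a posterior
  source-density surface, and **hit scores**: the fraction of the study area
  that must be searched before reaching a cell, so low scores flag likely
  sources. Records are first thinned (temporal cutoff, 200-m single-linkage
  deduplication keeping the earliest record).
- *Occupancy dynamics* (`invasionscape.occupancy`): the extent of occupancy
  C(year) is the cumulative union area of 1-km discs around all records up
  to that year, and the expansion speed converts areas to equivalent-circle
  radii r = √(C/π), reported both as yearly radius differences and as
  increment radii √(ΔC/π).

**From genotypes**

- Diversity and structure (`invasionscape.popgen_stats`): per-locality Ho,
  unbiased He, F_IS = 1 − ΣHo/ΣHe; pairwise Weir–Cockerham F_ST;
  Cavalli-Sforza & Edwards chord and Prevosti distances; two-level AMOVA
  (Φ_ST with permutation p); PCoA on mean-imputed genotypes; Mantel tests
  for isolation by distance over Euclidean or along-river waterway distance.
- Admixture clustering (`invasionscape.clustering`): a STRUCTURE-style Gibbs
  sampler (uncorrelated frequencies, α = 1), replicate-run consolidation by
  label alignment, Evanno ΔK model choice, and hierarchical reapplication
  within clusters with the q ≥ 0.6 locality-assignment rule.
- Connectivity and kinship (`invasionscape.geneflow_kinship`): Wang (2002)
  pairwise relatedness with full-sib filtering (≥ 0.5 within localities) and
  cross-locality dispersal edges (≥ 0.35); divMigrate-style directional
  relative migration (Nm from G_ST and Jost's D against pooled frequencies,
  max-normalised to 1) with per-locality immigration/emigration summaries
  R_I/E, Mann–Whitney cluster comparisons and distance-to-source
  regressions with Cook's distances.
- Landscape surfaces (`invasionscape.resistance_surface`): isolation-by-
  distance residual resistance maps (residuals from g = a + b·log(1+d)
  spread along pair segments, cell significance by resampling the residual
  pool) and moving-window rarefied-Ho diversity surfaces filled by ordinary
  kriging, correlated against geoprofile hit scores to detect serial founder
  effects.

A synthetic-invasion generator (`invasionscape.synthetic_data`) produces both
data streams with full ground truth — staggered sources, a dispersal barrier,
long-distance dispersal, two divergent founder origins, stepping-stone
drift and clutch (full-sib) structure — so the whole pipeline is testable
offline; the per-locality diversity table of the motivating study system is
shipped as a packaged fixture (`table1_fixture()`).

## Worked example

```python
import numpy as np
from invasionscape import (InvasionTruth, SigmaPrior, simulate_invasion,
                           run_dpm, thin_records, ThinningConfig, eoo_by_year)

truth = InvasionTruth(sources=[(0, 0, 2000), (15_000, 0, 2003)],
                      sigma_true=500.0, detection_prob=0.4)
records = simulate_invasion(truth, range(2000, 2012), seed=42)
thinned = thin_records(records, ThinningConfig(cutoff_year=2006,
                                               dedup_radius=200.0))
profile = run_dpm(thinned, SigmaPrior(mean=5.0, variance=10.0, shape=1.5),
                  n_burn=300, n_sample=600, n_chains=3, cell_m=500, seed=1)
series = eoo_by_year(records)
print("posterior mode of source count:", profile.k_mode)
print("sigma posterior mean (km): %.2f" % profile.sigma_mean())
print("Gelman-Rubin: %.4f" % profile.gelman_rubin_stat)
print("final EOO (km^2): %.1f" % series.eoo_km2[-1])
print("mean expansion speed (m/yr): %.0f"
      % np.nanmean(series.speed_radius_diff_m))
```

Output:

```
posterior mode of source count: 2
sigma posterior mean (km): 1.11
Gelman-Rubin: 1.0012
final EOO (km^2): 69.0
mean expansion speed (m/yr): 339
```

The profiler recovers both planted sources (k = 2) from the 30 thinned early
records — thinning to the pre-saturation years matters, because geoprofiling
assumes records scatter around their sources rather than around a moving
front — and the occupancy series shows the buffered range growing to
~69 km² at a front speed of a few hundred metres per year.

A command-line interface wraps the same functions:

```bash
invasionscape simulate --preset two-origin-barrier --seed 5 --out data/
invasionscape geoprofile --occurrences data/occurrences.csv --seed 1 \
    --out-prefix out/profile
invasionscape occupancy --occurrences data/occurrences.csv --out out/eoo.csv
invasionscape run --config config.json
```

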