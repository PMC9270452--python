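# Methods

## The inference problem

The package asks whether species assemblages grouped into ordered time bins
become more compositionally similar toward the present. With only seven bins,
regressing similarity on time is not credible, and similarity statistics are
sensitive to the number, richness and spatial spread of sites. The core
procedure therefore compares each bin's observed mean pairwise similarity
with a permutation null that reassigns whole sites to bins at random,
preserving (i) every site's species list, (ii) every bin's site count, and
(iii) the global pool of occurrences. Only the association between sites and
time is destroyed. The standardized effect size
`SES = (observed − null mean) / null SD` and a percentile band of the null
replicates summarize each bin.

Assumptions worth stating explicitly:

- **Incidence only.** All metrics are presence–absence; abundance structure
  is deliberately outside scope.
- **Sites are the exchangeable unit.** The null treats sites as
  interchangeable across bins; spatial autocorrelation among sites is not
  modelled, it is addressed by the sensitivity designs (equal-site
  resampling, longitudinal-window restriction, geographic subsets).
- **Pairwise means over non-independent pairs.** The SEM attached to a bin's
  mean similarity is the naive SD/√n over the s(s−1)/2 pairs; pairs sharing
  a site are correlated, so this SEM understates uncertainty. Inference never
  relies on it — it rests on the permutation null.

## Data rules

- **Vetting.** A site enters the analysis only with ≥ 20 species and at
  least one rodent, one artiodactyl and one carnivore. Vetting is idempotent
  and applied before binning.
- **Layer merging.** Fossil layers whose coordinates agree to 4 decimal
  places (≈ 11 m) and whose ages differ by ≤ 500 yr are pooled (species
  union; age = mean of member ages). Merging is a transitive closure, so a
  chain of layers each within 500 yr merges into one site. Merged-layer age
  uses the mean rather than a pooled median; with 5,000-yr bins the choice
  is immaterial to binning except exactly at an edge.
- **Time bins.** Default edges 30,000 / 25,000 / 20,000 / 15,000 / 10,000 /
  5,000 / 500 yr BP plus a modern bin. A bin covers `old ≥ age > young`
  (closed at the old edge), so an age equal to the oldest edge is kept and
  ages in (500, 0] that are not flagged modern are dropped. Alternative edge
  sets (e.g. aligned with climatic events) are plain constructor arguments.
- **Subsets.** Site-level filters: east of the Rockies (lon ≥ −105°,
  configurable) and south of 49° N. Species-level filters: excluding extinct
  species, and strict body-mass thresholds (> 1 kg, > 5 kg). Species filters
  do not re-trigger vetting — they operate on the already-vetted site list —
  and a site stripped of all its species is removed.

## Similarity metrics

Registry names: `jaccard`, `forbes_corrected`, `sorensen` (similarities),
`simpson_turnover`, `nestedness` (Baselga dissimilarity components).
Numerical conventions:

- β_sim = min(b,c)/(a+min(b,c)) is defined as 0 when its denominator
  vanishes (the nested limit), which keeps the partition identity
  β_sor = β_sim + β_sne exact.
- The corrected Forbes index `a(n+√n) / [a(n+√n) + 1.5bc]` equals 1 for any
  strictly nested pair (bc = 0 with sharing), not only for identical sets —
  an inherent property of Forbes-type indices, and the reason Jaccard is the
  headline metric.
- Multiple-site partitions use the closed forms over Σmin(b_ij, b_ji),
  Σmax(b_ij, b_ji) and ΣS_i − S_T; at two sites they reduce to the pairwise
  values. They are reported but not compared across bins with different site
  counts.
- Mean pairwise statistics use unordered pairs without self-pairs.

## Null model and sensitivity designs

- 1,000 shuffle replicates by default. Fewer replicates make the percentile
  band measurably anti-conservative (the empirical false-positive rate at a
  95% band was ≈ 6.9% with 200 replicates vs ≈ 5.4% with 1,000 in
  calibration runs), so the default is not a tuning knob.
- The 95% band is the 2.5th–97.5th percentile of the null replicates
  (distribution-free); a normal-theory band (mean ± 1.96 SD) is available via
  `band="normal"`. When the null SD is zero the effect size is undefined
  (NaN, logged) and significance falls back to the band.
- **Age-error randomization:** each replicate adds N(0, 2000 yr) noise to
  every fossil age (modern sites exempt), re-bins, and recomputes per-bin
  mean similarity; sites perturbed outside the bin scheme (including past
  zero) are dropped for that replicate.
- **Equal-site resampling:** 15 sites per bin (the poorest bin's count) drawn
  without replacement, 1,000 times. The longitudinal-extent variant draws
  only within a window whose width is the smallest per-bin maximum pairwise
  longitudinal distance, placed uniformly at random; a bin-replicate that
  cannot fill after 100 window redraws is recorded as NaN and counted.
- **Richness control:** OLS of per-bin mean similarity on per-bin pooled
  richness (slope, R², p), to confirm the similarity trend is not a species-
  pool artefact.
- One `numpy` Generator seeds every stochastic experiment; replicate index
  advances the stream, so all 1,000-replicate procedures are bit-reproducible
  given a seed.

## Geography

- Sphere of radius 6371 km throughout; distances are haversine.
- The occupancy grid is 100-km squares under a Behrmann (cylindrical
  equal-area, standard parallel 30°) projection: x = Rλcos30°,
  y = R sinφ/cos30°, which is exactly equal-area. The default continental
  window (168.5–51.5° W, 6–84° N) is a configurable choice; any fixed-extent
  grid is valid since occupancy is a proportion of its cell count. Sites map
  to the nearest cell center, ties going to the lower cell index, so
  co-located sites occupy one cell and never inflate occupancy.
- **Range size** is the summed convex-hull area of single-linkage point
  clusters covering ≥ 95% of a species' occurrence points (≥ 5 sites
  required). Clustering is greedy and deterministic: the cheapest move is
  either attaching a point to the cluster to whose three nearest members it
  has the smallest mean distance, or seeding a new cluster from a point and
  its two nearest unassigned neighbours (scored by the trio's mean pairwise
  distance); joins win ties, then the lowest point index. Clusters are then
  retained largest-first (ties by compactness, then lowest member index)
  until coverage reaches the level, which discards outlying small clusters.
  Hulls of < 3 distinct points contribute zero area.
- **Distance decay** is a binomial GLM with log link (similarity is bounded
  and the classic decay form is exponential); OLS is available by flag.
- **Multivariate dispersion** embeds a dissimilarity matrix by principal
  coordinates and reports mean distance to the group centroid, subtracting
  squared distances on negative-eigenvalue (imaginary) axes before the
  square root and clipping at zero — the standard correction for
  non-Euclidean dissimilarities.
- **Space-for-time map:** for each occupied focal cell, occupied neighbours
  within 1,000 km are subsampled without replacement with probability ∝ 1/d
  (10 cells by default), and the cell's value is the mean pairwise Jaccard
  among the sampled cell assemblages; cells without occupied neighbours are
  NaN.

## Climate turnover

Four variables (annual minimum and maximum temperature in °C, actual
evapotranspiration and total precipitation in mm/yr) are standardized and
decomposed by a single pooled PCA across all time slices, so scores — and
hence turnover, the mean pairwise Euclidean distance in (PC1, PC2) within a
slice — are comparable between slices. A per-slice PCA mode exists for
sensitivity checks but its turnover values share no common basis. Euclidean
distance on the first two components is the dissimilarity; 500-yr slice
turnovers average (unweighted) into the 5,000-yr bins. Duplicated samples are
ordinary samples: all unordered pairs, including zero-distance ones, enter
the mean.

## Synthetic records

The generator emulates the structure of a vetted late Quaternary compilation:
~350 species with log-uniform body masses (0.01–1,000 kg) across a
Rodentia/Artiodactyla/Carnivora/other mix (40/10/15/35%), 35–67 spatially
clustered sites per bin across seven bins (352 sites at the defaults),
detection probability 0.75, and latent geodesic-disc ranges (log-normal
radii, median 1,000 km). Every emitted site passes the ≥ 20-species /
three-order vetting by construction (failed draws are redrawn). An extinction
pulse removes 72% of species heavier than 44 kg from all bins younger than
10,000 BP by default. `range_inflation` is a per-bin **area** multiplier
(radius × √m), so an inflation of 1.5 injects a 50% mean range-size increase
— the magnitude the recovery analyses are designed to detect — and, through
increased co-occurrence, a positive similarity signal in the inflated bins.

What the generator does not emulate: taphonomic and collection biases
correlated with age or body size, time-averaging within sites, irregular
(non-disc) and environmentally structured ranges, spatially varying detection
and richness gradients, and taxonomic uncertainty. Passing calibration and
recovery tests therefore demonstrates the *machinery* is unbiased and
powerful under known truth, not that real records are free of these biases —
that is exactly what the sensitivity designs probe on real data.

### Validation experiment designs and sizes

- **Calibration:** 500 datasets at generator defaults with no extinction and
  no inflation; 1,000 shuffle replicates each. Expected: ≈ 5% of bins outside
  the 95% band, mean SES ≈ 0. Exchangeability holds because site placement
  and composition are independent of bin when no signal is injected.
- **Power:** 100 datasets at defaults with 1.5× inflation in the final two
  bins; late-bin SES should exceed +1.96 in ≥ 80% of runs (empirically ~100%).
- **Range recovery** uses a dedicated dense two-bin design
  (`simulate.range_recovery_config`): 150 species, 3,500 uniformly placed
  sites per bin, detection 0.9, compact discs (median radius 400 km,
  log-SD 0.2) kept ≥ 800 km inside the domain edge, vetting disabled. The
  design exists because convex hulls of k points under-cover their generating
  region by a factor that shrinks as k grows; with O(100) occurrences per
  species per bin and no disc clipping at the domain boundary the
  inflated-to-baseline ratio of mean hull areas is recovered within a few
  percent (pilot mean 1.478–1.505 for a true 1.5), whereas sparse clipped
  designs mis-recover it by construction, not by implementation error.

## Known limitations

- The naive SEM on mean pairwise similarity (above) is descriptive only.
- Cluster-hull range areas are biased low for sparsely recorded species;
  comparisons across bins are safe only when per-species occurrence counts
  are comparable, which is why the per-bin mean is paired with a
  site-shuffling null rather than read absolutely.
- The grid's cell count depends on the chosen window; occupancy values are
  comparable only within one grid.
- The binomial-log distance-decay GLM can fail to converge when similarities
  hug 1; the OLS fallback is provided for such data.
- Multisite partition values depend on the number of sites and are not
  compared across bins by the pipeline.
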