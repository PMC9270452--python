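# paleobeta

Quantitative tooling for detecting **biotic homogenization** — the increase
through time of compositional similarity among ecological assemblages — in
time-binned fossil and modern occurrence records, built for late Quaternary
North American mammal faunas but agnostic to taxon and region.

Paleoecologists comparing assemblages across millennia face two coupled
problems: occurrence data are unevenly sampled in space and time, and the
number of time bins is far too small for regression-style inference. The
package addresses both with the field's standard design: vetted
presence–absence assemblages, incidence-based similarity metrics, and a
site-shuffling permutation null.

## The model

For sites *i, j* with species sets *S_i, S_j*, pairwise similarity is measured
by the Jaccard index

    J(i, j) = a / (a + b + c)

where *a* is the number of shared species and *b, c* the numbers unique to
each site (joint absences are ignored). The corrected Forbes index, the
Sørensen index, and Baselga's partition of Sørensen dissimilarity into
turnover (Simpson, β_sim) and nestedness (β_sne = β_sor − β_sim) components
are available under the same interface, in both pairwise and multiple-site
forms.

The test statistic per time bin is the mean of *J* over all s(s−1)/2 site
pairs. Its null distribution comes from shuffling whole sites among bins —
preserving each site's species list and each bin's site count — and the
departure from the null is the standardized effect size

    SES = (observed − null mean) / null SD,

with significance read from the 2.5th–97.5th percentile band of the null
replicates. SES > 0 means assemblages in that bin are more alike than
expected if composition were unrelated to time: biotic homogenization.

Around this core the package provides:

- **occurrences** — CSV ingestion, merging of stratigraphic layers dated
  within 500 years at one deposit, site vetting (≥ 20 species; Rodentia,
  Artiodactyla and Carnivora all present), 5,000-year time binning, and the
  six standard data subsets (all; east of the Rockies; south of 49° N;
  excluding extinct species; species > 1 kg; species > 5 kg).
- **nullmodels** — the `HomogenizationModel`/`HomogenizationResults` pair,
  age-error randomization (N(0, 2000 yr) dating noise), equal-site
  resampling (15 sites per bin, optionally within a restricted longitudinal
  window), and the similarity-vs-richness control regression.
- **geography** — great-circle distances, a Behrmann equal-area 100-km grid,
  single-linkage cluster hulls for 95%-level geographic range size, grid
  occupancy, distance decay of similarity, multivariate dispersion, and a
  space-for-time similarity map.
- **climate** — correlation PCA of four climate variables and per-slice
  climate turnover (mean pairwise distance in PC1–PC2 space).
- **simulate** — a synthetic fossil-record generator with latent disc
  ranges, an extinction pulse for large-bodied species, and controllable
  per-bin range inflation, so every stage is testable with known truth.

## Worked example

Generate a synthetic record whose final two bins carry a 1.5× range-area
inflation (a homogenizing signal), then fit the permutation null:

```python
from paleobeta import GeneratorConfig, HomogenizationModel
from paleobeta.simulate import bin_dataset, generate_dataset

cfg = GeneratorConfig(range_inflation=(1.0,) * 5 + (1.5, 1.5))
ds = generate_dataset(cfg, seed=11)
binned = bin_dataset(ds, cfg)
results = HomogenizationModel(binned, metric="jaccard").fit(reps=1000, seed=12)
print(results.summary())
```

```
Biotic homogenization: site-shuffling permutation null
metric: jaccard   replicates: 1000   sites: 352   band: percentile
------------------------------------------------------------------------------
           bin   observed  null mean   null sd     lo95     hi95      SES
------------------------------------------------------------------------------
   30000-25000     0.2437     0.2330    0.0160   0.2064   0.2679    0.67
   25000-20000     0.2406     0.2339    0.0145   0.2088   0.2638    0.46
   20000-15000     0.2318     0.2345    0.0139   0.2107   0.2644   -0.20
   15000-10000     0.2363     0.2330    0.0128   0.2112   0.2618    0.25
    10000-5000     0.2273     0.2343    0.0127   0.2121   0.2620   -0.55
      5000-500     0.2789     0.2335    0.0116   0.2122   0.2578    3.91*
        modern     0.2733     0.2341    0.0108   0.2146   0.2562    3.62*
```

The five uninflated bins sit inside the null band (|SES| < 1); the two
inflated bins show mean Jaccard similarity well above the null (SES 3.9 and
3.6, starred), i.e. the injected homogenization is detected exactly where it
was placed. `results.to_frame()` returns the same table tidily;
`results.plot()` draws the similarity curve with the null ribbon.

The same analysis runs from the shell:

```sh
paleobeta sim --seed 11 --out data/
paleobeta run --seed 12 --input data/ --out results/ --reps 1000
paleobeta report results/
```

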