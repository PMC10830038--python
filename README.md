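# telemax

Winter-season distribution modelling for GPS-tracked raptors: a tested,
reusable implementation of the full analysis chain from raw satellite
telemetry to an evaluated habitat-intensity map.

## The problem

Conservation planning for golden eagles (and similar wide-ranging raptors)
has historically focused on territory-holding adults at their nests.  In
winter, however, the population in a region like the interior western U.S.
is a mixture of resident breeders, non-territorial adult "floaters",
pre-breeding-age residents, and long-distance migrants from the subarctic —
groups whose habitat use is not captured by nesting-habitat models.
`telemax` implements the analysis a team would run to map the **relative
intensity of winter use** for those groups from a multi-study GPS/Argos
telemetry compilation and a library of environmental rasters, and to
quantify how much the resulting winter surface overlaps an independent
(e.g. nesting) surface.

Because real eagle telemetry is proprietary, the package ships a
first-class synthetic-data module that emulates the whole study — smooth
autocorrelated covariate fields, a known ground-truth intensity surface,
and two-state movement tracks for all life-history groups with injected
Argos error and spike outliers — so every stage is testable against known
truth.

## The model

Filtered, thinned presence locations `x_1..x_n` are contrasted with
background points drawn from the modelled area (within 20 km of training
locations) under the maximum-entropy / inhomogeneous-Poisson point-process
model: the relative intensity at a cell with feature vector `f(x)` is

    λ(x) ∝ exp( f(x) · λ̂ )

with coefficients maximising the L1-penalized log-likelihood

    L(λ) = mean_presence f(x)·λ − log mean_background exp(f(x)·λ) − Σ_j β_j |λ_j| ,

where `β_j` scales with the regularization multiplier, a feature-class base
penalty interpolated in the presence sample size, and the feature's SD on
the background sample.  Features are the standard MaxEnt expansions
(linear, quadratic, product, threshold, hinge, categorical indicators),
and the solver is monotone proximal coordinate descent.  Upstream of the
model sit the telemetry filters (Argos location-class screen, spike and
velocity filters, hourly standardisation, NOAA-solar daytime windows,
residence-in-space-and-time behavioural segmentation, two-per-day
thinning, 75/25 split), KDE-based life-history classification, and
multi-scale focal covariate engineering with mean-ratio and VIF screening.
Downstream sit the evaluations: binned calibration R², area-adjusted
frequencies (AAF), the Boyce index (Spearman rank correlation of AAF
against bin rank, reported squared), AAF magnitude-of-difference, repeated
holdout cross-validation, per-region calibration, coarse-grid quartile
concordance, top-quantile overlap between two surfaces, and
surface-management observed:expected summaries.

## Worked example

Evaluate a published per-group AAF table and run a seeded parameter-recovery
study (1 informative + 4 noise covariates, 1,000 presence points):

```python
from telemax.datasets import example_aaf_table
from telemax import evalsuite as ev
from telemax.pipeline import run_recovery

tbl = example_aaf_table()
aaf = tbl["adult_migrant"].to_numpy()
print("Boyce (squared):", round(ev.boyce_index(aaf), 3))
print("AAF magnitude:  ", round(ev.aaf_magnitude(aaf), 1))

r = run_recovery(seed=1)
print("truth Spearman rho:", round(r["spearman_rho"], 3))
print("holdout calibration R^2:", round(r["holdout_r2"], 3))
print("top covariate:", max(r["contributions"], key=r["contributions"].get))
```

prints

```
Boyce (squared): 0.976
AAF magnitude:   128.4
truth Spearman rho: 0.986
holdout calibration R^2: 0.991
top covariate: wind_uplift_1
```

The Boyce value of 0.976 says the adult-migrant test locations are ranked
almost perfectly by the intensity bins (the single swap between bins 1 and
2 costs 0.024); the AAF magnitude ~128 says the top bin is used ~128×
more, per unit area, than the lowest occupied bin.  In the recovery run
the fitted surface reproduces the ground-truth intensity ranking
(ρ = 0.986) and correctly identifies the generating covariate.

A full synthetic pipeline — simulate, filter, classify, screen covariates,
tune the regularization multiplier, fit, project, evaluate — runs from the
command line:

```bash
telemax run --config configs/demo.yaml --out out/ --seed 7
```

Each stage writes its artifacts and a provenance manifest under `out/`
(about half a minute at the bundled demo scale; see `telemax run --help`
for production-style settings).

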