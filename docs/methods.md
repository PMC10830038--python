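# Methods

This note documents the models and procedures implemented in `telemax`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design
was genuinely open.

## 1. Telemetry filtering

The filtering ladder reduces a raw multi-source telemetry compilation to
winter daytime sedentary locations away from breeding territories, in this
order:

1. **Proofing.** GPS fixes are kept; Argos (Doppler) fixes are kept only in
   location classes 3, 2, 1 (nominal error radii < 250 m, 250–500 m,
   500–1500 m).  *Spikes* — out-and-back artifacts — are interior fixes
   whose turn angle is below 15° with both adjacent legs above 2,500 m, or
   below 25° with both legs above 5,000 m; the filter re-runs until no
   spike remains, since removals expose new neighbour geometry.  A greedy
   forward velocity filter removes fixes implying sustained speed above
   `vmax` from the last retained fix; candidates are 20, 27.8 and 40 m/s
   with a default of 27.8 m/s (the middle candidate).  The per-individual
   visual choice of threshold used in field practice is not reproducible
   and is replaced by this configurable default.
2. **Standardisation.** At most one fix per individual per UTC clock-hour
   (earliest kept).  Clock-hours rather than rolling 60-minute windows:
   deterministic and timezone-free.
3. **Season and daytime.** Winter is December–February; summer (kept
   separately for home-range estimation) is June–August.  Winter fixes
   survive only within [sunrise + 1 h, sunset − 1 h], with sunrise/sunset
   from the NOAA solar equations (zenith 90.833°) evaluated per fix from
   its coordinates.  Accuracy is ~1–2 minutes, ample for a ±1 h margin.
4. **Behavioural state.** Residence in space and time (RST): within each
   gap-free tracking bout (≥ 28 days, no gap > 48 h), every fix gets a
   residence time and residence path-length inside the 30-km circle
   centred on it, computed by exact segment–circle clipping.  Both are
   normalised to [0, 1] **by the within-bout maximum** and the residual
   (time − distance) classifies the fix: negative = distance-intensive =
   transit; otherwise sedentary (time-intensive and time-and-distance-
   intensive pooled).  We anchor the normalisation at zero rather than at
   the within-bout minimum deliberately: both quantities have a natural
   zero, and subtracting the minimum amplifies microscopic within-patch
   variation into the full [0, 1] range whenever a bout contains little
   true transit, randomising the residual's sign (measured ~50%
   misclassification on truth-labelled tracks, versus ~1% with the maximum
   anchor).  The 30-km radius is the largest of the candidate set
   {6, 10.5, 15, 22.5, 30 km}, giving an inclusive definition of sedentary
   behaviour that removes only fast long-distance transit.
5. **Thinning.** Two fixes per individual-day — one uniformly random
   before local solar noon, one after, at least 1 h apart; a lone
   half-day contributes one fix.  Solar noon is computed per fix from its
   longitude (the study-wide "~12:20 local standard time" value is used
   only as a documentation cross-check).
6. **Split.** A uniform random 75/25 train/test partition.

Filters only remove rows; every removal records the first rule that fired,
and input count = output count + per-reason removals by construction.

## 2. Life-history classification

Each individual-winter is assigned to adult/non-adult (age ≥ 4 biological
years, biological year starting in April) × migrant/non-migrant, with
resident adults split into territory holders and non-territorial floaters:

* **Migrants** originate (tagging latitude) or keep a summer range (mean
  summer latitude) north of 58.25° N; all their study-area winter fixes
  are retained.
* **Nestling-tagged birds** with known natal sites lose fixes that are both
  within one year of tagging and ≤ 3.2 km of the natal site (territory
  core radius).  First-calendar-year birds with unknown natal sites are
  removed entirely if their summer and winter 95% KDEs overlap and both
  are < 200 km² (conservative natal-territory screen).
* **2–3-year-olds** not tagged as nestlings keep all winter fixes.
* **Adults** with all summer fixes > 16 km outside the study area are
  non-territorial (all fixes kept).  Otherwise a summer 95% KDE is
  required; individuals with < 25 summer locations or < 30 days are
  removed as unassessable.  A KDE < 200 km² marks a territory holder and
  winter fixes inside the governing summer polygon are removed; ≥ 200 km²
  marks a floater (all fixes kept).  Adults with no summer fixes at all
  are treated as non-territorial rather than removed — with zero summer
  presence there is no evidence of a local territory.

Home ranges are 95% kernel density isopleths with per-axis bandwidth =
0.7 × the ad hoc bivariate-normal reference bandwidth (σ·n^(−1/6)).  The
"0.7" is read as a bandwidth multiplier — the standard `href × proportion`
convention of home-range software.  The density is a binned KDE (2-D
histogram smoothed by the kernel), evaluated on a ~256-cell grid with a
4-bandwidth margin; the isopleth threshold is the largest density level
whose superlevel set holds 95% of mass, and area is cell count × cell
area.

## 3. Covariates

Base rasters (120-m native convention; tests and synthetic studies use
coarser grids, see §7) are summarised over circular windows at extents
(diameters) from the native cell to 6.4 km with mean/SD/min/max focal
statistics; at the native extent the window is the single cell, so only
the mean (identity) is generated.  Edge cells use the window's
intersection with the (buffered) grid.

Screening is two-stage:

1. **Best scale per base variable.**  Candidates are min-max rescaled to
   [0, 1] — making the screen invariant to units and usable for fields
   that take negative values — and scored by mean-at-training-locations /
   mean-at-10,000-random-locations.  Candidates where fewer than 20% of
   training locations have non-zero values are discarded (the sparsity
   clause is ambiguous in its source; the ≥ 20%-non-zero reading avoids
   selecting pathologically sparse layers).  Near-ties (within 5%
   relative) resolve to mid-ladder extents and to mean over SD over
   min/max — a deterministic stand-in for expert judgment.
2. **VIF within category.**  At the background sample (subsampled to
   10,000), the layer with the largest variance inflation factor is
   removed while any VIF ≥ 4; categorical layers are exempt.

## 4. The intensity model

Presence/background maximum entropy, equivalent to an inhomogeneous
Poisson point process.  Background: 100,000 points (configurable) uniform
over the modelled area — grid cells within 20 km of any training location.
Features: linear, quadratic, pairwise products of surviving covariates,
threshold indicators and hinge ramps on background-quantile knot grids
(default 50 knots), and per-class indicators for categorical covariates;
every feature is affinely scaled to [0, 1] on the background sample, and
projection clamps covariates to their training range (clamp counts are
logged).  Penalties follow the published MaxEnt convention:
β_j = reg_multiplier × class-beta(n_presence) × SD_j(background) / √n_presence,
with class-beta tables {linear/quadratic/product: 1.0→0.05 over n = 10→100;
categorical: 0.65→0.25; threshold: 2.0→1.0; hinge: 0.5}.

The solver is cyclic proximal coordinate descent: each coordinate takes a
Newton step soft-thresholded by its penalty, halved until the penalized
objective does not decrease, so the objective path is monotone
non-decreasing and (the problem being convex) converges to the global
optimum; the stopping rule is relative objective change < 1e-6 over a full
cycle.  Per-coordinate objective increases are credited to the updated
feature's parent covariate (split evenly for products) and normalised to
100% — the percent-contribution table.

The regularization multiplier is tuned by repeated holdout: for each
candidate in {0.5, 1, 2, 4, 8}, k = 10 times, ~25% of training locations
are held out, the model is refitted, and binned calibration R² on the
holdout is recorded; the best mean R² wins, ties to the larger multiplier
(the more general model).  After tuning, covariates contributing < 1% are
dropped and the model refitted, up to three rounds.

Output scaling: raw relative intensity exp(f·λ̂) is min-max scaled to
[0, 1] over the clipped area (not logistic/cloglog), because the response
is interpreted as relative intensity of use on an equal-interval 0–1 map
scale.

## 5. Evaluation

All calibration evaluations use 10 equal-interval bins of the scaled
surface, (0, 0.1], …, (0.9, 1.0], with 0 in bin 1.  Predicted counts
share the test total out proportional to summed intensity per bin;
calibration R² is the squared Pearson correlation of observed and
predicted counts.  AAF is (bin's share of locations)/(bin's share of
area); Σ_b AAF_b × area-share_b = 1 identically.  The Boyce index is the
Spearman correlation of AAF against bin rank 1..10, reported squared
(matching the convention of the evaluation tables this suite mirrors; the
signed value is also returned); bins with zero area are excluded.  The
AAF magnitude-of-difference is top-bin AAF over the lowest bin with
AAF > 0.  Cross-validation repeats a 22% random holdout (configurable to
25%) k = 10 times and reports per-bin means with normal-theory 95% CIs.
Geographic evaluation recomputes the bin tables within region masks
(pooled R² across region-bin pairs) and, at 30-km/15-km grid scale,
compares quartile bins of observed counts against predicted counts (mean
cell AAF × cell's share of the modelled area × n_test); quartiles come
from mid-rank percentiles so tied blocks land mid-scale, and only cells
containing test data are binned.

**Sample-size sensitivity of the Boyce index.**  Because the intensity
surface is min-max scaled to its maximum cell, the top equal-interval
bins cover well under 1% of area.  With a few hundred evaluation points
their observed counts are single digits, and the AAF rank ordering — and
hence the Boyce index — is dominated by counting noise: a Monte-Carlo
with a perfectly calibrated model and a typical bin structure reaches
squared-rank Boyce ≥ 0.9 only ~13% of the time at 250 evaluation points,
~54% at 1,000, and ~99% at ~9,000.  Binned-calibration R² is far more
robust at small n (it weights bins by their counts).  Boyce-based
conclusions should therefore rest on evaluation sets of several thousand
points.

## 6. Comparison of two surfaces

Cell-wise Spearman correlation over the mutual valid footprint; top-10%
and top-20% **area** quantiles (fixed cell counts, ties broken by
intensity then deterministic cell order — value-range quantiles would not
sum across categories) with percent overlap measured against one top set
(both have equal area by construction); and per-management-category area
shares, top-quantile shares, and observed:expected = top-10% share /
area share.

## 7. Synthetic data

The generator emulates the study's data regime with known truth:

* **Covariates:** Gaussian-filtered white noise (default smoothing length
  10 cells), standardised, one shared latent component per category
  (correlation 0.6) to exercise redundancy screening; a categorical
  ecoregion layer bins a heavily smoothed field into ≥ 2 contiguous
  classes.
* **Truth intensity:** exp of a linear combination of chosen layers,
  normalised to sum to 1 (computed with max-subtraction, so it cannot
  overflow for finite inputs).
* **Movement:** a two-state discrete-time model.  Sedentary: AR(1)
  jitter (σ = 1.5 km, lag-1 correlation 0.9) around patch centres drawn
  proportional to truth intensity, with per-fix displacement capped at
  2.4 km so undisturbed movement sits strictly below the spike filter's
  leg threshold — only injected outliers and Argos error create spike
  geometry, making the "no outliers ⇒ proofing removes nothing"
  invariant exact.  Transit: directed 10 m/s legs between patches
  (default separation ≥ 100 km), advancing only during a ±4 h window
  around local solar noon so transit is observable after the daytime
  filter.  Group structure: migrants summer at 60–64° N; breeders hold
  compact summer territories (95% range ≪ 200 km²) partially reused in
  winter; floaters range over three shifting summer centres (range ≫
  200 km²); non-adult residents are half nestling-tagged with known natal
  sites, half 2–3-year-olds.  Default deployment counts per group
  (54/60/44/74/36) mirror the winter tracking sample the study design
  follows.
* **Observation error:** a configurable Argos fraction (default 9%) with
  class mix over {3, 2, 1, 0, A, B} and class-specific isotropic
  displacement radii; spike outliers displace a configurable fraction of
  fixes by 5–15 km.

What it does **not** emulate: real movement energetics, weather-driven
behaviour, demography, fix-rate duty cycling, or real Argos error
geometry.  Passing tests demonstrate that the implementation recovers
known structure under this generative model, not that the model describes
any particular real dataset.

**Problem sizes.**  The synthetic studies used by the test suite and the
acceptance script run at reduced scale chosen to keep each study
statistically informative while completing in seconds: grids of
100–150 km at 1-km resolution (the production convention is 120 m),
10–16 individuals at one fix/hour, 1,000 presence points with 5,000
background points for parameter recovery, and 2 winter patches per
individual.  All stochastic stages derive their streams from a single
seed plus fixed per-stage offsets; identical configurations reproduce
bit-identical outputs.

## 8. Known limitations

* The spherical Lambert azimuthal equal-area projection ignores the
  Earth's flattening; areas are exact on the authalic sphere (sub-0.5%
  error at study scale), which is ample for relative-use modelling.
* The binned KDE underestimates isopleth area for very small samples
  (n < ~30) where the histogram approximation is coarse.
* Percent contribution is path-dependent (credited along the coordinate-
  descent trajectory), like the convention it mirrors; correlated
  covariates share credit in an order-dependent way.
* The Boyce index at small evaluation sample sizes is noisy (see §5).
* Tuning, pruning, and cross-validation refit the model repeatedly; with
  the full 100,000-point background and 50-knot hinge grids this is
  minutes of compute, and the defaults in the bundled configurations are
  scaled down accordingly.
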