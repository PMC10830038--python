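# Small demonstration study: 150-km grid at 1-km resolution, 12 birds.
nrows: 150
ncols: 150
resolution: 1000.0
n_per_category:
  climate_weather: 1
  vegetation_landcover: 1
  topography: 1
  wind_uplift: 2
true_betas:
  wind_uplift_1: 1.2
group_counts:
  adult_migrant: 2
  adult_resident_breeder: 2
  adult_resident_floater: 2
  nonadult_resident: 4
  nonadult_migrant: 2
n_winter_patches: 2
min_patch_separation_m: 50000.0
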