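# pwsfire

Plant-water sensitivity and wildfire vulnerability analysis for gridded
fuel-moisture data.

## The problem

Rising atmospheric aridity — measured as vapour-pressure deficit (VPD) —
drives increasing burned area in semi-arid regions, but ecosystems differ
widely in how strongly their vegetation moisture responds to climatic water
limitation. **Plant-water sensitivity (PWS)** quantifies that response per
pixel: it is the summed slope of a distributed-lag regression of live-fuel
moisture content (LFMC, % water per dry biomass) anomalies on dead-fuel
moisture content (DFMC, a meteorologically derived wetness index) anomalies,

```
PWS_s = Σ_i β_{s,i}
LFMC'_{s,t} = Σ_{i=0,15,…,150} β_{s,i} · DFMC'_{s,t−i} + γ_s ,   β_{s,i} ≥ 0
```

with lags `i` from 0 to 150 d in 15-d (half-monthly) steps, anomalies taken
against each pixel's epoch-of-year climatology, June–November observations
over a five-year window, and every slope constrained non-negative (drier
air must not make fuels wetter). High PWS means LFMC tracks climate water
stress closely; low PWS means the vegetation buffers it.

The package implements the full analysis chain around that statistic:

- **`pwsfire.regression`** — `NonNegativeLagRegressor`, an exact
  active-set NNLS estimator with a free intercept (scikit-learn API);
- **`pwsfire.pws`** — per-pixel lag-design construction, masking rules
  (≥ 50 % valid LFMC record, ≥ 30 design rows) and the PWS map;
- **`pwsfire.sensitivity`** — equal-vegetated-area binning of the PWS map,
  per-bin OLS of annual burned area on annual mean VPD (April–March fire
  years), the final slope-vs-PWS regression, hazard classes
  (low < 1 ≤ medium ≤ 1.5 < high) and the percent-change variant;
- **`pwsfire.drivers`** — random-forest attribution of PWS to 14 plant and
  soil hydraulic trait rasters with normalised impurity importance and
  3-fold cross-validation;
- **`pwsfire.trends`** — per-pixel VPD trends, double-hazard masks,
  wildland–urban-interface (WUI) population exposure by hazard zone, and
  confounder screens (mean/variance VPD, NDVI metrics, antecedent
  precipitation sensitivity);
- **`pwsfire.synthetic`** — generators for every input with recorded
  ground truth, so each stage is testable closed-loop;
- **`pwsfire.grid` / `pwsfire.preprocess` / `pwsfire.io`** — grid
  definitions and regridding, the half-monthly epoch calendar,
  climatologies/anomalies, fire-year aggregation, NetCDF/TIFF/CSV I/O;
- **`pwsfire.pipeline` / `pwsfire.cli`** — a `pwsfire` command-line
  orchestrator (`simulate`, `pws`, `hazard`, `run-all`).

## Worked example

A 64×64 synthetic domain with a known PWS field in [0, 2], AR(1) climate
anomalies, LFMC generated from the true lag kernels plus noise, and burned
area following the affine law d(BA)/d(VPD) = 350 + 233·PWS km² hPa⁻¹:

```python
import numpy as np
from pwsfire import (GridDef, LagConfig, estimate_pws_map, make_truth,
                     simulate_climate, simulate_lfmc, simulate_annual_vpd,
                     simulate_fire, equal_area_bins, bin_annual_series,
                     ols_slope, sensitivity_curve)
from pwsfire.preprocess import AnnualFireSeries

grid = GridDef(64, 64, pixel_area=16.0)
truth = make_truth(grid, seed=42)
climate = simulate_climate(grid, range(2015, 2021), seed=43)
lfmc = simulate_lfmc(climate, truth, noise_sd=4.5, seed=44)
pws = estimate_pws_map(lfmc, climate.dfmc, LagConfig())

years, vpd = simulate_annual_vpd(grid, range(2001, 2021), seed=45)
ba = simulate_fire(truth, years, vpd, seed=46, noise_sd=1.0)
fire = AnnualFireSeries(years, ba, vpd, grid)
bins = equal_area_bins(pws, np.ones(grid.shape, bool), grid.pixel_area, 15)
_, bab, vpdb = bin_annual_series(fire, bins, grid.pixel_area)
slopes = [ols_slope(bab[:, b], vpdb[:, b]) for b in range(15)]
curve = sensitivity_curve(bins, slopes)
```

This prints (via the obvious `print` statements):

```
valid pixels: 4096
median fit r2: 0.27
corr(PWS_hat, PWS_true): 0.811
d(BA)/d(VPD) vs PWS: slope = 174.2 km2/hPa per PWS unit (truth b = 233.0), r2 = 0.97, p = 5.8e-11
```

Reading the numbers: every pixel had a sufficiently complete LFMC record;
the per-pixel lag regressions achieve a median r² of 0.27 at this noise
level, yet the estimated PWS map still correlates 0.81 with the generating
truth. The slope-vs-PWS regression is extremely tight (r² = 0.97) but its
coefficient (174) is attenuated below the generating value (233): binning
on a *noisy* PWS estimate dilutes the regression by roughly the square of
the estimate–truth correlation. Binning on the true PWS field (or lowering
the LFMC noise) recovers 233 within a few percent — the acceptance script
below does exactly that.

The same loop runs from the shell:

```sh
pwsfire run-all --seed 42 --out run/ --verbose
```

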