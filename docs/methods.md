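# Methods

## The PWS statistic

Plant-water sensitivity at pixel *s* is defined through a distributed-lag
linear model of live-fuel-moisture anomalies on dead-fuel-moisture
anomalies,

LFMC′(s, t) = Σᵢ β(s, i) · DFMC′(s, t − i) + γ(s),  β(s, i) ≥ 0,
PWS(s) = Σᵢ β(s, i),

with lags i ∈ {0, 15, …, 150} days (11 terms on the half-monthly epoch
calendar). The slopes are dimensionless (% LFMC per % DFMC) and the sum is
unweighted, so concurrent and antecedent moisture conditions count
equally. The non-negativity constraint encodes the physical prior that an
increase in climate-derived moisture can never dry live fuels; roughly
half the coefficients end up exactly zero under noise, which the fit
reports as `zero_fraction`.

**Solver.** The intercept is eliminated exactly by centring (for any fixed
slope vector the optimal intercept is ȳ − x̄·β), after which
`scipy.optimize.nnls` — an active-set method that is exact and
deterministic for these 11-column designs — solves the constrained
problem. The test suite checks the solver against exhaustive active-set
enumeration (all 2¹¹ column subsets), which is the independent oracle.
With a free intercept the intercept-only model is nested in the feasible
set, so the in-sample r² is never negative; it is still clipped at zero
defensively.

**Observation window and masking.** Fitting uses June–November epochs of
2016–2020 (plant dry-down season; 60 rows when complete). Pixels whose
in-season LFMC record is ≤ 50 % valid are masked, as are pixels with fewer
than `p_min = 30` complete design rows (≈ 2.7 observations per parameter;
the value tolerates exactly the 50 % loss the validity mask allows). Rows
with any missing lagged predictor are deleted listwise. Because the season
starts at epoch-of-year 11 and the deepest lag reaches back 10 epochs,
lagged predictors never cross a calendar-year boundary; computing both
climatologies over the same 2016–2020 window therefore makes the
noise-free closed loop exact to machine precision.

**Anomalies.** The epoch calendar splits each month into days 1–15 and
16–end (24 epochs/year). Anomalies subtract the pixel's epoch-of-year mean
over the analysis years; entries with fewer than 2 contributing years are
nodata (a 1-year "climatology" would force that year's anomalies to zero).
The DFMC climatology uses all epochs of the year, not only June–November,
because the lagged predictors reach back into spring.

**Known estimator bias.** Truncating zero-mean slope estimates at zero
inflates PWS under noise: each candidate lag contributes a half-normal
spurious slope of scale ≈ noise_sd / (predictor_sd · √n_rows), about
0.1 · noise_sd/predictor_sd in the standard design. At the calibrated
noise level this floor is ≈ 0.3 PWS units for a pixel whose true PWS is
zero. The bias is monotone in noise and common to all pixels, so rank
structure (and hence binning) is far less affected than absolute levels —
which is why PWS recovery is assessed by correlation, and why the null
(β* = 0) check in the tests runs at small noise.

## Burned-area sensitivity to VPD

The PWS map is split into k = 15 classes of equal vegetated area by
sorting pixels on PWS and cutting the cumulative-area curve (ties broken
by pixel index; bin areas differ by at most one pixel). Per bin and
April–March fire year, burned area is summed and VPD averaged with
vegetated-area weights (an unweighted mean is available via a switch).
Each bin's d(BA)/d(VPD) is an OLS slope with an unconstrained intercept
and classical standard error; the final curve is an unweighted OLS of the
bin slopes on the bin-representative PWS (area-weighted mean by default,
median optional). The displayed per-bin standard errors are not used as
weights in the final regression.

Because a bin's summed burned area scales with the area aggregated,
slope-curve coefficients for different bin counts are compared after
normalising to a common aggregation area (the 10-bin coefficient is
multiplied by 10/15 before being set against the 15-bin one); at the
generator's noise level they agree well within mutual standard errors.

Hazard classes on PWS use low < 1, medium 1–1.5 (closed), high > 1.5 —
the only exhaustive, non-overlapping reading of the class boundaries. The
percent-change variant transforms each bin's burned area to
100·(BA_y − BA_2001)/BA_2001 before the OLS on VPD, giving % per hPa and
making the slope invariant to rescaling burned area.

## Trait attribution

A random forest regresses the PWS map on 14 static trait rasters
(six soil: saturated conductivity K_s, retention shape n, porosity,
sand/silt/clay; eight plant: canopy height, xylem capacitance, stomatal
slope g₁, maximum xylem conductance, ψ₅₀, hydraulic functional type,
isohydricity, maximum rooting depth). Hyperparameters: 50 trees, minimum
six samples per leaf, minimum impurity decrease 5×10⁻⁶, minimum two
samples per split, per-tree bootstrap resampling (the natural reading of
"bootstrapped samples during node splits"). Importance is the normalised
mean impurity decrease; fit strength is 3-fold cross-validated r² with
random pixel folds. Traits with > 50 % missing pixels are excluded with a
warning; remaining incomplete pixels are dropped listwise. The categorical
hydraulic-functional-type trait stays integer-coded (trees split integers
natively and a single importance per trait is wanted).

**Spatial leakage caveat.** Trait rasters are coarser than the analysis
grid (nearest-neighbour upsampled), so pixels within one coarse block
share identical trait vectors. With a spatially smooth response, random
(unblocked) CV folds then measure block memorisation, not skill: in the
synthetic null (traits independent of PWS) CV r² is ≈ −0.05 when trait
vectors are independent per pixel but ≈ 0.9 when duplicated over 4×4
blocks. The package therefore runs null checks at coarse factor 1 and
ships a spatially-blocked-CV switch for real coarse rasters; the default
remains random folds to match the stated protocol.

## Trends, double hazard, exposure

Per-pixel VPD trends are OLS slopes of annual-mean VPD on year (1980–2020
design; ≥ 10 years required), vectorised but identical to the textbook
formula, with relative trends dividing by the pixel's long-term mean.
Double hazard marks pixels by either criterion: PWS and trend jointly
above their medians (computed over jointly valid pixels, which avoids
mask-induced bias), or PWS ≥ 1.5 with an above-average trend (mean by
default, median switchable). Under independent continuous fields the
joint-median fraction converges to 0.25, a useful null anchor.

WUI exposure sums the 1990 and 2010 census populations over WUI pixels per
hazard zone; percent changes are undefined-and-flagged (not infinite) for
zones with zero base population, and zone shares sum to one per epoch.
Confounder screens report Pearson r and r² of PWS against candidate
covariates over jointly valid pixels; the antecedent-precipitation screen
first fits per-pixel OLS slopes of fire-season NDVI on December–May
precipitation, then correlates those slopes with PWS per land cover and
optionally per mean-precipitation group. Constancy checks use a relative
tolerance of 10⁻¹⁰ so that exactly-linear inputs (whose fitted slopes
differ only by rounding) are recognised as constant.

## Synthetic data and calibration

The generators emulate the statistical structure the analysis assumes:

- **Climate** — pixel-specific seasonal cycles (smooth random mean, amplitude
  and phase fields) plus AR(1) anomalies with lag-1 autocorrelation 0.7
  and marginal sd 3 % (DFMC). VPD anomalies share a negatively signed
  component with DFMC (weight 0.5 by default; 0 for independence tests)
  plus an optional secular trend. All fields are bit-reproducible given
  (config, seed).
- **LFMC** — seasonal cycle plus the true kernel convolution of DFMC
  anomalies plus Gaussian noise; kernels are sparse exponentials
  (decay ≈ 3 epochs, 60 % of lags retained, lag 0 always active) rescaled
  so their sum equals a smooth PWS field spanning [0, 2].
- **Noise calibration** — the noise level targeting a median per-pixel fit
  r² of 0.3 starts from the analytic value sd_signal·√((1−r²)/r²) and
  bisects a multiplier against the median r² measured on a 512-pixel
  subsample (the analytic value ignores the finite 60-row design and the
  non-negativity constraint). Achieved map-wide medians land within ±0.05
  of the target.
- **Burned area** — BA(s, y) = base(s) + (a + b·PWS*(s))·(VPD(s, y) −
  ref)/area_norm + noise, clipped at zero (base is set high enough that
  clipping is negligible); area_norm equals the expected bin membership so
  that equal-area-bin sums have slope ≈ a + b·mean(PWS). Defaults a = 350,
  b = 233 km² hPa⁻¹ put the sensitivities at ≈ 350 for PWS 0 and ≈ 700 for
  PWS 1.5. Annual VPD combines a smooth pixel mean (15–25 hPa), a shared
  interannual component (sd 1.5 hPa) and small pixel noise (sd 0.2 hPa).
  The shared component is common to all pixels, so a single realisation's
  domain-mean trend estimate carries noise of sd σ/√Stt (≈ 0.02 hPa yr⁻¹
  over 41 years); trend-recovery checks therefore either use 2·SE bounds
  or average over an ensemble of realisations.
- **Traits** — generated at a coarser grid (default factor 4, emulating
  25-km products) as linear functions of standardised block-mean PWS plus
  noise, then nearest-upsampled; texture fractions are softmax-normalised
  and the functional type is quartile-coded.
- **WUI** — a random 30 % of classified pixels, lognormal 1990
  populations rescaled to configured zone shares, 2010 = 1990 × zone
  growth × optional jitter. The calibrated configuration (total 10 M, zone
  shares 0.558/0.345/0.097, growths 2.07/1.95/2.60) yields a 108 % total
  change and a high-hazard share moving from 9.7 % to ≈ 12.1 %.

**What passing these tests does not show.** The generators are Gaussian,
spatially smooth and stationary; real fuel-moisture retrievals have
retrieval bias, snow/cloud gaps with seasonal structure, spatially
correlated noise and land-cover heterogeneity, and real burned area is
zero-inflated and fat-tailed rather than Gaussian around an affine law.
Closed-loop recovery demonstrates the estimators are correct and
well-conditioned under the assumed structure, not that the assumptions
hold for any particular real dataset.

## Problem sizes and numerical choices

The standard fixture is a 64×64 grid (4,096 pixels) over six years
(2015–2020, the first year providing the lag window), chosen so the whole
closed loop — calibration, PWS map, binning, attribution — runs in well
under a minute per stage on one CPU while leaving enough pixels for stable
rank statistics. Equal-area binning breaks PWS ties by flat pixel index
via a stable sort, making results independent of pixel ordering. Regrid
block methods require integer resolution ratios; bilinear propagates
nodata from any contributing source cell, while block aggregation ignores
nodata unless a whole block is empty. Maps are written as float64 TIFFs so
resumed pipeline stages reproduce byte-identical reports. All seeds are
explicit; every generator, the forest and the CV folds are deterministic
given them.

## Known limitations

- PWS carries the positive truncation bias described above; absolute PWS
  levels at high noise should be interpreted relative to the ≈ 0.3 floor.
- Binning on an estimated (noisy) PWS map attenuates the slope-vs-PWS
  coefficient by roughly the squared estimate–truth correlation
  (regression dilution); the package reports what the data support and
  makes the clean-recovery comparison available through the generators.
- Random-fold CV over spatially structured predictors overstates fit
  quality; use the blocked-CV option when trait rasters are much coarser
  than the response.
- No uncertainty is attached to PWS itself (none is defined for the
  statistic), and no map projections are handled — all grids are assumed
  co-registered.
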