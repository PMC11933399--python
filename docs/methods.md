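# Methods

`aquahazard` implements a national-scale groundwater-quality assessment
as a reusable, testable pipeline: screening ten physico-chemical
parameters against drinking-water standards, aggregating violations
into a district-level multi-parameter hazard index by two independent
estimation pathways, scoring districts with the Weighted Arithmetic
Water Quality Index (WAWQI), attaching population exposure, and
analysing monitoring-station time series.  Because the national agency
well databases this kind of study relies on are generally not
redistributable, the package ships a synthetic-data generator that
reproduces their statistical anatomy, and every estimator is validated
against the generator's exhaustively computable ground truth.

## Hazard index

For each district the index is the mean over the n = 10 index
parameters (chloride, alkalinity, nitrate, nitrite, fluoride,
phosphate, TDS, hardness, iron, sulphate) of the within-district
proportion of evaluation units violating the WHO / US EPA limit:

    index = (1/n) * sum_par  #(units violating) / #(units).

The index lives in [0, 1].  Screening uses strict inequality — a value
exactly at the limit is compliant.  Iron is the one deliberate
reversal: low iron in drinking water provides no nutritional benefit
and is associated with anemia in children and pregnant women, so iron
counts as violating *below* its 0.3 mg/L limit.  pH is carried in
descriptive statistics only and never enters the index.

Two pathways produce the evaluation units:

* **interpolated** — each parameter's point observations are mapped
  onto a 2-km raster (ordinary kriging; IDW for nitrate) and the units
  are the grid cells inside the district;
* **imputed** — missing well values are completed by chained
  random-forest imputation and the units are the district's wells.

Both always run and are reported side by side; their agreement is
itself a robustness check.

Hazard classes use fixed breaks (0.10, 0.20, 0.30), chosen so that the
extremes typical of national studies (district indices of roughly 0.09
to 0.37) span the low to very-high classes; a boundary value joins the
upper class.  Population exposure is all-or-nothing at district
resolution: a district's whole population (regardless of actual
drinking-water source) counts as exposed when its index exceeds a
threshold.  No consensus cutoff for "exposed to poor groundwater
quality" exists, so the threshold is a required, explicit argument
everywhere (the CLI and acceptance script use 0.2, the middle class
break, and say so).

## WAWQI

Unit weights are inversely proportional to the standards,
W_i = K / S_i with K = 1 / Σ(1/S_i) (so Σ W_i = 1); quality ratings
are Q_i = 100 (V_i − V_o)/(S_i − V_o) with ideal V_o = 0 for all
chemical parameters (7.0 would be used for pH); the score is
Σ W_i Q_i / Σ W_i, and the conventional bands classify it:
[0, 25) excellent, [25, 50) good, [50, 75) poor, [75, 100) very poor,
≥ 100 unsuitable.  District scores are the mean of per-well scores —
this preserves the influence of hotspot wells, which scoring the mean
concentrations would smear out; the alternative is available via
`aggregate="score_of_means"`.  Where the Sri Lankan national standard
is a desirable-to-permissible range, the single screening scalar is the
lower (most protective) bound.

## Spatial interpolation

Ordinary kriging solves the semivariance system augmented with the
unbiasedness constraint (weights sum to 1), giving predictions and
kriging variances; with a zero nugget it interpolates exactly.  The
empirical semivariogram is binned half squared differences; models
(spherical, exponential, gaussian) are fitted by least squares with
Cressie weights, N_j / γ_model(h_j)² — pair-rich bins count more and
short lags, which govern interpolation behaviour and the nugget, are
not drowned out by the far-lag bins.  By default all three families are
fitted and the lowest weighted SSE wins; a nonzero fitted nugget lets
kriging filter measurement noise instead of honouring it.  Gaussian
models with a zero nugget are numerically near-singular, so a tiny
ridge (sill × 1e-8) stabilizes them.

Concentrations are strictly positive and right-skewed, so kriging runs
in log space by default and back-transforms with the lognormal mean
correction exp(pred + σ²/2), σ² being the kriging variance of the log
field (`log_transform=False` disables the whole transform).  Nitrate is
routed to inverse-distance weighting (power 2, 12 neighbours) to
preserve local variation; IDW predictions are convex combinations of
neighbour values and exact at data points.

For networks larger than `max_neighbors` (default 32) kriging switches
to a moving neighbourhood with batched linear solves; the global and
moving predictions agree closely away from neighbourhood truncation.

Leave-one-out standardized RMSE — the RMS of (held-out residual /
predicted kriging sd) — is the calibration diagnostic: ≈ 1 means honest
variances; inflating the sill by 4 halves it.

## Chained random-forest imputation

Per-parameter coverage in the emulated survey ranges from 96% down to
29%, so the point pathway first completes the table.  The imputer
follows the standard chained random-forest scheme: initialize missing
cells with column medians; visit parameters in order of increasing
missingness; regress each on all other index parameters plus the
auxiliary predictors (x, y, depth, and one-hot district / climate
zone); re-predict its missing cells; stop when the normalized squared
change in imputed values first increases (keeping the previous
iterate), or after `max_iter = 10` rounds.  Forests use 100 trees and
mtry = sqrt(p), the convention of random-forest imputation; each fit's
out-of-bag predictions give a per-variable error estimate without a
held-out set.  Observed cells always pass through unchanged, and a
single seed fixes every forest.

Imputation error against known truth is the NRMSE over the deleted
cells only,

    NRMSE = sqrt( mean((X_true − X_imp)²) / var(X_true) ),

pooled across parameters after dividing each parameter's squared errors
by the variance of its own true masked values — without that
standardization TDS (hundreds of mg/L) would drown out fluoride
(tenths).  0 is perfect; ≈ 1 is no better than the column mean, and
mean imputation indeed scores ≈ 1 under MCAR.  On the default synthetic
scenario the chained-RF imputation reaches roughly a quarter to a third
of the baseline's NRMSE; the per-variable OOB breakdown is always
reported alongside.  Single imputation deliberately estimates
conditional means — it understates tail fractions at districts whose
concentrations hug a limit, which is why the imputed pathway carries a
looser recovery tolerance than the interpolated one.

## Synthetic world

The generator emulates a Sri Lanka-sized study: a 250 × 420 km
rectangle partitioned into 25 Voronoi districts, three contiguous
climate zones assigned by a smooth northeast gradient (dry north/east,
wet southwest; 50/30/20% of districts by rank), and lognormal district
populations scaled to exactly 22 million.

True concentration fields are lognormal transforms of Gaussian random
fields (Gaussian-filtered white noise, 40 km correlation length,
within-zone coefficient of variation 0.8), multiplied onto a zone-mean
surface blurred 15 km across zone boundaries (chemistry transitions
gradually, not at administrative lines) and renormalized so each
climate zone's realized spatial mean matches its published target
exactly.  Lognormal marginals reflect the strong right skew of such
surveys (e.g. chloride mean ≈ 4× median).  Parameters share latent
fields in two clusters — a salinity/mineralisation cluster (chloride,
TDS, hardness, sulphate, alkalinity) and a nutrient cluster (nitrate,
nitrite, phosphate), with fluoride and iron independent — giving the
cross-parameter correlation (latent weight 0.7) that imputation needs
to beat the mean baseline.

Wells are placed uniformly at random, read the nearest truth cell, and
carry 5% multiplicative lognormal measurement noise; depths are
lognormal around a 40 m median clipped to 4–105 m.  Missingness is
MCAR per parameter at the rates implied by the emulated survey's
observed counts (4% hardness … 71% phosphate).  Each generator stage
mixes a distinct domain tag into its seed sequence, so passing the same
integer seed to successive stages cannot couple their random streams
(e.g. a deletion mask correlating with well coordinates).

What the generator does **not** emulate: the real island geography and
aquifer units, preferential well placement near settlements, non-random
(MNAR) missingness, temporal drift across four decades of one-off
sampling, and censored laboratory detection limits.  Passing recovery
tests therefore show that the estimators are correct and well
calibrated under clean MCAR, stationary-noise conditions — not that
real agency data meet those conditions.

The dense truth rasters stay available, so
`true_district_exceedance` can score both pathways against exhaustive
counting.  A note on that comparison: because the fields are smooth at
the 40-km scale, a district whose concentrations hug a limit turns the
violation fraction into a knife-edge functional — millimetre-scale
prediction wobble (even just the 5% measurement noise) moves the
fraction by tenths.  District-index errors average this over ten
parameters, but occasional per-parameter excursions of 0.1–0.2 at such
districts are intrinsic to threshold counting, not estimator bugs.

## Station trends

Surface-water series are analysed at monthly cadence: calendar-month
means (empty months stay missing, never zero), OLS of value on
mid-month decimal time with slopes reported per year (Theil–Sen behind
`robust=True`), a 12-month missing-aware climatology, and a station ×
month matrix with rows ordered by descending station mean (ties broken
by station id) for heatmap display.  A trend requires at least 24
monthly values; a climatology at least 12.

## Numerical and design choices

* Strict-inequality screening; boundary values compliant.
* Cell-centre containment assigns grid cells to districts; a cell on a
  shared boundary goes to the lowest district id.
* Duplicate well coordinates are averaged (with a warning) before
  kriging; ill-conditioned systems get a ridge jitter with a warning.
* Degenerate (constant) data yield a flagged nugget-only variogram and
  a constant interpolation surface.
* NRMSE uses population variance (ddof = 0), matching the plain "mean"
  in its numerator; zero-variance masked truth raises rather than
  returning infinity.
* All coordinates are planar km; real-data users can carry a CRS string
  through the I/O layer, but no reprojection happens inside the tool.
* Run orchestration derives one sub-seed per stage as
  `(seed · 1000003 + crc32(stage)) mod 2³¹`, making a whole run
  reproducible from one integer.
* Problem sizes in the shipped tests (688–2,000 wells, 2-km grids, 25
  districts, 5–10 seeds) match the defaults of the emulated study; the
  recovery suite uses 2,000 wells so sampling error does not mask
  estimator bias.

## Known limitations

* Single imputation, no uncertainty propagation; multiple imputation is
  out of scope.
* Isotropic variograms only; no co-kriging, no anisotropy.
* Exposure is all-or-nothing per district and uses total population —
  it is an upper bound given actual source-mix data.
* The WAWQI variant implemented is the canonical one; sub-index
  conventions differ across the literature, so the standards table and
  ideals are explicit arguments for swapping.
* No risk computation (risk = hazard × exposure × vulnerability):
  vulnerability modelling needs data the method does not assume.
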