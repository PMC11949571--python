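# Methods

This note documents the models implemented in `karst_gep`, the choices made
where the published method left the design open, what the synthetic data
emulate, and the limits of what the tests demonstrate.

## Accounting chains

**Grazing.** Grazing capacity is a field statistic — cattle per hectare for
natural and artificial grassland — not derived from biomass and intake
norms. Whether a per-unit figure denotes potential carrying capacity or
realized stocking is often ambiguous in survey data; the config therefore
accepts both (`gc_*_pua` and optional `gc_*_realized_pua`) and
`grazing_basis` selects which enters the account, and hence the realized
value. The default is `potential`.

**Water retention.** The yield Y_x = (1 − AET/P)·P is damped by three
capped factors (flow velocity, topographic index, saturated conductivity).
Numerical choices: the topographic-index logarithm is base 10 by default
(`ti_log_base: "e"` switches to natural log — seasonal-water-yield
implementations differ on this, and an unqualified "log" conventionally
means base 10); a negative TI floors the middle factor at 0 so retention is
never negative; zero-precipitation cells yield zero rather than NaN. The
249 and 300 caps are config-exposed (`velocity_cap`, `ksat_cap`) because
their unit-dependence is not documented in the source method. The
mm→tonne conversion is the dimensional identity 1 mm over 1 hm² = 10 m³ =
10 t. Velocity coefficients are supplied per land-cover class through a
required CSV lookup; there are no hidden defaults.

**Soil retention.** The RUSLE cover/practice bracket is implemented as
printed in the source method, (1−C)·P; `rusle_bracket: standard` gives the
more common retention form (1−C·P). The sediment-reduction chain is grouped
dimensionally: mass / bulk density → volume (m³), × sediment fraction ×
reservoir-capacity cost. Nutrient contents are configured as printed
percentages (`nutrient_content_percent`) and converted to mass fractions
exactly once, in `StudyAreaConfig.soil_params()`; a test pins this.
Organic-matter content (~41%) is treated as a mass fraction of retained
soil exactly like N/P/K, since it is supplied in the same list. Soil
retention is reported both as t·yr⁻¹ and kg/m² over the grassland mask
(1 t/hm² = 0.1 kg/m²).

**Carbon and oxygen.** The dry-matter→carbon constant is 0.45
(config-overridable). The oxygen chain applies the 32/44 CO₂→O₂ mass ratio
to the two vegetation compartments only — soil and karst carbon release no
oxygen. Note a dimensional tension inherited from the source method: the
quantities entering the 32/44 ratio are labelled carbon, not CO₂; the
chain is implemented exactly as specified rather than silently corrected,
and the ratio is itself a config field for users who prefer a different
convention.

**Biodiversity.** Shannon–Weiner index per 1 m² quadrat with natural log,
averaged over the (typically three) quadrats of a plot, then over the plots
of a stratum — never computed on pooled counts. Tier pricing uses half-open
intervals [lo, hi): an index exactly on a bound takes the tier that starts
there. The four default tier bounds (0, 0.5, 1.0, 1.5) follow grassland
assessment practice; the prices are deliberately **required** config —
the authoritative tier-price table is not public, and inventing prices
silently would corrupt every downstream value.

**Tourism.** The time-cost weight α has no default for the same reason: it
is a judgment call between 0 and 1, and the CLI offers a sensitivity sweep
(`--sweep`) over {0, 0.25, 0.5, 0.75, 1}. Times are declared in days or
hours per segment and converted to days. The wage rate is the daily rate
(annual wage / 365), computed upstream.

**Account.** GEP is the exact floating-point sum of the seven components;
shares and the realization rate are derived from it; rounding happens only
at the report layer (2 decimals). All arithmetic is in USD at the fixed
2023 rate of 7.0467 CNY/USD; CNY figures are a report-time conversion.
`validate_account` re-derives cross-checks (component sum, rate range,
share sum, per-unit × area vs total, and agreement with any supplied
published figures) and flags failures instead of resolving them — a
published total that disagrees with published per-unit × area is reported
as an internal inconsistency, never reconciled silently.

## Bare-rock index

NDRI is stretched between its p_low = 1% and p_high = 99%
cumulative-frequency anchors (linear-interpolation percentiles) and clamped
to [0, 1]; the anchors are saturation points, so clamping (not masking) is
the intended behaviour outside them. The literal published normalization
places the high anchor in the numerator, which makes the output non-positive
for ~99% of cells and contradicts its meaning as a cover fraction; it
remains available (`as_printed=True`, CLI `--ndri-as-printed`) for
comparison. Normalization is per input raster; computing one stretch over a
pooled mosaic is possible by mosaicking upstream.

## Driver analysis

Pearson correlations (two-tailed by default; one-tailed exposed) with
significance stars at 0.05/0.01; constant columns are flagged with NaN,
not dropped. One-way ANOVA (F via pooled sums of squares) is followed by
Fisher's LSD pairwise test on the pooled within-group mean square, with a
compact letter display (insert-and-absorb). The random forest uses 500
trees, a 70/30 train/test split, impurity importance normalized to sum
to 1, and a fixed seed (default 20230801); the published analysis states no
hyperparameters, so these are chosen for reproducibility. Metrics (R²,
MAE, MSE, RMSE, MAPE as a fraction; zero-truth rows excluded from MAPE
with a logged count) are computed on the held-out split, and the report
records that choice. Below n = 30 the report carries a small-sample
warning and claims no cross-validation.

## Synthetic study areas

The generator emits three complete input bundles along a desertification
gradient. Its defaults are anchored to the three South China Karst
demonstration areas: precipitation means 984.4/1192.5/1100 mm, temperatures
12.8/15.5/18.4 °C, elevations 1878/1300/947 m, natural/artificial grassland
areas 593.11+4.89, 95.14+17.02, 209.27+22.09 hm², 9/6/6 villages, natural-
stratum Shannon targets 1.22/0.88/0.40. Soil depth thins (40/25/15 cm) and
the bare-rock target rises (0.12/0.30/0.50) along the gradient; velocity
and conductivity parameters are set so mean water retention (≈14/11/6 mm)
and RUSLE factors so soil retention (≈46/14/3 kg/m²) decrease monotonically
with comfortable margins at the default 100×100 raster of 10 m cells.

Mechanics worth knowing:

* **Seeding** — one global seed fans out through
  `numpy.random.SeedSequence(seed, spawn_key=(area, stream))`; every output
  file has its own stream, so adding an output never perturbs existing
  ones, and bundles are byte-reproducible.
* **Float32 quantization** — rasters are rounded through float32 before
  both writing and truth computation, so the pipeline's disk round-trip
  matches the generator's closed-form account (`known_truth`) to float
  precision.
* **Shannon tuning** — quadrat counts are multinomial (120 individuals, 12
  species) over a geometric-series abundance vector whose entropy is set to
  the target by bisection; the multinomial entropy bias ≈ (S−1)/2N ≈ 0.05
  keeps plot means within 0.1 of target.
* **Bare rock** — the rock-cover field is a Gaussian random field pushed
  through a Beta(5t, 5(1−t)) quantile map, so both the level and the shape
  of the NDRI distribution track the target and the per-raster percentile
  stretch preserves the gradient ordering.
* **Villages** — the realization rate is planted as a linear function of
  two drivers (default AAP and AA, standardized; coefficients 12 and 8 on
  the percent scale, noise SD 3), so driver-recovery is testable.
  Within-area SDs for village precipitation (130 mm) and elevation (350 m)
  reflect karst relief and keep the planted signal identifiable: elevation
  and precipitation anchors are anti-correlated *between* areas, and
  narrower within-area variation would let that collinearity cancel the
  planted drivers' marginal associations.

**Driver-study size.** At the surveyed design (21 villages) impurity-based
importance cannot attribute even a noiseless signal: with 14 training rows,
fully-grown trees hit ties that leak importance to arbitrary features (a
feature that *equals* the target earns only ~0.6 importance). Recovery
simulations therefore use `driver_study_spec` — 30 villages per area
(n = 90), where the same estimator assigns ~0.95 to a copied feature and
recovers the planted pair in 20/20 simulations. The bundle default remains
the surveyed 9/6/6.

**What the synthetic data do not emulate:** real Sentinel-2 radiometry,
spatial autocorrelation beyond smooth Gaussian fields, measurement error in
plot biomass protocols, or the socioeconomic covariance structure of real
villages. Passing the recovery tests shows the pipeline computes its own
equations correctly end-to-end through file I/O; it does not validate the
equations against independent field measurements.

## Known limitations

* Published per-area component values are not fully deposited at the needed
  granularity, so the published random-forest fit statistics and importance
  shares are not reproduction targets; the oracle, recovery and invariant
  suites stand in for them.
* The realization-rate reproduction from the archived supplementary
  component table requires downloading that table (see
  `tests/test_acceptance.py` for the expected path and columns); without it
  that check reports failure.
* Valuation is annual and static: no discounting, capitalization or
  benefit transfer.
* Raster I/O targets single-band TIFFs with GDAL-style nodata and pixel
  scale tags plus a JSON description; full GeoTIFF CRS machinery
  (projections, transforms) is out of scope — grids are compared by an
  opaque CRS tag and must be co-registered upstream.
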