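# Methods

This note documents the models, numerical choices and open design decisions
behind `biopotential`, and what the synthetic-data tests do and do not show.

## Pedotransfer (soil_capacity)

Soil-evaluation records carry a texture class (S, Sl, lS, SL, sL, L, LC, C)
and a quality index, the Bodenzahl (integer, 1–100). The packaged reference
table (`data/nfk_reference.csv`) maps each (class, Bodenzahl interval) to a
plant-available field capacity class nFK ∈ {50, 90, 140, 200, 250, 270,
300} mm. Interval predicates are lower-exclusive/upper-inclusive
(`lo < n ≤ hi`); the top interval of each type is open-ended. One printed
boundary of the sandy-loam row carries an obvious sign typo in its source
and is shipped corrected (`> 92`, consistent with every other row).
Non-integer soil numbers are floored with a warning.

For a continuous estimate, one anchor is placed per interval — closed
intervals at their midpoint, the open top interval at its lower bound plus
half the preceding interval's width — and a polynomial is least-squares
fitted through the anchors. The degree is the smallest value (capped at 4)
whose maximum anchor residual is ≤ 5 mm; a fixed low degree (1–2) cannot
meet that bound for the types with six or seven classes, which is why the
degree adapts per type (S:2, Sl:2, lS:3, SL:3, sL:3, L:4, LC:2, C:1).
Because a raw polynomial may dip outside its anchor range, evaluation is
tabulated on the integer Bodenzahl grid, repaired to be non-decreasing by a
running maximum, and clamped into the type's class-value range. Class
values feed the simulation (data units are class-based); continuous
estimates feed the mapping step. Both conventions are exposed.

## Climate preparation (climate_prep)

Daily records (station, date, t_mean, precip, optional t_min/t_max) are
aggregated per station-month: temperatures averaged, precipitation carried
**both** as the monthly total and the mean daily rate, because "monthly
mean values" is ambiguous for rain; the crop engine consumes the total (a
water balance needs depth, not rate). Months missing more than 5 days are
flagged, not dropped — an invented quality gate. The long-term normal
period defaults to 1981–2010 and is configurable. Region assignment
resolves in order: explicit region id → polygon containment → nearest
station centroid.

## Surrogate crop engine (crop_engine)

The engine is deliberately a minimal, fully inspectable stand-in for a
process-based crop model, run per data unit and year on monthly inputs
(matching the monthly aggregation of the climate data). Per season month:

    w   ← min(nFK, w + P)                      soil water bucket, full at season start
    D   = k_c · 5.0 mm/°C · max(T, 0)          evaporative-demand proxy
    S   = min(w, D);  w ← w − S                supply
    f_T = clip((T − T_base)/(T_opt − T_base), 0, 1)
    ΔB  = G_max · f_T · (S/D if D > 0 else 1)

Yield = harvest index × ΣΔB, capped at 30 t DM/ha. The model is
deterministic, non-decreasing and saturating in nFK, and zero when the
whole season stays at or below the base temperature. Winter crops span the
year boundary: the harvest year indexes the season (Oct of year−1 … summer
of the harvest year), and the pipeline generates one climate lead year so
the first harvest year is simulable.

Crop parameter files (`data/crops/*.yaml`) were calibrated once so that
adjusted regional mean yields on the synthetic region fall in realistic
bands for a temperate lowland (maize 12–19, triticale 14–17, cup plant
12–19 t DM/ha) with the expected qualitative structure: maize (C4,
summer season, k_c = 1.0) most water-sensitive and highest-yielding when
warm and watered; winter triticale (season Oct–Jun, k_c = 0.9, growth
concentrated before summer drought) least nFK-sensitive; cup plant
(established perennial stand, Apr–Sep, k_c = 1.2) intermediate, weakest on
sand. These parameters are a calibration of this surrogate, not a claim
about any other model.

The default data-unit selection keeps 3–5 nFK classes per soil type (35
total): all classes for the narrow-span types, while SL, sL and LC drop
the 50 mm class and L drops 50 and 90 mm — the poorest soils, which the
validation comparisons exclude anyway. The exact composition of the
historical 35-class selection is not recorded; this reconstruction is a
documented guess, configurable per run.

## Unit conversions and breeding trend (yield_units)

Silage-maize dry matter converts to statistics units as fresh mass at an
assumed 35 % dry-matter content (`dt fresh = t DM × 10 / 0.35`). Winter
cereal whole-plant dry matter converts to grain with the empirical
regression `grain = (DM × 10 + 51.377)/2.5188` (dt/ha); its positive
intercept makes extrapolation below ~4 t DM/ha meaningless, so inputs
below that window raise. The window's exact edges are a package choice —
the source regression's range is not published.

A model calibrated on recent cultivars over-predicts early-decade yields.
The breeding-trend deduction fits OLS observed ~ year and subtracts
`slope × (pivot − year)` from predictions before the pivot (default 2000,
after which no significant breeding gains are assumed). The slope is
fitted on pre-pivot years by default — fitting over the full window would
dilute the trend with the trendless post-pivot years; the window is
configurable (`fit_window="all"`). The deduction applies to winter cereals;
maize yields show no comparable trend and default to no deduction. If the
pivot precedes the whole series the function is the identity.

## Validation protocol (validation)

The adjustment factor is mean(observed)/mean(predicted), kept at full
precision internally and reported at two decimals; with the full-precision
factor mean(adjusted) ≡ mean(observed) algebraically. RMSE, the overall
percent error (100·RMSE/mean obs) and Willmott's 1981 index of agreement
are computed on observed vs adjusted by default; the basis is configurable
to raw predictions because published reports do not always state it.
Pearson's r is invariant under the (affine, positive) adjustment, so it is
always computed on the raw predictions. Degenerate inputs: identical
constant series give d = 1 by convention; correlation on a zero-variance
series is reported as NaN in the assembled report and raises when called
directly. Comparisons are pre-filtered on the simulated side: winter
cereals only on units with nFK > 90 mm, maize omitting only units below
40 mm — regional statistics do not cover soils a crop is not grown on.

On the packaged Hannover series the recomputed per-year error columns
match the printed ones to their one-decimal precision; seven printed wheat
"adjust" values (2000–2006) are internally inconsistent with
prediction × 0.80 and are shipped verbatim but excluded from the per-row
cross-check. The printed maize column means and RMSE/WIA footer values are
not exactly recoverable from the printed columns (their computation basis
is not stated); the acceptance suite therefore holds the factor,
correlations, footer wheat means and anomaly percentages to printed
precision, and the RMSE-derived statistics to properties and recomputed
values only.

## Potential mapping (potential_mapping)

Simulated unit yields are averaged over the mapping climate period
(default 1991–2007, configurable; the more recent half of the record is
more representative of current climate). Per (crop, soil type, region), a
least-squares polynomial of degree min(2, n−1) through the (nFK class,
mean yield) points serves as a pure interpolation curve; evaluation clamps
to the fitted nFK domain (no extrapolation, so no negative-x regime) and
floors at zero. Degree is capped at 2: the empirical yield–nFK relations
are single-bend (concave) curves, and higher degrees would oscillate
between 3–5 support points. Parcels receive their curve value at their
continuous nFK estimate, times the crop's adjustment factor (winter-cereal
factor reused for triticale and cup plant, which lack own statistics), and
a half-open lower-inclusive band label with default edges
{12, 14, 16, 17, 19} t DM/ha. The join preserves cardinality exactly;
unresolvable parcels carry a null potential and a reason code, and strict
mode fails above 10 % unresolved.

GeoJSON I/O is attribute-focused (json + shapely); geometries pass through
untouched and no CRS handling is attempted.

## Synthetic region (synthetic_data)

The generators emulate the statistical structure the pipeline assumes, as
pure functions of (config, seed) with independent substreams per product:

* **Soil map** — parcels uniform on a 100 × 100 km square; the soil-type
  mixture blends logistically (10 km scale) from a loam-dominated south to
  a sand-dominated north; Bodenzahl uniform within a plausible span per
  type; five west–east climate-region bands. Default 5,000 parcels (test
  speed); a 114,357-parcel preset exercises the full-scale join.
* **Daily climate** — seasonal sine through the region's monthly
  temperature normals plus AR(1) anomalies (φ = 0.8, σ = 1.6 °C) and a
  small west–east station offset; precipitation as Bernoulli wet days
  (p = 0.5) with gamma amounts (shape 0.8) whose expectation reproduces
  the monthly normals (May 56, June 65, July 67 mm, …).
* **Observed statistics** — gap_factor (default 0.75, the documented upper
  range of the field-vs-trial gap) times the engine's own regional mean in
  statistics units, minus a pre-pivot breeding deficit (0.9 dt/ha/yr) for
  the winter-cereal analogue, times lognormal noise (CV 0.07, chosen to
  mimic the year-to-year scatter of the real series).

What passing the synthetic tests shows: the pipeline's plumbing and the
estimators are correct — the planted gap is recovered within ±0.02 (30-seed
mean), the planted trend within twice its least-squares standard error, and
the north–south potential ordering emerges for every crop. What it does not
show: skill of the surrogate engine against real field data, spatially
correlated weather, real geomorphology, or soil-profile heterogeneity
(profiles are homogeneous by assumption).

## Problem sizes and determinism

Default test/acceptance sizes: 5,000 parcels (2,000 in shared test
fixtures), 175 data units × 27 years × up to 4 crops per engine run,
30 seeds for gap recovery, one full-scale (114,357-parcel) join in the
acceptance script. Identical inputs give bit-identical outputs everywhere;
all randomness flows through `numpy.random.default_rng` seeded from the
user-supplied seed.

## Known limitations

* The engine's demand proxy is temperature-linear; no radiation, humidity
  or wind terms, no phenology by thermal time, no CO₂ response, no
  pest/nutrient limitation.
* Monthly time steps hide within-month drought timing.
* The 35-class selection and the nFK-curve anchor placement are reasoned
  reconstructions, exposed as configuration.
* Band edges for mapping are prose-derived defaults, not survey-calibrated.
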