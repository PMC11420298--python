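# Methods

This note documents the models and procedures implemented in `airmob`, the
choices made where several reasonable designs exist, and what the synthetic
validation scenarios do and do not demonstrate about real mobile-monitoring
data.

## Setting and data model

The package analyses 1 Hz georeferenced pollutant observations collected by
an instrumented vehicle driving fixed urban routes during daytime sessions
(nominally 07:00–17:00, occasionally later). Six species are handled:
PM2.5 (µg/m³), NO and NO2 (ppb), O3 (µg/m³), CO and CO2 (ppm). Missing
values are explicit (NaN) and only ever increase through quality control —
no stage imputes data it does not have.

## Ingest and quality control

- **Detection limits.** Present values strictly below the limit of
  detection (LOD) are replaced by LOD/2, the standard censoring
  substitution. The substitution is idempotent and applied once at the 1-s
  resolution and again to 8-s rolling medians against the (lower) 8-s LOD.
  The LOD values shipped in `pollutants.DEFAULT_LODS` are plausible
  placeholders for a 1 Hz mobile platform, not instrument certificates;
  they are fully overridable via a YAML `LodTable`.
- **NOx conversion.** NO and NO2 in ppb are combined and expressed as NOx
  on the NO2 mass scale: (NO + NO2) × 1.9125 µg/m³ per ppb. The constant
  is the NO2 molar mass (46.0055 g/mol) over the ideal-gas molar volume at
  20 °C and 760 mmHg (24.055 L/mol); no temperature correction is applied.
  The pipeline applies this conversion at ingest so that all downstream
  NO2 statistics are on the same scale as the guideline thresholds.
- **Ozone cadence.** The O3 channel is natively slower (3 s); it is held
  forward onto the 1-s grid for up to one native period so all channels
  share a single time base. Longer gaps stay missing.
- **Duplicates.** Duplicate timestamps keep the first record, with a
  warning. Rows with unparseable time or coordinates are dropped and
  counted.

## Temporal aggregation

The "drive pass" unit is an 8-s right-aligned rolling window stepping at
the 1-s cadence, summarised by its median; the median of a short window is
unmoved by any single-sample spike (breakdown point of the median), which
is the reason this statistic is used for street-segment concentrations.
Windows never span session gaps longer than `max_gap_s` (default 60 s).

The hierarchy above segments is: clock-hour medians (hours with fewer than
`min_samples = 4` segments flagged incomplete), then per-date daytime
medians computed from the day's 8-s values (a switch allows computing them
from hourly medians instead; the default follows the finer-grained
reading). Ozone uses the maximum of the day's hourly medians instead of
the median, the daytime-campaign proxy for a short-term peak metric. Days
covering fewer than `min_hours = 3` hours are dropped. Both `min_samples`
and `min_hours` are pragmatic completeness floors, configurable.

Five-day moving averages are centred, computed on a contiguous date axis
with a minimum of 3 contributing days, so gaps in the campaign propagate
rather than being silently bridged. Diurnal profiles report per
hour-of-day quartiles with whiskers at the most extreme values within
1.5×IQR of the quartiles. All percentiles use linear interpolation between
closest ranks (numpy default); this is stated because percentile
conventions differ across software.

## Baseline extraction and source decomposition

Each pollutant's series is split as

    C_t(k, j) = C_bg(k, j) + C_lc(k, j),    P_lc(k, j) = C_lc / C_t,

on the hypothesis that the lowest values within a window are minimally
influenced by nearby plumes and therefore trace the regional/urban
background. Two baseline estimators are provided:

- **Running percentile** (default): the 5th percentile over a trailing 1-h
  window of drive-pass values. The percentile, window, and input
  resolution are configurable; the 5th percentile tolerates up to 5 %
  plume occupancy per window exactly (a property the tests exploit).
- **Block minima**: the per-block minimum of next-finer-block medians —
  per day, the minimum hourly median; per hour, the minimum 1-min median —
  assigned to block centres, linearly interpolated between them, and held
  constant beyond the first/last centre. This is the estimator used for
  the event-scale partition.

Baselines are clipped into [0, C_t]; P_lc is defined as 0 where C_t = 0.
The clipping convention attributes any apparent deficit to background
rather than allowing negative local contributions.

The local remainder is partitioned by time scale with a hierarchical
subtraction: background = daytime-scale baseline; longer-lived local
(persisting ~2–8 h) = hour-scale baseline − background; short-lived local
(sub-hour plumes) = total − hour-scale baseline. The baselines are ordered
by clipping (day ≤ hour ≤ total) before differencing, so the three
non-negative components sum to the total *exactly* at every timestamp —
conservation is enforced, not approximate. An optional third (1-min)
scale can be switched on to split sub-minute spikes from the short-lived
component; it is off by default.

Because published percentage contributions can be read either as time
means of the instantaneous fraction or as ratios of time means, and the
two differ whenever the local share covaries with the total,
`component_fractions` reports both conventions.

Known bias: a smoothly varying (non-constant) background passes through a
minimum- or low-percentile-based baseline with a downward bias of order
the within-window signal range. On a 24-h sinusoid this is a fraction of a
percent of the total for realistic amplitudes; it is the price of
robustness to one-sided (non-negative) plume contamination.

## Guideline exceedance

The registry holds WHO 2021 AQG and EU limit values at the metrics a
daytime mobile campaign can evaluate: the **daytime median stands in for
the 24-h averaging period** (there is no nighttime coverage — a documented
caveat, not an equivalence), and the daily maximum hourly value proxies
the ozone 8-h metric. Exceedance is strict (value > threshold); boundary
values comply. Percentages are reported alongside their integer counts and
are recomputed from them, never back-derived from rounded percentages.
High-pollution days — daytime PM2.5 > 15 µg/m³ or NO2 > 25 µg/m³ — are
ranked by NO2 descending and feed the hotspot stage.

## Hotspot analysis

Points are projected onto a locally centred equirectangular tangent plane
(x = R·Δλ·cos φ₀, y = R·Δφ). At city scale (≲20 km) the distortion of
this projection is far below one cell width, which is why a full
map-projection library is not needed. The fishnet is a regular grid of
square cells (default 100 m) aligned to the projected lattice; each cell's
analysis value is the mean of the segment concentrations that fall in it,
and cells with fewer than `min_count = 5` points keep their count but are
excluded from inference.

The self-inclusive Getis–Ord Gi* statistic is computed per analysed cell
with binary distance-band weights (default band 1.5 × cell size, i.e.
rook + corner neighbours plus self):

    Gi* = (Σⱼ wᵢⱼ xⱼ − x̄ Wᵢ) / ( S √[ (n Σⱼ wᵢⱼ² − Wᵢ²) / (n − 1) ] ),

with x̄ and S the global mean and population standard deviation over the n
analysed cells. Two-sided p-values come from the standard normal
approximation; if all cell values are equal the statistic is defined as 0
with p = 1 and flagged degenerate. p-values are Benjamini–Hochberg
adjusted across analysed cells (the false-discovery-rate correction
standard for many simultaneous local statistics), then binned:
|bin| = 3/2/1 for adjusted p < 0.01/0.05/0.10, signed by z — the familiar
99/95/90 % hot and cold categories.

Cell size, band distance, minimum count, alpha levels, and correction are
all configurable; the defaults are conventional street-scale choices, and
results are emitted as GeoJSON polygons (WGS84) plus a CSV twin.

## Synthetic scenario generator

The generator exists so every stage can be validated against known ground
truth without any external download. Per pollutant:

    observation = background + Σ plumes + instrument noise,

- **Route**: constant-speed motion along a waypoint polyline, reflecting
  at the ends, with a continuous odometer across 07:00–17:00 daily
  sessions at 1 Hz. The default route is a lawnmower sweep over a
  ~1 km × 1 km block grid, giving each 100-m cell repeated visits per day.
- **Background**: mean + diurnal cosine harmonics (two, at 24 h and 12 h,
  reproduce a bimodal rush-hour shape) + an annual cosine peaking
  mid-January (the heating season) + AR(1) noise stepped per sample,
  started from its stationary distribution, clipped at zero. Default mean
  levels (e.g. PM2.5 7 µg/m³, NO2 14 ppb, O3 46 µg/m³, CO2 440 ppm) are
  typical urban-background magnitudes for a northern European city.
- **Plumes**: Poisson arrivals (per-sample Bernoulli thinning, exact at
  rate·Δt ≪ 1) with lognormal amplitudes and instantaneous rise +
  exponential decay — the simplest shape consistent with
  seconds-to-minutes traffic spikes, and analytically checkable. An
  event is truncated once it has decayed below 1 % of its amplitude. A
  designated set of fishnet cells multiplies the arrival rate while the
  vehicle is inside ("hotspots"), and an optional 24-element hour-of-day
  profile modulates the rate (rush-hour schedules). The amplitude
  distribution is a modelling choice; nothing here claims real spike
  amplitudes are lognormal.
- **Censoring and missingness**: below-LOD values are emitted as drawn
  (the ingest stage owns the substitution — a single owner for LOD
  logic); missingness is iid per sample and pollutant at the configured
  fraction (default 0.3, inside the 20–40 % range typical of such
  campaigns).

Identical configuration (including seed) yields byte-identical output;
all randomness flows from one `SeedSequence` spawned per pollutant and
component.

What the generator does **not** emulate: meteorological dispersion and
wind sectors, street-canyon topology, instrument drift and
cross-sensitivities, correlated missingness (instrument dropouts), or
weekend/nighttime patterns. Passing tests therefore demonstrate the
*algorithms* recover known structure under the stated noise model, not
that any particular real-world campaign satisfies that model.

A physical note that matters for hotspot validation: plume decay acts on
the *sensor's* time axis, so with a 60-s decay a moving vehicle smears an
event over several hundred metres of track. Scenarios used to validate
spatial hotspot recovery use a 15-s decay — shorter than one 100-m cell
transit (12.5 s at 8 m/s) — so that event mass stays predominantly in its
source cell; this is a property of the validation design, not of the
detector.

## Problem sizes and numerical choices

- Validation scenarios are 1–3 simulated days (36 000 1-s samples per
  day), 10–20 seeds per property; these sizes give the binomial/Poisson
  checks 3σ resolution while keeping the whole suite fast.
- Decomposition conservation is asserted to 1e-9 absolute (achieved:
  ~1e-14, pure floating-point roundoff).
- Gi* is asserted against an independently coded from-the-formula
  evaluation to 1e-10 relative on grids up to 25 cells.
- Seeded-hotspot sensitivity uses a 2×2 hotspot block at 3× arrival rate
  over 2-day scenarios (≥50 in-block events); the neighbourhood of a
  seeded cell then contains several seeded cells, matching the clustered
  nature of real traffic hotspots and the cluster-detecting design of
  Gi*.
- The null false-positive check uses spatially uniform plume scenarios;
  the fraction of cells flagged at ≥95 % confidence is averaged across
  seeds (individual scenarios can legitimately contain chance spatial
  clusters, which Gi* correctly reports).
- Tie-breaks and conventions: percentiles by linear interpolation;
  fishnet cells are half-open (left/bottom inclusive) so every point lands
  in exactly one cell; duplicate timestamps keep the first record.

## Limitations

- The daytime median is not a 24-h mean; exceedance percentages against
  24-h guidelines inherit that caveat from the campaign design.
- The equirectangular projection is inappropriate for study areas
  spanning ≫100 km or high latitudes near the poles; swap in a proper
  projected CRS upstream if needed.
- Gi* p-values rest on the statistic's asymptotic normality and, after
  FDR adjustment, control the false discovery rate — they do not make the
  per-cell z-scores independent, and spatial dependence between
  neighbouring cells remains in the z field itself.
- The block-minima baseline is biased low on smoothly varying signals (see
  above); users comparing background estimates across methods should hold
  the estimator fixed.
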