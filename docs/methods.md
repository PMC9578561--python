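# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the known limitations of the package.

## The screening battery and its outcome measures

The battery scores each worm on five binary endpoints (lethality, abnormal
body shape, stickiness under standardized shaking, abnormal eye
regeneration, failure to scrunch under noxious heat) and eighteen continuous
endpoints (ten 30-s speed bins of the phototaxis assay, resting fraction,
phototaxis response, wall preference, locomotor-burst total and ratio,
thermotaxis fraction, and noxious-heat rate and strength).  Each endpoint is
assayed on day 7 and/or day 12 of exposure in adult and/or regenerating
worms and may be scored in one or both directions.  An *outcome measure* is
one (endpoint, day, direction) combination per worm type; the default
schema enumerates to exactly 70 adult and 71 regenerating measures (the
extra regenerating measure is eye regeneration, which has no adult
counterpart).  Binary endpoints are scored in the increasing direction
only: a chemical can only add abnormal incidence over the control rate, and
apparent decreases are within control variability.

## Behavioral endpoint extraction

Frame speed is the Euclidean displacement between consecutive *tracked*
frames divided by the elapsed time, assigned to the later timestamp; a
tracking gap contributes no sample, and an empty 30-s bin is a missing
value, never zero.  Bin means weight each tracked sample equally (frame
intervals are nominally uniform; irregular sampling is not reweighted).
The resting threshold is 0.2 mm/s with strict inequalities on both sides:
a frame exactly at 0.2 mm/s is neither resting nor moving and can neither
start nor complete a locomotor burst.  Burst detection considers only
adjacent samples (a gap larger than twice the modal frame interval resets
the below-threshold state) so tracking dropouts cannot fabricate
crossings.  Wall preference uses a rim annulus covering the outer 25% of
the well radius by default (about 44% of the well area) — wide enough to
capture wall-following without counting ordinary excursions; the fraction
is configurable.  The noxious-heat metrics operate on an externally
supplied displacement series: the rate is the least-squares slope over the
heating window and the strength the median displacement over a terminal
sub-window (default: the last quarter of the recording).

## Normalization

Continuous endpoints are normalized per plate against the median of that
plate's vehicle-control worms, using the endpoint's rule: subtract-and-
scale-by-100 (speed bins, resting, phototaxis, noxious rate), divide-
and-scale (wall preference, thermotaxis, noxious strength — endpoints whose
natural scale is a fraction of control), or plain subtraction for the
locomotor-burst endpoints, whose counts are left in natural units.  A plate
whose vehicle median is zero under a divide rule is unnormalizable for that
endpoint and dropped.  Binary endpoints pool affected/total counts across
replicates (n ≥ 24 per condition); stickiness and scrunching, whose control
response is variable, subtract the pooled in-plate vehicle incidence, and
negative rates are clamped to zero.  Behavioral values of worms dead on a
given day are missing, not zero — lethality is scored separately.

## Benchmark-response selection and benchmark concentrations

The analysis assumes a monotone concentration response.  Summary curves
(per-concentration medians for continuous measures, control-adjusted
incidence in percent for binary ones) are corrected by zeroing responses
opposite to the scored direction and then clipping top-down, i.e. replacing
each value by the minimum over itself and all higher concentrations.  This
suffix-minimum is the pointwise-largest non-decreasing curve dominated by
the observed magnitudes — the minimal conservative correction, in the sense
that no response is ever amplified and the total correction is smallest
among all monotone minorants.  The property is pinned by an exhaustive
oracle test on short grid curves.

The benchmark concentration at a threshold (BMR) is the first crossing of
the monotone curve with the threshold, interpolated linearly in log10
concentration.  A curve whose top response stays below the BMR is inactive;
a curve already at or above the BMR at the lowest tested concentration is
low-censored and reported at that concentration (BMCs are never
extrapolated outside the tested range).

The BMR itself is selected per outcome measure from the whole screen.  For
each candidate threshold (5…95 step 5 by default; step 1 and 0.5 for the
locomotor-burst total and ratio, whose response range is small; maximum 150
for the high-variance speed and resting endpoints), every chemical
contributes the variance of its log10 bootstrap BMCs (100 bootstrap
resamples of worms within concentration; chemicals with more than 50%
censored samples at that threshold are excluded, and thresholds retaining
fewer than half the maximum number of contributing chemicals are dropped —
near the response plateau only the few curves whose noise exceeds the
threshold still cross, and their variances are biased low by the squeeze
against the top tested concentration).  The per-threshold statistic is the
mean variance over contributing chemicals.  The recommended BMR is the
smallest threshold whose statistic has decayed to within 5% of the plateau,
where the plateau is the mean statistic of the three largest evaluable
thresholds and the 5% is measured against the decay amplitude; a flat
variance curve therefore recommends the smallest scanned threshold.  On a
screen with no genuinely active chemical the scan has nothing to calibrate
against and recommends floor-level thresholds — the same situation the
source workflow resolves with manual overrides, which are first-class here:
day-7 regenerating lethality is pinned to 10 and stickiness to 50 (2.5
control SD) by default, and arbitrary per-measure overrides, concentration
masks and replicate exclusions are declarative configuration.

The final BMC uses 1,000 bootstrap resamples at the selected BMR and is
reported as the median with 5th/95th percentiles of the non-censored log10
BMCs; a measure with more than 50% censored samples is inactive.  The
resampling unit is the individual worm within concentration for both
endpoint kinds (the worm is the experimental unit).  Child seeds for every
bootstrap are derived deterministically from the master seed and the
(worm type, measure, chemical) identity, so results are reproducible and
insensitive to the set of other chemicals analyzed.

On synthetic screens with Hill ground truth (plateau 100, slope 2, EC50
10 µM) at blue-light-speed noise (control SD 49 normalized units, 24 worms
per concentration), the selected BMRs land at 30–80 normalized units
(matching the 1–2 SD pattern of the battery's published thresholds), the
median absolute log10 error of the BMC against the analytic crossing
c* = EC50·(BMR/(Rmax−BMR))^(1/h) is below 0.1, and chemicals simulated
with no effect are scored inactive in ≥95% of runs.  These figures are
recomputed by `scripts/acceptance.py` and asserted by the test suite.

## Phenotypic barcodes and clustering

A barcode row is one chemical × concentration; a cell is active when the
pooled-across-replicates median normalized response (continuous) or pooled
incidence (binary) lies *strictly* beyond the measure's BMR (boundary
values are inactive; strictness is configurable).  This per-concentration
binarization deliberately ignores concentration-response shape — it is a
phenotypic pattern descriptor, not hit identification.  Rows with 100%
pooled lethality are removed first (to focus on sublethal phenotypes), then
all-inactive rows and columns are removed to a fixed point.  Clustering
uses Jaccard dissimilarity ("binary distance": 1 − |A∩B|/|A∪B| of the
active sets) with Ward's minimum-variance criterion in the ward.D2
convention (distances squared inside the criterion, merge heights on the
distance scale), computed via scipy's linkage and checked against an
independent Lance–Williams implementation in the tests.  Binary barcodes
produce many tied distances and agglomeration under ties depends on row
order, so rows are put in a canonical order (by barcode content, then row
id) before linkage; the partition is then invariant to input order.  The
cluster count (k = 6 in a full screen; smaller in the demonstration panel)
is configuration, not model selection.

Chemical-level summaries link a chemical to an endpoint class when any
member outcome measure has an active BMC on either assay day; dark-period
speed, resting and locomotor bursts pool into a single "Motility" class,
and the two noxious-heat measures into "Noxious stimuli".  Potency rankings
(e.g. most sensitive BMC vs IC80) are compared with Spearman's rho computed
from average ranks, with an exact permutation p-value for n ≤ 9 chemicals
and the asymptotic approximation above that.

## Ellman analysis

Enzyme activity is the slope of the best linear window of the kinetic
absorbance read — the longest window of at least 4 points with R² ≥ 0.98,
falling back to the full series — divided by the protein concentration;
negative slopes mean no measurable activity and are clipped to zero with a
warning.  Percent activity is 100 × rate / mean vehicle rate, with protein
normalization applied before technical-replicate averaging.  The
concentration-inhibition curve is the two-parameter log-logistic with
asymptotes fixed at 0 and 100, parameterized directly by (IC50, b) and fit
by least squares over (log10 IC50, log10 b) from a 15-point multi-start
grid, which makes IC_p = IC50·(p/(100−p))^(1/b) closed-form.  A fit whose
IC50 exceeds 10× the highest tested concentration carries no usable
inhibition signal and is flagged right-censored; an IC_p beyond the tested
range is flagged extrapolated.

## The synthetic-data model

The generator reproduces the screen design: 48-well plates with 8 vehicle
wells and 8 wells per concentration, 5 concentrations per plate (a
10-concentration chemical occupies two plates per worm type), at least 3
replicates, quarter-log (0.25 log10) or semi-log (0.5) dilution series
rounded to 3 significant figures, both worm types, days 7 and 12.
Continuous effects are Hill curves on the normalized scale added to an
endpoint-specific baseline and mapped back through the endpoint's
normalization rule; per-worm noise is Gaussian with SD pre-scaled by
1/0.958 so that the realized control SD *after* in-plate median
normalization (which shrinks vehicle-worm deviations, factor estimated by
Monte Carlo for n = 8) matches the configured battery value, verified
within 15% in the tests.  Binary effects are Bernoulli draws from a control
rate plus a Hill-shaped incidence increase; death is drawn once per worm
with a cumulative (non-decreasing across days) probability, and dead worms
emit no behavioral values from the day of death.  Trajectories are
persistent random walks in a circular well with per-frame resting, gamma-
distributed moving speeds calibrated so the overall mean frame speed equals
the requested value, an optional heading bias toward the rim
(wall affinity), and a multiplicative speed modulation during green/blue
light phases; steps that would leave the well slide along the wall,
preserving step length.  Ellman tables are log-logistic percent activities
plus Gaussian noise.

What the generator does not emulate — and what passing tests therefore do
not establish about real screens: non-Gaussian and temporally
autocorrelated behavior within worms, plate edge effects and batch drift
between replicates, fission events, partially tracked worms, body-shape
category structure (only a single abnormal/normal label), and any
pharmacokinetics linking nominal to internal dose.  Endpoint noise is
independent across endpoints and days, so the synthetic barcodes lack the
across-endpoint correlation structure real chemicals produce.

## Problem sizes

The test suite and acceptance script use 20 signal + 20 null chemicals at
24 worms per concentration for BMC recovery (100 selection / 1,000 final
bootstraps, as in the full procedure), 100 simulated inhibition experiments
for IC50/IC80 recovery, exhaustive monotonization checks on all signed grid
curves up to length 5, and 100–1,000 random matrices for the clustering
properties; the demonstration panel in `analysis/` runs four chemicals
through the complete two-worm-type, two-day battery with 500 final
bootstraps.  These sizes give stable statistics (the recovery medians move
by well under their tolerances across seeds) while keeping any single run
in seconds to a few minutes.

## Known limitations

The variance-plateau rule is this package's concrete instantiation of
"threshold where the bootstrap response stabilizes"; the cited curve-
correction software does not publish its exact criterion, so agreement is
structural (same scan grids, same bootstrap design, same reporting) rather
than numerical.  Low-censored BMCs are reported at the lowest tested
concentration by convention.  Non-monotonic concentration responses are
outside the model by construction: the monotonization flattens them, which
trades sensitivity for robustness to noise.  Barcode binarization inherits
the BMR table; with table (rather than scan) BMRs it is conservative for
endpoints whose realized noise is below the published SD.
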