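# Methods

This note documents the models, parameters, and design decisions behind
`mangrove-drivers`, and what the synthetic experiments do and do not
demonstrate about real satellite data.

## Loss detection model

The decision variable is the mean NDVI change relative to a reference
state. Per pixel:

- **Reference**: median NDVI over January 1998 – December 2001. A pixel
  needs at least `min_quality = 10` valid (cloud-free) observations in
  the reference window; otherwise it is excluded from the whole
  analysis. The quality rule applies to the reference window only;
  observation windows need just one valid observation.
- **Cumulative anomaly**: Σ_t (NDVI_t − median) over January 2001 –
  December 2016, skipping nulls; dividing by the observation count
  gives the mean change Δ̄. The identity Δ̄ · n_obs = cumulative holds
  exactly. The one-year overlap between the reference and observation
  windows (2001) is reproduced deliberately, as is the asymmetry that
  epoch windows start in 2000 while the full observation window starts
  in 2001.
- **Threshold**: loss ⇔ Δ̄ ≤ −0.2 (inclusive) inside the baseline
  mangrove mask. Inclusivity is a convention; the boundary case is
  tested explicitly. Detection is monotone in the threshold.
- **Epoch dating**: Δ̄ is recomputed per epoch window (2000–2005,
  2005–2010, 2010–2016, half-open, tiling the record) restricted to the
  full-window loss extent. A pixel is dated to the earliest epoch that
  crosses the threshold. A pixel detectable only over the full record
  falls back to the epoch with the most negative Δ̄ — this fallback is
  what guarantees the epoch masks partition the total loss mask, which
  re-thresholding alone cannot (a gradual decline can cross at full
  length but in no 5-year subset). NDVI is always recomputed from
  bands so QA masking is applied exactly once.

## Land cover classification

A 2014–2018 per-band median composite supplies the predictors. The
seven predictors are the standard literature index definitions — NDVI,
NDMI = (NIR−SWIR1)/(NIR+SWIR1), MNDWI = (Green−SWIR1)/(Green+SWIR1),
GCVI = NIR/Green − 1, ratio54 = SWIR1/NIR, ratio35 = Red/SWIR1 (names
in Landsat-5/7 band numbering), and a bare "surface reflectance" band
value. Which band the bare reflectance refers to is genuinely open; we
use NIR because it maximizes vegetation/water contrast, and it is
configurable. Division by zero yields a null, and a null in any
predictor nulls the whole feature vector, excluding the pixel from
training and prediction.

Training points expand to circular buffers of **area** one hectare
(radius √(10⁴/π) ≈ 56.42 m): a "radius of one hectare" is not
dimensionally meaningful, and a 1 ha disc is the only sensible reading.
Pixel membership is centre-in-disc (deterministic and easily checked by
a brute-force geometry oracle: a buffer captures 9–13 of the 30 m
pixels depending on where the point falls). Pixels claimed by
conflicting labels are dropped.

The classifier is a 200-tree random forest with library-default split
settings and a mandatory seed: with three well-separated spectral
classes, determinism matters more than hyperparameter tuning.
Out-of-bag accuracy is exposed on the fitted model. Prediction is
restricted to the loss mask.

## Driver attribution rules

Spectra cannot separate land *uses* that share land *cover* (an
aquaculture pond and coastal water are both water), so attribution uses
ancillary evidence through fixed per-class rule cascades,
first-match-wins:

| cover | rule order |
|---|---|
| water | ocean-connected → ER, else CM |
| wet soil | near agriculture (≤ 500 m) → CM; shoreline band (≤ 300 m) → ER; near infrastructure (≤ 1000 m) → NPC; else EWE |
| dry soil | near settlement/roads (≤ 500 m) → ST; near infrastructure (≤ 1000 m) → NPC; else EWE |

Ocean connectivity uses 8-connected component labelling against an
open-ocean seed region; proximity is centre-to-centre Euclidean
distance (an exact distance transform). Distances parametrize
"presence" of infrastructure because dieback patches sit near, not on,
roads; all five thresholds and the connectivity live in `RuleConfig`,
never in code, and are desk-scale stand-ins rather than claims about
operationally calibrated values. Unclassified cover becomes
`unattributed` (code 255) and is excluded from area accounting; a
per-stage pixel audit checks loss-in = attributed + unattributed.

Epoch driver maps are cuts of the single full-period map by each
epoch's loss extent — driver assignment is not regenerated per epoch,
on the assumption that post-conversion land use is stable over the
record.

## Accuracy assessment

Stratified (per mapped class) validation with proportional allocation
by largest-remainder rounding and a floor of one sample per class.
Estimators use area-weighted cell proportions p̂_ij = W_i n_ij / n_i·:
OA = Σ p̂_jj, UA_i = p̂_ii/p̂_i·, PA_j = p̂_jj/p̂_·j, reference-corrected
areas Â_j = A_tot Σ_i W_i n_ij/n_i·, with the standard stratified
variance estimators and fixed z = 1.96 for 95% intervals. Corrected
areas conserve the mapped total by construction. Raw count-based UA/PA
are exposed alongside, because published per-class accuracies are often
count-based; the count-pooled overall accuracy is what the acceptance
script reports against the published figure.

A class can be reference-only (zero mapped area, e.g. a driver the map
never assigns): it enters the matrix as a column with an empty row,
receives a corrected area and PA but no UA. Sampling only within the
mapped loss extent means loss *omission* is outside the design and is
not estimated — a limitation mirrored from the validation design this
package implements.

Desk-scale reference labels come from scene ground truth; where a
sampled pixel has no true driver (a false-positive loss pixel) the
mapped label is kept, mirroring an interpreter restricted to the
five-driver legend. An optional row-stochastic confusion matrix can
perturb reference labels; this drives the CI-coverage experiments,
where true class areas are known in closed form (A_true = Pᵀ A_map).

## Reporting conventions

Integer shares use round-half-away-from-zero. Percent declines return
full precision plus both truncated and rounded integer forms, because
published declines mix the two conventions; checks against published
integers use ±1 point. Epoch rates divide by the nominal epoch lengths
{5, 5, 6} years. Primary-driver ties break in the fixed order
ER < CM < ST < NPC < EWE. Region membership is pixel-centre-in-polygon;
overlapping region polygons are an error, and uncovered pixels report
under `unassigned`.

## Synthetic scenes

The generator emulates the *observational structure* of a Landsat
surface-reflectance archive, not its radiometry: monthly acquisitions
1998-01–2016-12 (228 dates — dense enough that the 10-observation
quality rule survives ~50% cloud), six reflective bands at 30 m,
per-pixel-date i.i.d. cloud gaps (default 30%), and i.i.d. Gaussian
band noise (σ = 0.02) truncated to [0, 1]. Class spectra come from one
editable endmember table chosen for separability: mangrove NDVI 0.75,
wet soil 0.15, dry soil 0.10, water −0.30. Every post-conversion class
therefore drops NDVI by at least 0.3 — a deliberate detectability
margin over the −0.2 threshold.

The default scene is 200 × 200 pixels: ocean strip, mangrove band,
inland zone with road, settlement and agriculture layers, and one 90 ha
conversion event per driver (450 ha total) placed so each driver's
diagnostic evidence holds by construction — erosion fronts carve inward
from the ocean edge (8-connected to ocean), commodity ponds are
enclosed, the settlement patch abuts the settlement block and is sized
to stay inside the 500 m buffer, dieback patches abut a road (NPC) or
sit beyond every infrastructure radius and the shoreline band (EWE).
Conversion dates (2003-01/2003-07, 2007-01/2007-06, 2010-07) spread
events across the three epochs while keeping each event's full-window
mean NDVI change below the −0.2 threshold; a conversion too late in the
record would be undetectable at full length no matter the method, which
is a property of the decision variable, not a flaw in it. Events are
quantized to whole pixels, so truth areas are exact; oversized or
overlapping events raise errors.

Default problem sizes (200 × 200 × 228 dates for the headline
experiments, 64 × 64 and smaller grids for unit tests) keep the full
suite and the acceptance script in the tens of seconds on one CPU.

What passing tests show: the pipeline recovers known conversions
exactly in the noise-free limit, and within a few percent under the
default noise/cloud regime, with estimator code that matches
first-principles formulas to 10⁻¹². What they do not show: skill on
real imagery — real scenes add phenology, tides, sensor differences,
spatially correlated clouds, mixed pixels and spectrally ambiguous
transitions that the generator intentionally omits (and the published
global accuracies of ~68–88% per class reflect exactly those
ambiguities).

## Known limitations

- Flat-grid geometry: pixel area is `pixel_size²` everywhere; no
  geodesic correction, projection, or CRS handling (rasters are plain
  TIFF with a JSON metadata sidecar, vectors GeoJSON in scene-local
  metre coordinates).
- No gain/regrowth mapping, no sub-epoch dating, no sensor
  harmonization, no atmospheric correction.
- Attribution thresholds are stand-ins; on real data they would need
  calibration against interpreted samples.
- The published global figures are used only as *inputs* to accounting
  arithmetic; desk-scale scenes cannot and do not reproduce
  archive-scale results.
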