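# Methods

This note documents the models, numerical choices and limitations of
the `forestchange` pipeline in enough detail to reproduce or audit its
behaviour.

## Time representation

All timestamps are decimal years, `year + day_of_year / 365.25`. The
annual cycle of the season-trend model is therefore `sin(2πt + δ)`
with no separate frequency parameter; a period printed in days would
be dimensionally inconsistent with a slope per year. Trend intercepts
are reported at the origin 1999.0, the first year of the assembled
satellite record, so intercepts are interpretable as "state at the
start of monitoring".

## Change-class definitions

Classes are defined on the canopy-cover dimension only. A disturbed
plot whose canopy fell below the 20% forest-definition threshold is
*deforestation* (DEF) regardless of the contiguous area cleared; a
disturbed plot still above the threshold is *degradation* (DEG); an
undisturbed forest plot is *no change* (NOCH) and a non-forest plot is
NONFOREST. An area-based degradation criterion (clearings below
0.5 ha) exists behind a disabled-by-default flag
(`ClassificationRules.area_rule_enabled`); it is off because canopy
condition, not area, is what ground photos can verify. Report
verification is modelled as an explicit overrides map with an audit
log — a human-in-the-loop step, not automated image analysis.

## Preprocessing

- **Sieve** (`apply_sieve`): connected clusters of *valid* pixels with
  ≤ 5 members are removed from each per-date validity mask. These are
  typically unmasked cloud remnants inside scan-line gaps. Connectivity
  is 4-neighbour, the conservative default of standard sieve filters;
  the cluster-size rule is inclusive (a 5-pixel cluster is removed, a
  6-pixel cluster kept). The operation is idempotent.
- **Indices**: normalized differences (NDVI, NDMI, NBR, NBR2) and
  tasseled-cap transforms. The packaged coefficient CSV carries the
  Crist (1985) surface-reflectance coefficients with columns ordered
  (B, R, G, NIR, SWIR1, SWIR2). The tasseled-cap angle is
  `arctan(TCB/TCG)` by default, matching the tabulated form used by
  the workflow this package operationalizes; the more common literature
  convention `arctan(TCG/TCB)` is available via
  `tca_literature_convention=True`. Zero denominators and masked
  pixels propagate as NaN.

## Temporal metrics

Per band, six covariates:

| metric | definition |
|---|---|
| `rlm_intercept`, `rlm_slope` | Huber M-estimator line fit to the full series, intercept at 1999.0 |
| `gamma1`, `gamma2` | seasonal amplitude per segment, γ = √(a² + b²) ≥ 0 |
| `beta1`, `beta2` | linear trend per segment |

**Robust fitting.** Huber loss with tuning constant 1.345 (95%
efficiency at the normal), scale estimated by median absolute
deviation, iteratively reweighted least squares to coefficient
tolerance 1e−8 or 50 iterations (statsmodels `RLM`). On noiseless data
the robust fit equals ordinary least squares to ≤ 1e−8 (tested). The
harmonic is fit linearly as `a·sin(2πt) + b·cos(2πt)`; amplitude and
phase are `hypot(a, b)` and `atan2(b, a)`, so γ ≥ 0 by construction
and δ ∈ (−π, π].

**Single-break detection.** At most one structural change per series
is assumed (reasonable for permanent-agriculture frontiers; wrong for
shifting cultivation with disturbance–recovery cycles). Candidate
split points are scanned exhaustively between minimum-segment bounds
of `max(ceil(0.15·n), 8)` observations — 15% is the customary minimum
segment of least-squares break estimation, and 8 is the parameter
count of two season-trend segments with slack. Each candidate is
scored by least-squares season-trend fits on both segments with
`BIC = n·ln(RSS/n) + k·ln(n)`, k = 9 for the one-break model (2 × 4
parameters + break position) against k = 4 without a break. The break
is accepted only if the best one-break BIC is *strictly* lower (ties
resolve to no break, by parsimony). Segments are then refit robustly
for the reported γ and β. The BIC scan deliberately uses least-squares
RSS, mirroring the standard break-estimation procedure, while the
reported segment parameters come from the robust refits. Series
shorter than twice the minimum segment return a degenerate no-break
result rather than an error.

**Full-series trend.** The overall RLM fit is a pure line (no
harmonic): its role is to summarize gradual change across the whole
record, and the seasonal signal is absorbed by the robust loss.

When no break is detected, `gamma2`/`beta2` duplicate
`gamma1`/`beta1`, keeping the metric vector a fixed length of
6 × n_bands (84 for the full 14-band set). Bands with too few
observations yield NaN metrics and are reported as missing.

## Change model

- 7000 trees by default (500 in desk-scale tests and importance
  iterations, where the OOB estimate is already stable); scikit-learn
  `RandomForestClassifier` with bootstrap and OOB scoring. Trees are
  grown to purity, so averaged leaf distributions equal the fraction
  of trees voting for each class — class probabilities are vote
  fractions.
- OOB errors: overall = 1 − OOB accuracy; per class from the OOB
  confusion-matrix rows. Rows with missing covariates are dropped
  before training with a logged count (forests need complete rows).
  Training requires ≥ 2 classes and ≥ 10 samples per present class.
- **Iterative updating**: the labelled report stream is split at two
  phase boundaries into periods A, B, C. Training phase: fit on A,
  predict held-out class probabilities for B. Operational phase: fit
  on A∪B, predict for C. Held-out locations are disjoint from the
  training rows, so full-forest prediction (not OOB) is used for the
  validation probabilities. An empty period C downgrades to a warning;
  empty A or B is an error.
- **Band importance**: per iteration, one forest per band is fit on
  that band's six metrics alone; bands are ranked by overall and by
  class-specific OOB accuracy (accuracy = 1 − OOB error; bottom
  rank 1, top rank n); ties break by canonical band order so results
  are seed-reproducible. The score is the mean normalized rank
  `S = mean((x − 1)/(n − 1)) ∈ [0, 1]`. Each iteration reseeds only
  the forests' bootstrap; rows are not resampled — the simplest
  reading of "repeat the algorithm N times". Default N = 1000
  (analytic benchmark); pipeline runs use configurable smaller N.
- **Reduced mapping model**: all six SWIR2 metrics, all six TCW
  metrics, and the green band's RLM intercept and slope (14 columns) —
  the covariate subset found most informative for change/no-change
  separation in the workflow this package reimplements.

## Mapping

The baseline forest mask thresholds the valid NDVI observation nearest
a baseline date (default threshold 0.6 for synthetic scenes, window
±1.5 yr); the mask source is pluggable, since operational masks come
from classified baseline imagery. Forest pixels get per-class
probabilities from the model; non-forest pixels and pixels with fewer
than `min_obs` (default 12) valid observations in any required band
are nodata in all classes, with a logged count. Pixels are processed
in fixed-size chunks purely as a memory contract — output is identical
for any chunk size (tested). Histogram summaries exclude nodata, so
per-class counts sum to the number of valid pixels.

## Synthetic data: what it emulates, what it does not

The generator draws per-pixel piecewise season-trend trajectories with
class-conditional spectra: forest reflectance means (e.g. NIR 0.35,
SWIR2 0.07) shift to cleared-surface means (NIR 0.25, SWIR2 0.20)
fully for DEF, partially (35–60% of the distance, with a mild
continuing trend) for DEG, and not at all for NOCH/NONFOREST. Break
times are uniform over the middle 60% of the window; phases are
per-pixel and shared across bands. Defaults describe a 16-year record
(1999–2015) at a nominal 16-day revisit with 30% dropout, Gaussian
noise of 0.01 reflectance units and 5% cloud-like outliers of 0.1 —
one-sided per band (positive in the visible/SWIR, negative in NIR), as
unmasked cloud contaminates real records. Desk-scale test scenes use
24–60 dates, which corresponds to a sparser-than-archive record; the
per-series statistical tests use ~250–300 observations, matching a
full archive.

Expert reports sample change pixels without replacement, weighted by a
logistic east–west accessibility gradient (purposive sampling; a
uniform flag exists). Classes are interleaved evenly along the stream
so that every monitoring period contains all classes — the premise of
a continuous monitoring programme, and a precondition of phase-wise
training. Canopy-cover attributes are drawn consistently with the
label so the report-labelling rule reproduces the truth; a label-noise
parameter flips a configurable fraction of labels.

Not emulated: radiative-transfer realism, spatial autocorrelation
beyond the accessibility gradient, multi-break histories,
cross-sensor radiometric differences, and geolocation error. Passing
tests therefore demonstrate the statistical machinery (robust fitting,
segmentation, ranking, phase protocol) under the assumed data
structure — not performance on any real archive, where class
separability is far weaker. The separation between class spectra is
deliberately strong so that failures indicate implementation defects
rather than statistical noise; the magnitude split between DEG and DEF
is exposed as parameters (`deg_fraction`, class spectra) rather than
fixed, because no reflectance-scale definition of that boundary
exists.

## Problem sizes and determinism

Test and benchmark sizes (20×20 scenes, 36–60 dates, 120–150 reports,
200-replicate simulations, 500-tree forests) are chosen so the whole
suite runs in a couple of minutes on one CPU while keeping Monte-Carlo
margins wide; all generators and forests take explicit seeds, and
fixed seeds give bit-identical output. Hypothesis-based property tests
run derandomized.

## Known limitations

- Change *timing* is deliberately not estimated; report timestamps and
  satellite-visible change dates disagree systematically in ground
  truth of this kind, so only the thematic dimension is modelled.
- The BIC scan is O(n · candidates) per series per band; wall-to-wall
  mapping over full scenes is why the reduced covariate set exists.
- The OOB error of a purposively sampled training set is not a design-
  based accuracy estimate; it measures internal consistency only.
- Raster I/O uses plain TIFF with a CSV manifest; no geo-referencing
  or CRS handling is included.
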