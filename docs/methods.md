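# Methods

This note documents the statistical procedures implemented in `gazesat`,
the modelling choices behind them, and what the synthetic-data tests do and
do not establish about real gaze data.

## Distribution maps and their transforms

A distribution map is a dense grid over the stimulus in which cell
`(⌊y/d⌋, ⌊x/d⌋)` counts the gaze samples or fixations landing there;
`d` is an integer *downscale* factor (default 1). Downscaling trades
spatial resolution for speed — at `d = 10` a 1920×1080 stimulus becomes a
108×192 grid and a full bootstrap run takes seconds rather than hours.
Every degree↔pixel conversion accounts for `d`; analyses at different
downscales are not mixed (the similarity functions reject mismatched
frames).

Three transforms are applied in a fixed order:

* **Gaussian blur** with σ expressed in degrees of visual angle and
  converted via the geometry's pixels-per-degree; the kernel is truncated
  at 4 σ and the grid is padded with nearest-edge values so that border
  gaze is not penalised by mass leaking off the stimulus. The default
  σ = 1° corresponds to ≈ 45 px at a typical 45 px/° viewing geometry; the
  package always uses the exact pixels-per-degree of the supplied
  geometry rather than a rounded kernel size.
* **Standardisation** (z-scoring) over all pixels using the *population*
  standard deviation — this is a map-wide normalisation, not an inference
  about pixels, so no degrees-of-freedom correction applies. A constant
  map has no z-scale and maps to the all-zero grid with a warning.
* **Min–max scaling** to [0, 1]; a constant map maps to all 0.5 with a
  warning.

Blur and standardisation do not commute; the pipeline blurs first and the
test suite pins the order with a non-commutativity check.

## Similarity metrics

Both metrics compare a raw *comparison* count map against a raw
*benchmark* count map on the same grid.

**NSS.** The comparison map is blurred then z-scored. The benchmark map is
z-scored but *not* blurred, and acts as a mask: NSS is the mean comparison
z-value over pixels where the benchmark z ≥ 0. The threshold is inclusive —
pixels exactly at the benchmark mean belong to the mask. NSS is unbounded
above; 0 is chance level (a z-scored map has mean 0 over any full-grid
mask, so a constant benchmark — whose fallback z-map is all zeros — yields
NSS = 0 identically). This is the mask-based variant of NSS appropriate
for map-to-map comparison; the classic fixation-list variant evaluates the
z-scored map at discrete fixation points instead, and the two agree only
in the limit of one mask pixel per fixation.

**AUC.** Benchmark z ≥ 0 defines binary labels (same inclusive threshold);
the blurred, min–max-scaled comparison map defines predictions; the score
is the area under the ROC curve computed over *every* pixel of the grid by
the rank-based Mann–Whitney formula with average ranks for ties. No
negative subsampling is used: full-grid evaluation is deterministic and
cheap at working resolutions. Constant predictions (all ties) score
exactly 0.5; one-sided labels raise an error naming the degenerate side.
Both metrics are invariant to positive rescaling of either raw map, since
z-scoring and min–max scaling absorb scale.

## Leave-n-out bootstrap saturation curves

For sample sizes `n` in a configurable grid (dense up to 50, then century
steps, capped at ⌊N/2⌋), each bootstrap iteration draws `n` participants
uniformly without replacement, pools their points into the comparison map,
then draws a **benchmark of fixed size ⌈N/2⌉** from the non-sampled
remainder and pools it into the benchmark map. Holding the benchmark size
constant across `n` is deliberate: it keeps the reference standard equally
informative at every sample size, so the curve isolates the effect of the
sample. The alternative — benchmark = all N − n non-sampled participants —
makes the benchmark itself degrade as `n` grows; at desk scale (N = 200,
n = 64) that degradation visibly outweighs the sample's improvement and
bends the mean AUC curve downward, an artifact of the design rather than a
property of the data. At the largest admissible `n = ⌊N/2⌋` the two
definitions coincide (the benchmark is exactly the remaining half). The
⌊N/2⌋ cap guarantees a disjoint half is always available.

Within an iteration sampling is without replacement; iterations are
independent redraws. Participants are always processed in sorted-id order
and all randomness flows from a single seed, so curve statistics are
invariant to the order in which participants are supplied, and identical
seeds give bit-identical outputs.

The engine never convolves inside the bootstrap loop: the Gaussian blur is
linear, so each participant's map is pre-blurred once and the blurred
pooled map of any subset is the sum of pre-blurred maps. Each iteration
then costs only array sums and one ranking pass.

**Multi-image studies.** When the same observers viewed several images,
each iteration applies the *same* sampled participant ids to every image
(scored against that image's own benchmark draw) and averages the metric
across images; a category mapping can restrict the image set to one
stratum. Whether to pool fixations across images or average per-image
scores is genuinely open; per-image-then-average was chosen because it
weights images equally and mirrors how multi-image datasets report
observer counts per image.

**Derived tables.** Curves are summarised by the bootstrap mean and the
2.5th/97.5th percentiles (the 95% range). The percentage-change curve is
computed on bootstrap means for consecutive `n` (per-iteration changes are
available but not the default, since the mean change with a separate
dispersion band is the more stable summary). The threshold table scans the
means greedily: starting from the smallest `n`, each next row is the
smallest `n` whose mean is ≥ (1 + r) times the previous row's (default
r = 0.05); exhaustion is recorded as "> n_max". Cross-reference matrices
tabulate the relative change between arbitrary sample-size pairs. Table
values are rounded to 2 decimals for display; underlying CSVs keep full
precision. Threshold comparisons carry a 1 × 10⁻¹² relative slack so that
boundary cases that are exact in real arithmetic (e.g. strictly geometric
curves) are not decided by floating-point rounding.

## AOI metrics and variance curves

Areas of interest are simple polygons in pixel coordinates; point-in-AOI
tests are boundary-inclusive so fixations on an edge are classified
deterministically. A *visit* is a maximal run of consecutive in-AOI
fixations — a single intervening out-fixation splits visits; no time-gap
criterion is applied. Five per-participant metrics follow: visit count,
percentage of fixations inside, time to first fixation (missing when the
AOI is never fixated), dwell per visit (total dwell / visits, missing when
there are no visits), and total dwell. AOIs whose minimum-rotated-
rectangle minor axis falls below 2.2° trigger a size warning, following
standard recommendations that AOI size scale with eye-tracker accuracy.

The variance analysis subsamples `n` participants per iteration, takes the
across-participant mean of a metric — participants with missing values are
excluded pairwise from that mean, and the exclusion count is recorded so
the treatment of never-fixating observers is auditable — and reports the
95% range of those means across iterations. Because draws are without
replacement, the range collapses to exactly 0 at `n = N`, and its decay
with `n` follows √((1 − (n−1)/(N−1))/n): the familiar 1/√n CLT shrinkage
multiplied by a finite-population correction that matters once `n` is an
appreciable fraction of N. The variance-reduction table applies the same
greedy scan as the threshold table, downward on the 95% range (default
25% steps).

## Synthetic observers

The generator exists so that every stage of the pipeline is testable
without any data download. Each participant's fixation locations are drawn
from a three-part mixture:

| component | default weight (single-image / multi-image profile) | what it emulates |
|---|---|---|
| shared hotspots | 0.45 / 0.60 | image-driven (bottom-up) attention common to all observers |
| idiosyncratic hotspots | 0.40 / 0.20 | observer-specific interests; the source of inter-observer variability |
| centre bias | 0.15 / 0.20 | the central-fixation tendency of screen viewing |

Shared hotspots are fixed Gaussian attractors (per-image randomised in
multi-image sets); idiosyncratic hotspots (3 and 2 per observer in the two
profiles, σ = 2°) are drawn once per participant, uniformly over the
central 80% of the stimulus to avoid edge artifacts; the centre bias is a
Gaussian at the screen centre with σ = 4°, a mid-range value for
free viewing of feature-rich scenes. Fixation durations are normal
(mean 250 ms, sd 100 ms) truncated at 50 ms and fill the viewing time
exactly (the final fixation is clipped), so a 10-s view at 60 Hz expands
to exactly 600 samples. Locations are clipped (not rejected) at the
stimulus border to preserve fixation counts. The two profiles' geometry,
sampling rate, viewing time and precision (1920×1080 at 38.4 px/°, 60 Hz,
10 s, RMS-S2S 0.41°; 1280×960 at ≈45.7 px/°, 500 Hz, 5 s, RMS-S2S 0.006°)
are fixed by the study designs they emulate; the mixture weights are
modelling choices — the single-image profile gets the higher idiosyncratic
weight to reproduce the high inter-observer variability of an unsupervised,
demographically diverse observer pool. They are stated here once and not
tuned per analysis.

**Noise calibration.** Raw samples are the active fixation's location plus
iid isotropic Gaussian jitter. For per-axis sd *s*, the squared
displacement between consecutive samples is 2s²·χ²₂ with median 4s²·ln 2,
so the root-median displacement is 2s√(ln 2) and the jitter that realises
a target RMS-S2S of *r* degrees is s = r·px_per_deg/(2√(ln 2)) pixels
(constant ≈ 0.6006, verified numerically in the test suite). Measured over
a full recording, the RMS-S2S statistic also sees the ≈7% of sample pairs
that straddle fixation boundaries, which inflates it ~5% above the
within-fixation target; real recordings contain the same contamination,
which is why the statistic uses the median in the first place.

**Seeding.** A single global seed feeds hierarchical per-participant
streams keyed by participant index, so enlarging a population never
changes earlier participants' data — a prerequisite for stable leave-n-out
comparisons across sample sizes.

**What the generator does not emulate:** saccade trajectories (samples
jump between fixations), blinks and tracking loss, pupil data, temporal
order effects (the mixture is exchangeable over a view), and any
systematic relation between observer demographics and gaze. Tests passing
on synthetic data therefore validate the *machinery* — map construction,
metric arithmetic, bootstrap logic, table scans, reproducibility — and the
qualitative saturation phenomena, not the specific guideline numbers a
real dataset would produce; those depend on the dataset's own
inter-observer variability.

## Problem sizes used in the test suite

The suite exercises the pipeline at deliberately modest scales chosen as
the smallest that cleanly exhibit each property: saturation shape on a
200-observer single-image population (downscale 10, 200 bootstrap
iterations, n up to 64); CLT/finite-population scaling of AOI dispersion
on 1000 observers (1000 iterations); oracle equivalence on 4×4 grids
(100 random instances against independent brute-force reimplementations);
and end-to-end CLI runs on 10–16 observers. Bootstrap repetition counts
for production use default to 1000, matching common practice for stable
95% ranges.

## Known limitations

* The mask-based NSS differs from the fixation-list NSS of the wider
  saliency literature (documented above); values are comparable within
  this package, not across variants.
* Full-grid AUC treats pixels as exchangeable units; spatial
  autocorrelation introduced by blurring means the grid's effective sample
  size is smaller than its pixel count, so AUC differences should be
  interpreted via the bootstrap ranges, not parametric standard errors.
* Guideline tables scan bootstrap *means*; with few iterations the greedy
  scan can be sensitive to Monte-Carlo error near a threshold.
* The AOI analysis assumes fixations are already classified; no event
  detection is performed.
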