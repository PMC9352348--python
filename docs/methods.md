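# Methods

This note documents the models and procedures implemented in `astroca`,
the parameters that matter, and the choices made where the design was
genuinely open.

## Scientific setting

Astrocytes in awake-behaving mice produce large, near-synchronous Ca²⁺
transients during locomotion and startle, driven mainly by noradrenergic
arousal. The pipeline quantifies this signaling from two-photon GCaMP6f
movies (30 Hz, 512×512 pixels at 0.42 or 0.67 µm/pixel in vivo; smaller
frames in tests) recorded from head-fixed mice on a running wheel, with
simultaneous wheel-encoder, pupil-video and — in a subset of experiments —
norepinephrine-sensor (GRAB_NE) recordings, and relates the responses to
genotype (amyloid-bearing transgenics, TG, vs. wildtype littermates, WT)
and to arousal measured through pupil dilation.

## Event-based Ca²⁺ detection (ROA method)

A region of activity (ROA) is a connected set of supra-threshold
(x, y, t) voxels. Detection proceeds:

1. **Variance stabilization.** Element-wise square root, making
   Poisson-like photon noise approximately homoscedastic.
2. **Smoothing.** Separable boxcar means: 14 frames temporally (~0.47 s at
   30 Hz) and a 5×5 pixel square spatially (half-width 2). These fixed
   widths were chosen for a signal-to-noise ratio of roughly 9 and are not
   adapted at run time. Boundary windows are renormalized over the samples
   that exist, so constant movies stay constant. The boxcar is the
   simplest reading of "smoothed with 14 frames and two pixels"; it is a
   parameter, not a commitment.
3. **Thresholding.** Per pixel: threshold = temporal median of the
   smoothed trace (the baseline) + *k* × noise scale, *k* = 4. The noise
   scale is the median across pixels of the per-pixel temporal sample SD —
   one global scale added to per-pixel baselines. A per-pixel SD mode is
   provided (`per_pixel_sigma`) because "median standard deviation" admits
   both readings. The median baseline is robust to sparse events.
4. **Binarization.** Strictly greater than threshold; a voxel exactly at
   threshold is inactive (deterministic tie-break).
5. **Labeling.** Connected components on the (x, y, t) grid,
   26-connectivity by default (the most permissive reading of "adjoining
   in space and time"); 6 and 18 are options.
6. **Filtering.** Two independent exclusion rules: events shorter than 3
   frames, or whose *maximum single-frame area* is below 3 pixels, are
   removed. Thresholds are inclusive: a 3-frame, 3-pixel event is kept.
   "Spatial extent per frame" is read as the largest single-frame area.

Derived traces: **ROA density** is the percent of a compartment's pixels
active per frame (compartments — soma, process, endfoot, or the full
field of view — come from a label image supplied as input; the FOV is all
labeled pixels). **ROA frequency** is events whose onset falls in a
window and whose voxels touch the region, per 100 µm² per minute; the
normalization is declared in output headers because no canonical unit
exists. Coordinates are 0-based; epochs are half-open `[t0, t1)`; frame
`f` maps to time `f/fps`.

## Behavioral-state segmentation

From the wheel-encoder speed trace (forward positive):

* **Run**: maximal contiguous segment with forward speed > 30°/s, ≥ 4 s,
  with no movement (either direction) above 20°/s in the 10 s before the
  segment start, and not starting within 30 s after an air puff.
* **Quiet wakefulness**: maximal segment with |speed| < 2°/s, ≥ 10 s,
  preceded by 15 s with no movement above 2°/s, same puff exclusion.
* **Startle**: 600 frames (~20 s at 30 Hz) from the air puff (at 150 s of
  a 300 s trial; 10 puffs at 10 Hz in vivo), truncated with a warning at
  trial end. Trials with a run overlapping the 10 s before the puff are
  invalid; the 10 s lookback mirrors the run criterion because
  "immediately before" has no canonical duration, and is recorded in
  output metadata.

At the trial start the required lookback may not exist; an epoch start is
clamped so the full lookback is sampled (an all-still trial is quiet from
15 s on). This conservative rule avoids spurious trial-edge epochs. The
forward-speed threshold applies to signed speed; disqualifying movement
uses absolute speed. Maximum speed within an epoch is max |speed|.

## Pupil dilation

The pupil/eye diameter ratio removes camera-geometry scale. Dilation at
an event (puff or run onset) is (mean after − mean before)/mean before
over 6.67 s windows on each side, means taken over the native pupil
samples with no interpolation (pupil video is coarser than the movie);
the event sample belongs to the "after" window. A side with no defined
sample yields a missing value and the trial is dropped from pupil models.

## Norepinephrine (GRAB_NE) change

Raw traces are converted to dF/F₀ with F₀ the per-trace 10th percentile
(configurable; the percentile baseline is robust to responses), then
downsampled from ~30 Hz to ~5 Hz by non-overlapping 6-frame bin means.
The response is median dF/F₀ during the epoch minus the median over the
10 s immediately before it — signed so responses are positive, which
matches the direction of the reported effects. Vascular-dip correction is
a pass-through hook; no algorithm is shipped.

## Plaque distances

Methoxy-X04 z-stacks (5 µm steps) are binarized at a user-set threshold
(the threshold is manual in practice and therefore a required input),
specks smaller than 27 voxels (≈ one 3×3×3 block; the size is otherwise
unstated) are removed with 26-connectivity, and each ROI centroid gets
the 3-D Euclidean distance to the nearest plaque voxel *center* — a
point-to-point formula, not a surface distance. The imaging plane's
z-offset within the volume is an input (alignment is manual upstream).
The distance–activity relation is a mixed model: mean ROA density per ROI
with a fixed distance effect and a random intercept and slope per episode
(statsmodels MixedLM, REML; distance rescaled to 100 µm internally for
conditioning, slope reported per µm). Singular fits are flagged, not
dropped.

## Trial-level mixed models

Response (rise rate, max/mean density, or NE change) ~ genotype +
µm/pixel + depth + max speed [+ pupil + pupil×genotype], with a random
intercept per mouse. TG is the reference genotype, so the intercept is
the TG mean and the genotype coefficient the WT offset; µm/pixel is a
binary indicator when only two magnifications occur. The **rise rate** is
the maximal density increase between two frames at most 50 frames apart
within the epoch (a windowed maximum acceleration; negative for
decreasing traces). Trials with several runs contribute their median.

Estimation is REML with the 2–3 variance parameters profiled numerically
(Nelder-Mead on log variances); because each mouse has one genotype the
marginal covariance is block diagonal with exchangeable blocks
σ_g²I + σ_mouse²11′, handled in closed form. Where residual plots
indicate heteroscedasticity — operationalized as a per-genotype residual
SD ratio above 1.5, a deliberately simple trigger — the residual variance
is allowed to differ by genotype. p-values are two-sided t with
df = n_obs − n_fixed − n_mice + 1, a conservative containment
approximation chosen because mixed-model df conventions vary between
packages; the df rule is isolated and swappable. No multiple-comparison
adjustment is applied anywhere, and no adjusted-p field exists. The WT
pupil slope is the TG slope plus the interaction, reported at two
significant figures. Robustness checks refit after deleting each mouse or
trial in turn, skipping (with a warning) deletions that leave a genotype
with fewer than two mice.

Hierarchical summaries take medians per trial, then per mouse, then per
genotype (midpoint convention for even counts) — the three levels of the
hierarchical plots.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the pipeline
consumes, not the biology:

* **Movies**: constant baseline (default 100) + GCaMP6f-like transients
  (difference of exponentials, rise 0.1 s, decay 0.6 s — no kernel is
  canonical, any supra-threshold transient suffices) on disk-shaped
  patches (radius 3 px), + i.i.d. Gaussian noise (default SD 1), clipped
  at 0. Gaussian noise is used because the detector operates after
  variance stabilization, where photon noise is approximately Gaussian
  with constant variance; a Poisson mode would add realism but not change
  what the tests probe. Ground-truth membership is the half-amplitude
  rule, and the kernel is truncated at that same level so an implanted
  event's support *is* its ground truth: with an unbounded exponential
  tail, "the set of voxels above half amplitude" and "the set of voxels a
  zero-noise threshold marks active" diverge and voxel-level
  recall/precision lose meaning. Noiseless recovery runs therefore use no
  smoothing (smoothing is noise suppression; on a noiseless movie it only
  blurs the event boundary). Events are placed with disjoint padded
  space-time footprints.
* **Behavior**: piecewise-constant wheel traces with requested runs;
  speeds in tests straddle the 2/20/30°/s thresholds.
* **Pupil**: baseline ratio 0.30 with exponential-decay dilation
  responses (τ = 4 s) at epoch onsets, amplitude = coupling × arousal +
  noise, sampled at 7.5 Hz (coarser than the movie, as in practice).
* **Cohorts**: the mixed model run generatively. Default coefficients
  follow the published running-trial model for ROA density rise rate
  (interaction 1.1562, genotype −0.1245, …, depth per µm); covariates are
  drawn uniformly from the recording regime — depth 20–200 µm, µm/pixel ∈
  {0.42, 0.67}, pupil dilation 0–0.6, max speed 30–90°/s. These ranges
  are assumptions (no distributional description of the real covariates
  exists) and are flagged as such. Variance defaults: σ_mouse = 0.05,
  σ_resid = 0.10 per genotype — chosen so trial responses span a
  realistic 0–0.7 %/epoch range.
* **Plaques**: rasterized spheres on the (µm/pixel, µm/pixel, 5 µm) grid.

No astrocyte morphology, vasculature, motion artifacts, or amyloid
biology is simulated. Consequently, passing tests demonstrate that the
algorithms implement their definitions and recover known structure at
realistic noise and sample sizes — not that the defaults are optimal for
any particular real recording.

## Numerical choices and degenerate inputs

* Strict `>` at the detection threshold; ties inactive.
* Sample SD (ddof = 1) for noise estimation; ≥ 3 frames required.
* Median = midpoint of central order statistics throughout.
* Epochs shorter than 2 frames cannot yield a rise rate (error); empty
  regions, zero-length windows, non-uniform wheel traces, and negative
  fluorescence are rejected with named errors.
* REML variances are optimized on the log scale (no boundary issues);
  with zero simulated noise the fixed effects still solve exactly via GLS.
* A truncated NE baseline or a missing pupil window yields NaN, and such
  trials are dropped downstream rather than imputed.

## Problem sizes used in the shipped checks

Synthetic movies in tests are 128×128 at 30 Hz, 20–40 s — a crop of the
in-vivo geometry that keeps full-movie detection runs to seconds while
preserving every algorithmic code path. Cohort recovery runs use the
published pupil-model scale (44 episodes, 10 mice) with 200 seeded
replicates for CI coverage and type-I calibration; oracle equivalence
suites use ~1000 random masks (≤ 6³), ~500 random 300 s wheel traces, and
~1000 random density traces.

## Known limitations

* Movement correction is out of scope; movies are assumed registered.
* Compartment masks are inputs; no automatic soma/process segmentation.
* The ROA-frequency unit is a declared convention, not a reproduction.
* The heteroscedasticity trigger (SD ratio 1.5) and the df approximation
  are pragmatic choices; both are exposed as parameters.
* The cohort generator draws covariates independently; real covariates
  (depth, magnification, speed) are correlated within mice.
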