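# Methods

This note documents the models, estimators, defaults and numerical choices
behind `smtirf`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Synthetic acquisition model

**Geometry.** Movies are simulated on a pixel grid of 0.16 µm pitch with a
Gaussian point-spread function of width σ = 1.0 px, so one emitter spans
roughly 5×5 px. Fixed-cell photobleaching movies default to 400 frames at
100 ms/frame; live-cell tracking series to 300 frames at 10 Hz. A position
is continuous in µm; the centre of pixel (i, j) is ((j+0.5)·p, (i+0.5)·p)
with p the pixel size, so pixel-index coordinates are x_px = x_µm/p − 0.5.
This convention makes localization round-trips exact.

**Oligomers and bleaching.** A spot is a k-mer (k = 1..4) drawn from a
mixture; each of its fluorophores contributes an independent 2-D Gaussian of
peak amplitude `unit_intensity` (default 200 counts) and bleaches
memorylessly with per-frame hazard `bleach_rate`. Bleach times are geometric
(support 1, 2, …), truncated at the movie length; a fluorophore with bleach
time T emits in frames f < T. No blinking or recovery is modelled by
default. The default hazard of 0.01/frame was chosen once by balancing the
two failure channels of step counting in a 400-frame movie: a higher rate
makes near-simultaneous bleaches (unresolvable as separate steps) more
common, a lower rate leaves more fluorophores unbleached at the end of the
movie (a k-mer then shows k−1 steps). Around 0.01 the total unresolvable
fraction for tetramers is minimal.

**Motion.** Free motion is a 2-D Brownian walk with per-axis step variance
2·D·δt. Confined motion reflects the walk radially at a circular boundary of
radius R around the start; each frame interval is internally subdivided so
the sub-step standard deviation stays below R/5, because radial reflection
is only accurate for small steps (without subdivision the stationary
distribution is biased inward and the MSD plateau falls ~12% short of its
analytic value R²). Immobile particles sit at their start position.
Independent Gaussian localization jitter (`localization_noise_sd`, µm) is
added to all modes; it is the only displacement an immobile particle shows.

**Camera noise.** Photon shot noise is Poisson on signal plus background;
EM multiplication is approximated by inflating the Poisson variance by
`em_gain_factor` (default 2, the standard EMCCD excess-noise factor),
implemented as g·Poisson(µ/g) which preserves the mean. Gaussian read noise
may be added. `NoiseModel.for_snr(snr, amplitude)` chooses a background
level whose noise sd equals amplitude/snr, which is how the "SNR 5"
validation fields are defined. No illumination inhomogeneity, drift,
aberrations or fixed-pattern noise is modelled.

**Spot placement.** Spots are scattered with a hard-core minimum separation
of 0.64 µm (4 px) by default. This models the experimental practice of
selecting well-dispersed fields below 0.25 spots/µm²: two emitters much
closer than the diffraction limit are one spot to any detector, and the
downstream analysis excludes sub-4-px pairs anyway. Spot counts at a given
density remain Poisson. Pure Poisson placement is available by setting the
separation to zero.

## Detection

Background is removed per frame with the rolling-ball algorithm (radius
12 px by default; the detected spot count is insensitive to the choice of
12 vs 15 px — covered by a test). For stoichiometry the first
five background-subtracted frames are averaged before seeding. Seeds are
local maxima of a matched-filtered (σ = 1 px Gaussian-smoothed) image more
than 4 robust standard deviations above the median; each seed is fitted
with an elliptical 2-D Gaussian (amplitude, centre, wx, wy, offset) by
bounded least squares on a 5×5 window of the unsmoothed image. A spot's SNR
is its fitted amplitude over the robust (MAD-based) standard deviation of
the fit residuals; eccentricity is max(wx, wy)/min(wx, wy). Fits that fail
to converge or return non-positive amplitude raise a typed rejection and
are counted, never silently dropped.

Candidate gates (all applied, with the failure reasons recorded): SNR ≥ 3
(a per-instrument choice, deliberately configurable), detection in ≥ 5 *consecutive*
frames at a fixed position (±1 px tolerance), nearest-neighbour separation
≥ 4 px — both members of a closer pair are removed, since the intensity of
an unresolved pair cannot be attributed to either — and eccentricity ≤ 1.2.
For fixed-cell stoichiometry the eccentricity gate is judged on the
five-frame average (the shape estimate with the best SNR); for tracking it
is applied per frame. Filtering is idempotent: re-filtering the retained
set changes nothing.

At SNR 5 the single-frame localization error is noise-limited to roughly
0.2–0.3 px (consistent with the Cramér–Rao scale σ·noise/amplitude);
noiseless fits recover centres to better than 0.05 px.

## Trace extraction and slope exclusion

A retained spot's trace is the background-corrected integrated intensity in
its 5×5 window at a fixed position, frame by frame; the per-frame local
background is the median of the surrounding one-pixel annulus scaled to the
window area. Windows clipped by the image edge yield flagged, truncated
traces.

Traces that are a smooth slope with no distinct stepwise decrease are
excluded before counting. The rule has two clauses, both required:

1. a quadratic (degree configurable 1–3) fits the trace with R² > 0.83;
2. the polynomial's residual sum of squares is no larger than the penalized
   score of the best piecewise-constant segmentation of the same trace.

Clause 2 exists because clause 1 alone is not a slope test: any monotone
staircase correlates strongly with a smooth decreasing curve, and the bare
R² rule excludes even noiseless ideal 3- and 4-step staircases (R² = 0.94
and 0.96 — above the threshold) — i.e. exactly the high-order oligomer
traces the analysis is supposed to find. A genuine slope is distinguished
by the smooth fit reaching the noise floor, where a step model has no
advantage. Constant traces (zero variance, R² undefined) are retained and
reported as zero-step.

## Step counting

Counting is penalized least-squares change-point segmentation, solved
exactly by dynamic programming over all segmentations with segments of at
least `min_segment_length` frames (default 3) and at most `max_steps`
change points (default 8):

    minimize  Σ_segments SSE(segment) + β · (#change points),
    β = penalty_scale · σ̂² · log T.

σ̂ is the noise scale from the median absolute deviation of first
differences (robust to the steps themselves). `penalty_scale` defaults to 3;
with 2 the counter produced ~3% spurious extra steps on single-step traces
at step/noise = 3, with 3 the false-split rate drops below 0.5% without
losing sensitivity. An exhaustive brute-force minimizer of the identical
criterion is kept in the test suite and must agree with the dynamic program
on short traces.

Detected change points are then post-filtered: a boundary whose level drop
is upward or smaller than 3 standard errors of the difference of the two
adjacent segment means (SE = σ̂·√(1/n₁ + 1/n₂)) is merged away, weakest
first. The standard error — not the per-frame noise — is the scale on which
a step between averaged plateaus is resolvable; a gate of 3 per-frame sigmas
would equal the true step height at step/noise = 3 and randomly reject
about half of all real steps.

Finally, step heights are quantized: all fluorophores of a spot share one
unit intensity, so each accepted drop is divided by the trace's unit step
and rounded to a positive integer count of bleaching events. The unit is
selected among candidate values drop/j by minimizing the squared
quantization residual plus a per-extra-event penalty of (2·SE)² — without
that penalty an arbitrarily fine pseudo-unit fits any noisy drop pair
exactly. Ties prefer fewer events, so a clean single drop is always one
event. Across an experiment, traces with a single merged drop (simultaneous
bleaches) are re-counted against the global unit (median drop-per-event over
all traces). Quantization recovers most bleach pairs that fall inside the
temporal resolution limit; the remaining undercount comes from fluorophores
bleaching in the first frames (the initial plateau is too short to detect)
or surviving the whole movie.

Segment level means are weakly decreasing by construction. Traces may
bleach to a nonzero pedestal; only drop structure is counted. Fractions are
normalized over 1–4 counted steps; zero-step and ≥5-step traces are
reported separately, never silently dropped. Per-cell fractions and their
across-cell mean ± SD are emitted alongside the pooled fractions.

## Tracking and diffusion

Linking is a two-phase assignment mirroring standard tracking tools:
frame-to-frame global minimum-cost bipartite assignment (Hungarian
algorithm) gated at 7 px, then a gap-closing pass joining track ends to
later track starts across at most 2 missing frames within 7 px. Each
detection belongs to at most one track; unlinked detections start new
tracks. Gap-closed frames are linearly interpolated when a gapless grid is
needed (MSD, classification).

The MSD is implemented exactly as written in the header formula: the sum
runs over i = 1 … N−1−n, i.e. the pair anchored at the first frame is not
included, and the normalizer is N−1−n. The brute-force oracle in the tests
implements the same printed formula independently.

D comes from ordinary least squares on the first four MSD points with a
free intercept (the intercept absorbs static localization error; a
through-origin variant is available). The fit uses lags 1–4 — the origin is
not a measured point. A negative slope is floored at D = 0 and flagged.

Whole tracks are classified (transient within-track segmentation is out of
scope) in this order: **immobile** if the fitted D is at or below
`D_imm_max` (default 0.005 µm²/s — immobile tracks with 20 nm jitter
cluster well below it, while confined tracks at D = 0.1 µm²/s, R = 0.2 µm
land near 0.012 µm²/s even though their MSD is nearly saturated at the
first lag); else **confined** if the moment-scaling-spectrum slope is below
`S_conf` = 0.4; else **free**. The MSS slope is the slope of the scaling
exponents ν_p (log-log slope of the p-th displacement moment vs lag, p =
1…6) against p: 0.5 for free Brownian motion, near 0 for confined or
stalled motion. Both thresholds were calibrated once on simulated tracks at
the defaults above and are configurable. Tracks shorter than 20 frames are
labelled `unclassified` and excluded from fractions.

Per-mode D summaries are emitted in both pooling conventions (all molecules
pooled, and mean of per-cell means), since either may be wanted.

## Reproducibility

All randomness flows from one root seed through named substreams
(`simulate`, `detect`, `stoich`, `spt`) spawned from a `SeedSequence`, so
every pipeline run is byte-reproducible from its manifest (package version,
config, config hash, seed). The config hash excludes the output directory —
a storage location is not an analysis parameter. Logs record counts in and
out of every filter stage.

## Validation scale and limitations

The test suite and the acceptance script validate by parameter recovery at
these problem sizes: 1000 free tracks per diffusion level (300 frames,
δt = 0.1 s) for D recovery within 10%; 500 mixture traces at step/noise = 3
for stoichiometry recovery within ±0.05 per fraction; 1000 traces per
oligomer size for ≥95% exact step counts; one 512×512 field at SNR 5 and
0.2 spots/µm² for ≥0.95 detection precision and recall; 500 tracks per
motion mode for ≥85% classification accuracy. Smaller versions of the same
checks run in the unit tests.

What passing these does **not** show about real data: the simulator has no
blinking, no drift, no illumination or background structure, no intensity
heterogeneity between fluorophores beyond shot noise, no incomplete
fluorophore maturation or pre-bleaching (so true oligomer sizes are never
underlabelled), and immobile/confined/free modes are pure — real membranes
mix them within one track. Stoichiometry recovery close to the resolution
limit depends on the bleach-rate regime; the residual monomer-fraction bias
(~+2–3 points at the defaults) reflects genuinely unresolvable early and
simultaneous bleach events, not counter error. Raw-count intensity
thresholds of the kind tracking GUIs expose are instrument-specific and are
represented here by the SNR gate (a raw amplitude cut is available via
`DetectionParams.intensity_min`).
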