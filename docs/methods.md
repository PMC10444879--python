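# Methods

This note documents the measurement model, the numerical choices and the
synthetic-data design behind `tapscore`, and what the test suite does and
does not establish.

## Signal model

A hand-video is a sequence of 21-keypoint hand detections at a fixed frame
duration `t_frame` (total duration / frame count; variable-frame-rate input
is treated as constant-rate). Four keypoints matter: WRIST (0), THUMB_CMC
(1), THUMB_TIP (4), INDEX_FINGER_TIP (8). The tapping angle at frame *i* is

    X_i = arccos( (WT_i · WI_i) / (|WT_i| |WI_i|) )   [degrees, 0–180]

with `WT`/`WI` the wrist→thumb-tip and wrist→index-tip vectors. The angle is
invariant under rotation, translation and uniform scaling of the image, which
removes camera distance as a nuisance variable.

**Target-hand selection.** Among detections in a frame, candidates must match
the requested hand with handedness-classification score > 0.9. With several
candidates (other people in frame), the largest hand — greatest
wrist→thumb-tip distance — wins; exact ties keep the earliest-listed
(determinism). Detections with fewer than 21 keypoints are treated as missing
frames, not errors, and counted in the log.

**Missing-hand frames.** A frame is missing when no candidate exists or the
hand-presence score is below 0.90 (both thresholds are separate config keys).
Missing frames carry the sentinel −1.0 in the angle trace.

## Cleaning chain

Order: build angles → interpolate → longest segment → detect peaks → trim.

* **Interpolation.** A sentinel is filled when strictly more than half of the
  up-to-10 surrounding frames (5 per side, fewer at boundaries, mask fixed in
  a single pass) are visible. The fill value is a degree-3 polynomial
  least-squares fit to *all* visible samples, clamped to [0, 180]. Degree 3
  is a config key; a low-order fit avoids oscillation on long signals, at the
  price of being a crude filler inside fast oscillation — which is why
  trimming (below) and segment selection carry most of the cleaning weight.
* **Longest visible segment.** The longest run without sentinels (earliest on
  ties) removes pre/post-task positioning.
* **Peak detection.** Deterministic, in order: (1) candidates are strict
  interior local maxima (plateau apexes are not candidates; real traces have
  generic values); (2) amplitude floor: peak value must exceed the signal's
  25th percentile (linear-interpolation percentile); (3) minimum inter-peak
  gap 0.1 s — scanning left to right, a too-close candidate replaces the last
  accepted peak only if larger; (4) trough rule: between adjacent accepted
  peaks some sample must fall below min(pair) − 0.2·IQR of the signal; while
  violated, the smaller peak of the offending pair is dropped (ties drop the
  later) and the scan restarts. The gap default corresponds to 10 taps/s,
  beyond plausible human tapping; the trough depth fraction and floor
  quantile are config keys. An exhaustive rule-based oracle in the test suite
  reproduces the detector exactly on 100 random smooth signals.
* **Trimming.** The first and last tap are contaminated by hand positioning,
  so the retained signal runs from the 2nd through the 2nd-last peak; fewer
  than 4 peaks is an error naming the video.

## Feature inventory (registry version 1.0)

Exactly 65 named features per hand-video, fixed in
`tapscore.kinematic_features.FEATURE_NAMES`.

* **35**: {speed, acceleration, period, frequency, amplitude} × {median, IQR,
  mean, min, max, std, entropy}. Speed `|ΔX|/t_frame` (°/s) and acceleration
  `|Δs|/t_frame` (°/s²) are per frame; period `(P_i − P_{i−1})·t_frame` (s),
  frequency `1/T` (Hz, per-tap, not tap count/duration) and amplitude
  `X_{P_i}` (°) are per tap.
* **12 rhythm/hesitation features**: spectral aperiodicity; interruption
  count (speed < 50 °/s sustained ≥ 10 ms); freezing count and longest
  freezing duration (> 20 ms); period-line R² and slope; period polynomial
  fit complexity; amplitude end−mean, end−begin and per-tap slope; period
  variance normalized by the mean period; tap count. Thresholds are strict
  as stated (<, ≥, >); run duration is run length × `t_frame`.
* **18 wrist features**: {|Δx|, |Δy|, |Δ|} of the wrist in per-frame
  normalized coordinates (divided by that frame's wrist→THUMB_CMC distance,
  cancelling camera distance) × {median, IQR, min, max, std, entropy} — the
  mean is omitted from the wrist aggregates to fix the group at 18. Wrist
  motion is computed over the same trimmed segment as the tapping features.

**Numerical choices.** Distribution entropy is Shannon entropy (nats) of a
10-bin histogram spanning [min, max]; a range below float resolution counts
as constant (entropy 0). Aperiodicity is the Shannon entropy of the
real-FFT power spectrum of the mean-removed signal normalized to sum 1 (a
pure tone is minimal; arrhythmic tapping spreads power). Period-line R² is 1
by convention when period variance is 0; fit complexity sweeps degrees 1–10
and returns 11 when none reaches R² ≥ 0.9. Amplitude "end"/"beginning" are
the single last/first tap. Wrist displacements below 1e−9 of the coordinate
scale are rounding residue of the per-frame normalization and are zeroed.
End-of-scale note: the wrist |Δx|/|Δy| components are defined along image
axes (the magnitude |Δ| is rotation-invariant; the components are not when
the wrist genuinely moves) — so full 65-feature rotation invariance is exact
for drift-free input and holds for the tapping group and |Δ| aggregates in
general.

## Severity model

* **Redundancy filter**: greedy scan in registry order; a feature is dropped
  when |Pearson r| with an already-kept feature exceeds 0.85 (the later
  column of each pair is dropped). Constant columns have undefined r, are
  kept, and flagged.
* **Significance screen**: per-feature Pearson r against the 0–4 labels with
  the two-sided test p-value at α = 0.01, no multiplicity correction —
  report-only; all surviving features stay model candidates because strong
  non-linear relations can escape a linear screen.
* **Selection**: recursive feature elimination (step 2) with the LightGBM
  learner down to 22 features.
* **Regressor**: LightGBM (leaf-wise tree growth; 200 estimators, learning
  rate 0.05, 31 leaves, min 5 samples/leaf, deterministic single-thread
  mode), behind a per-feature standard scaler fitted on training rows only.
  Random-forest and support-vector alternates are pluggable; min-max scaling
  is a config alternative. Predictions are clipped to [0, 4]; classes round
  half-up. Minority oversampling is deliberately not implemented (it degraded
  regression quality in evaluation); the config key exists only to document
  the decision.
* **Evaluation**: leave-one-patient-out CV — one fold per participant, both
  hands held out together. By default the redundancy filter and feature
  elimination are re-fit inside every training fold (leakage-safe);
  `paper_mode=True` screens once on the whole table, reproducing the simpler
  whole-table protocol. Metrics: MAE, MSE, classification accuracy,
  Kendall τ, MAPE (over truth > 0 rows only, exclusions counted), PCC,
  Spearman ρ.
* **Attribution**: exact TreeSHAP via the tree ensemble's own
  path-dependent contribution computation; per row the attributions sum to
  the unclipped prediction minus the expected baseline. Global importance is
  the mean |attribution| per feature.

Hyper-parameters are fixed documented defaults — reproducibility over
search; a hyper-parameter sweep is out of scope.

## Rater analytics

Ground truth per video: modal value when at least two of the three expert
ratings agree (provenance `majority`), else the rounded mean (`averaged`;
three integers can never average to a half point). Non-expert ratings never
enter ground truth. ICC defaults to two-way random effects, absolute
agreement, single rater (all six variants selectable) with the F-based 95%
CI; Krippendorff's α uses the coincidence-matrix formulation at the ordinal
level by default (0–4 is an ordered scale; interval and nominal available)
and tolerates missing ratings. Video quality is `low` iff at least one
expert flagged the video as difficult; the quality analysis reports per-group
ICC and a chi-square independence test (dof 1, no continuity correction) of
majority-found × quality.

## Synthetic generator

The generator emulates what the pose-estimation front end hands to the
pipeline; it does not emulate video pixels.

* **Waveform**: each tap is a piecewise-linear arch from a 10° baseline up to
  `baseline + amplitude` and back, with the apex forced onto a sampled frame.
  Linear strokes keep the sampled per-frame speed constant (2·amplitude·rate)
  and far above the 50°/s hesitation threshold away from deliberate events.
  A smooth arch cannot do this: any smooth extremum sampled at 30 fps
  produces one near-zero frame difference per tap, i.e. one spurious ~33 ms
  "freeze" per tap, which would make planted-event counts unrecoverable by
  construction. A shaping exponent (default 1 = linear) can round the
  valleys for stress tests.
* **Events**: freezes/interruptions are runs of constant baseline angle
  inserted at inter-tap valleys (peak structure intact), quantised to whole
  frames; the truth record stores realised durations and the event counts
  expected inside the trimmed segment (events at the same valley merge; the
  first and last gap are trimmed away). At the 30 fps default a single
  quantised slow frame lasts 33 ms and therefore counts as freezing; tests
  that need interruption-but-not-freeze events (10–20 ms) use 60 fps
  parameters explicitly.
* **Noise**: per-tap period jitter (lognormal-free CV on the period,
  clamped), per-frame Gaussian landmark noise, wrist random-walk drift,
  Bernoulli missing frames, and missing lead-in/lead-out segments.
* **Cohorts**: participants are assigned severities 0–4 with the proportions
  22.1/37.0/28.8/11.0/1.1% (the severity distribution of a 489-video home
  recording study); each severity maps to a parameter regime in which median
  speed and amplitude strictly decrease, and jitter, decrement, hesitation
  rates and missing-frame rates increase, with severity — the direction of
  every documented severity–kinematics correlation. Three simulated experts
  rate each video as truth ± 1 with probability 0.2 (non-experts 0.45), and
  labels are derived from those ratings exactly as for real data. The
  standard evaluation cohort is 100 participants × 2 hand-videos.

**What the synthetic data does not capture**: pose-estimator failure modes
correlated with hand pose, tremor superimposed on tapping, inter-rater bias
structure, ON/OFF medication states, and the long-tail noise of real home
video. Passing the recovery and LOPO tests therefore demonstrates that the
pipeline measures what it claims on signals of known structure — not that
real-video performance reaches any particular level.

## Problem sizes and determinism

Tests and the acceptance script run the peak-detector oracle on 100 random
smooth signals, parameter recovery on single zero-noise videos, and LOPO on
the 100-participant cohort (200 hand-videos, ~50 LightGBM fits per fold with
in-fold elimination). All stochastic components derive from one root seed;
identical seeds give byte-identical generator output, selections,
predictions and attributions.

## Known limitations

* Plateau peaks (exactly equal adjacent samples) are invisible to the strict
  local-maximum rule; real-valued traces make this a measure-zero concern.
* The cubic interpolation filler is a poor estimator inside fast
  oscillation; it exists to bridge single-frame dropouts, and spurious peaks
  it may create are largely absorbed by first/last-tap trimming.
* MAPE is undefined at truth 0 and is reported over positive-truth rows
  only, which overweights mild-plus severities.
* ICC confidence intervals follow the library's F-based construction, which
  differs in the third decimal from some textbook variants.
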