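# Methods

This note documents the signal model, the analysis conventions and the
design choices behind `tremorkit`, and what its simulation-based tests do
and do not establish about real recordings.

## Signal model and assumptions

Wrist acceleration during one exam position is modelled as

    a(t) = g·n̂ + [A sin(2πf t + φ) + hA sin(4πf t + φ₂)]·û
           + d sin(2πf_d t)·n̂ + v sin(2πf_v t)·û + ε(t)

with gravity g along a posture-specific orientation n̂, tremor of
acceleration amplitude A (m/s²) at fundamental f on a fixed unit axis û with
optional second harmonic (ratio h), slow drift (amplitude d at f_d = 0.1 Hz),
a voluntary component v at f_v ≈ 1.25 Hz present only in the loaded-action
task, and isotropic Gaussian noise ε with per-axis SD σ.  The analysis
assumes tremor is approximately uniaxial and stationary *within* one 30 s
position (axis and gravity may change freely *between* positions) — the
empirical basis for projecting onto PC1 per epoch.

Under this model the metrics have closed forms used throughout the tests:
the PC1 direction is û (for A² / 2 ≫ σ²), and total band power is
A²/2 + (hA)²/2·1[2f in band] + v²/2·1[f_v in band] + σ²·(band width)/(f_N),
with f_N the Nyquist frequency.

## Pipeline conventions

* **Units.** Device CSVs carry acceleration in g; everything downstream is
  SI (1 g = 9.80665 m/s², the conventional standard-gravity constant).
  PSDs are m²/s⁴/Hz, band powers m²/s⁴.
* **Indexing.** Samples are 0-based, intervals half-open [start, end).
  Timestamps are parsed only to infer the sampling rate (reciprocal median
  gap when no header rate is present) and check monotonicity; the filename's
  start time anchors absolute time.  This avoids accumulating float-time
  error over ~30 min sessions.
* **Marker detection.** Pulse onsets are samples where the light channel
  first exceeds median + k·MAD (k = 10), with runs closer than 0.5 s merged.
  Median/MAD make the threshold insensitive to ambient-light level and
  drift; the debounce absorbs flashlight flicker.  With a constant channel
  (MAD = 0) and nothing above the median the result is an empty list, not an
  error.
* **Epoch trimming.** 1.0 s is cut from each epoch edge (30 s → 28 s,
  2800 samples at 100 Hz) to suppress the transition transients around the
  flashlight events.  The exam's 5–15 s buffers separate positions; within
  an epoch nothing else is discarded.
* **Rest epochs.** Only active positions are light-marked.  The default
  protocol contains two unmarked rest entries per repetition (the opening
  rest position and one intervening rest period); each maps to a window of
  its stated duration ending one nominal buffer (the midpoint of the 5–15 s
  range, 10 s) before the next marked epoch's start pulse.  Additionally,
  every unimanual epoch is scored as rest for the contralateral wrist (that
  arm rests on the armrest throughout).  Default totals per wrist per
  session: 6 dedicated + 6 contralateral = 12 rest epochs.  On real data the
  dedicated windows can include up to ~5 s of position-change movement when
  the actual buffer deviates from the nominal 10 s; the band-pass and the
  1 s trim mitigate but do not eliminate this.
* **Filtering.** Zero-phase (forward–backward) Butterworth band-pass,
  order 4, corners 0.5 and 25 Hz.  The corners deliberately bracket the
  1–20 Hz metric band so band-interior content is preserved (< 2 % energy
  change for components in roughly 1–15 Hz); content at the extreme upper
  band edge (≈ 18–20 Hz) is attenuated a few percent by the filter skirt —
  physiological tremor fundamentals (3–12 Hz) are unaffected.  Zero-phase
  application keeps markers and epochs aligned with the filtered signal.
* **PCA per epoch.** The projection direction is recomputed for every
  epoch because posture changes reorient both gravity and the tremor axis.
  Computed via SVD of the demeaned (N, 3) epoch; eigenvalues are s²/(N−1).
  Sign convention: the first loading entry with |entry| > 1e-12 is made
  positive.  An all-zero epoch is a degenerate-input error.
* **Welch estimator.** Hann window, 10 s segments (Δf = 0.1 Hz), 50 %
  overlap, mean averaging, one-sided density normalisation — about 5
  averaged segments per trimmed epoch, and ∫PSD df equals the sample
  variance within ~4 % at these lengths (worst case over the seeded test
  epochs).  0.1 Hz resolution supports reporting peak frequencies to two
  decimals.
* **Band metrics.** Peak search restricted to 1–20 Hz so the action task's
  ≈ 1 Hz voluntary component cannot masquerade as tremor from below the
  band; PSD ties resolve to the lowest frequency (deterministic); total
  power by trapezoidal integration over the band.
* **Summary vs per-epoch metrics.** Both are reported: each repetition's
  metrics, and the metrics of the pointwise-averaged spectrum (labelled
  `mean` in the CSV, matching the solid trace in the overview figure).  The
  averaged-spectrum values are the designated summary.
* **Spearman validation.** r_s is the Pearson correlation of mean-ranked
  data; p two-tailed via the t approximation with n−2 df for n ≥ 10, else a
  permutation test (exhaustive for n ≤ 7, seeded 10⁵-draw Monte-Carlo
  otherwise); 95 % CI via Fisher z ± 1.96/√(n−3), the standard large-sample
  interval, clamped at |r_s| = 1.  Strength labels weak/moderate/strong at
  |r_s| thresholds 0.4/0.6 (configurable).  No multiple-testing adjustment
  by default; Holm is available but off, since the validation grid is
  reported as raw two-tailed p-values.

## Simulator defaults (the study conditions)

| parameter | default | rationale |
|---|---|---|
| sample rate | 100 Hz | device maximum; Nyquist 50 Hz well above the band |
| epoch duration / repetitions | 30 s / 3 | the structured exam's prescription |
| inter-position buffer | 10 s fixed | midpoint of the prescribed 5–15 s |
| tremor amplitudes (ET profile) | rest 0.05, posture 1.0, bimanual 0.95, wing 2.0, action 1.5 m/s² | reproduces the characteristic rest ≪ posture < action ≤ wing severity ordering at clinically plausible power scales (TPwr ≈ 0.5–2 m²/s⁴) |
| tremor frequency (cohort) | Normal(4.6, 1.0) Hz truncated to [3, 12] | ET fundamentals cluster at 4–6 Hz; the truncated normal's location is calibrated so its *post-truncation* mean equals the configured 4.6 Hz (asymmetric bounds would otherwise bias the cohort mean upward by ≈ 0.1 Hz) |
| subject severity | lognormal, σ = 0.5, one factor per subject × per-position jitter σ = 0.1 | severity is a subject-level trait; position amplitudes within a subject are strongly correlated, keeping the ordering coherent |
| noise SD | 0.1 m/s² per axis | ≈ 1 % g: above the device's ~4 mG resolution floor, in-band contribution ≈ 0.004 m²/s⁴, consistent with the < 0.01 m²/s⁴ postural regime seen after successful tremor surgery |
| voluntary action component | 0.39 m/s² at 1.25 Hz | ≈ once-per-second drinking motion; gives tremor-free controls an action-band total power of ≈ 0.08 m²/s⁴, matching the reported ~0.09 ± 0.03 m²/s⁴ control level |
| drift | 0.05 m/s² at 0.1 Hz | slow postural sway; removed by the 0.5 Hz high-pass corner |
| light channel | baseline 10 + uniform[0, 1) flicker, pulses 2000, 0.2 s | bounded ambient flicker (a quantized photodiode floor) keeps the MAD finite while guaranteeing zero false marker detections; pulse SNR mimics a flashlight on a photodiode |

All randomness flows through one generator seeded per session; cohort
subjects use independent spawn-keyed substreams so cohorts are reproducible
element-wise.

**What the simulator does not emulate:** biomechanical limb dynamics and
harmonically rich or amplitude-modulated tremor, re-emergent-tremor latency
after posture changes, movement artefacts during the buffers, temperature
and calibration drift of the sensor, and variable flashlight timing.
Passing the simulation suite therefore establishes the *estimator
arithmetic* (segmentation, projection, spectral normalisation, metric
definitions, statistics) — not robustness to every artefact of real
recordings.

## Numerical choices and degenerate inputs

* Peak ties break to the lowest in-band frequency.
* PCA on an all-zero epoch, Spearman on constant input, SD of a single
  subject, fold ratios with non-positive denominators, bands outside the
  spectrum grid, high-cut at/above Nyquist: all explicit errors, never NaN.
* r_s is clipped to [−1, 1] against rounding before the CI/t computations;
  |r_s| = 1 reports the degenerate CI [r, r] and p from the permutation or
  the t limit (0).
* Fisher-z CIs use 1.96·(n−3)^(−1/2); for n = 4–9 this interval is known to
  be approximate and is labelled as the large-sample interval.
* Recordings whose inferred sampling rate exceeds the 100 Hz device ceiling
  are rejected unless the caller raises the ceiling explicitly.

## Open design points resolved here

* **Rest-epoch accounting.** Twelve rest epochs per wrist per session are
  obtained as 6 dedicated rest windows (two unmarked rest entries per
  repetition: the opening rest position and one intervening rest period)
  plus 6 contralateral unimanual epochs (the other arm's extended-arm
  posture and loaded action, each performed by both arms once per
  repetition).  The exam sequence is configuration, not a constant, so
  other conventions are a YAML file away.
* **PCA scope.** Per epoch, not per recording: a whole-session PCA would
  mix gravity orientations and tremor axes across postures and let
  high-power positions dictate the projection used for low-power ones.  A
  session-level PC1 variance fraction can still be read from the per-epoch
  fractions in the metrics table.
* **Which metrics feed cohort summaries.** Both per-epoch and
  averaged-spectrum metrics are emitted; cohort tables use whatever rows
  the caller selects (the `mean` rows by convention).
* **Strength thresholds.** 0.4 and 0.6 on |r_s| reproduce the published
  moderate/strong labelling of the validation grid (0.41–0.49 moderate,
  0.58 moderate, ≥ 0.60 strong); they are exposed in the API rather than
  hard-coded into interpretation.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use: 50 seeded epochs for the
Parseval check, 100 epochs for peak recovery (3/5/8/12 Hz) and for the PCA
oracle, 3 amplitudes (0.1/1/3 m/s²) for the closed-form power check, 20
two-wrist sessions for segmentation recovery, 1000 tied vectors for the
Spearman oracle plus 15 n = 10 pairs for the t-vs-permutation comparison,
one session for the scaling law, and a 25-subject ET cohort plus 6 controls
for end-to-end recovery.  The complete run takes on the order of two
minutes on one CPU.

## Known limitations

* The CSV dialect is the minimal timestamp/x/y/z/light convention plus a
  user column map; proprietary binary exports must be converted upstream.
* Rest-window placement on real data inherits up to ±5 s uncertainty from
  the unknown true buffer duration (see above).
* The 2-SE cohort-mean check is a statistical property: ~5 % of seeds are
  expected to fall outside it even with a perfectly calibrated generator.
* No gyroscope fusion, time–frequency analysis, or harmonic-distortion
  indices; tremor amplitude in displacement units is out of scope (the
  metrics are acceleration-based).
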