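# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the synthetic benchmark can show. It is the design record
for maintainers; the README covers usage.

## The correction model

ASR is an anomaly-detection-and-repair scheme in component space. Its
premise: artifacts (blinks, cable sway, broadband noise) carry far more
variance than brain signal, concentrated in a low-dimensional spatial
subspace that changes from window to window. Clean calibration data define
what "normal" variance looks like per component; anything beyond it is
reprojected onto the span of the remaining clean components, as seen
through the calibration mixing matrix M = U^{1/2}.

### Calibration

1. **Spectral shaping.** Both calibration and incoming data pass a fixed
   causal FIR that up-weights < 3 Hz and > 40 Hz relative to the alpha
   band — the bands where artifacts dominate resting EEG. The filter is a
   501-tap linear-phase design (amplitude breakpoints 0 Hz→3, 2→0.75,
   3→0.33, 13→0.33, 16→1, 40→1, rising to 3 at Nyquist) converted to
   minimum phase, so its causal group delay is a few samples and one
   filter state serves streaming use. Identical filtering on both sides is
   what makes thresholds and detection statistics commensurable. A bypass
   flag (`use_shaping=False`) exists for diagnostics.
2. **Robust covariance centre.** Sample covariances of non-overlapping
   analysis-window-length blocks are reduced to the Euclidean L1 geometric
   median (Weiszfeld iteration, Vardi–Zhang tie rule, tol 1e-8) in
   euclidean mode, or the Karcher mean (fixed-point iteration on the
   affine-invariant manifold, tol 1e-8 on the gradient norm relative to
   the trace scale) in riemannian mode. Medians and means of covariances
   instead of one long-window covariance: a single artifact block cannot
   drag the centre.
3. **Component statistics.** Activations Vᵀ(shaped data) are summarised by
   windowed RMS (window = analysis window, 50% overlap), with robust
   location/scale (median, 1.4826·MAD; plain mean/SD via
   `robust_stats=False`). Scales are floored at 1e-12·max(μ,1) so
   perfectly periodic components keep a defined threshold.
4. **Threshold operator.** T = diag(μ + k σ) Vᵀ. Row norms are the
   per-component amplitude limits; projecting T onto a new eigenbasis
   redistributes those limits correctly when the basis rotates inside
   nearly-degenerate subspaces.
5. **Burst reference (riemannian mode).** The clean-data distribution of
   b = log λ_max(U⁻¹ C_w) over the calibration windows is summarised by
   its median, MAD and maximum; the processing-time burst gate (below)
   triggers above max(median + 5·1.4826·MAD, max + 1). b is a maximum
   statistic with a right-skewed (extreme-value) distribution, hence the
   guard by the observed maximum plus an e-fold margin rather than a pure
   MAD rule.
6. **Self-cleaning.** `ASRModel.fit()` first corrects the calibration
   stretch with a model fitted on itself, then refits on the cleaned
   stretch (default on). Residual artifacts in the "clean" minute
   therefore cannot inflate the thresholds.

In riemannian mode the tangent-space PGA of the windowed covariances at
base U (log-map, √2-scaled vectorisation, PCA) is computed and stored as a
diagnostic: its leading variance fraction tells how one-dimensional the
calibration covariance scatter is. The component basis itself is the
eigenbasis of the robust centre in both modes — PGA directions are
symmetric matrices (covariance-space directions), not channel vectors, so
they cannot serve as the projection basis V that the threshold operator
requires.

### Processing

Both engines walk the recording causally, updating a smoothed covariance
estimate and its eigendecomposition at fixed intervals, and apply the
reconstruction operator with a raised-cosine cross-fade over a
`stepsize`-sample overlap at each operator change.

- **Euclidean (ASR).** Moving-average covariance over the analysis window
  (range = round(srate·window) samples), updated and decomposed every
  `stepsize` samples, smoothed across updates by exponential forgetting
  with weight w = 1 − 2^(−stepsize/range) on the current window (the past
  halves after one window's worth of updates). Output is emitted with a
  fixed latency of half a window so the analysis window straddles the
  samples it corrects; detection and artifact coincide instead of the
  correction trailing by a window. No sample depends on data beyond its
  own analysis window.
- **Riemannian (rASR).** One unbiased estimator covariance X Xᵀ/(t−1) per
  analysis window, one eigendecomposition per window — range/stepsize-fold
  fewer than ASR. Quiescent windows are smoothed into the running
  background estimate by a two-point Karcher mean with the same numeric
  weight w; each window is emitted corrected by its own operator (no extra
  latency beyond the window itself).
- **Burst gate (riemannian).** The geometric mean of a background matrix
  and a 100× rank-one burst is *not* background-plus-burst: its top
  eigenvector rotates away from the artifact direction (Euclidean
  averaging, being additive, leaves a rank-one artifact direction intact;
  geodesic averaging warps it). Smoothing must therefore pair like with
  like. When b = log λ_max(U_cal⁻¹ C_seg) exceeds the calibrated burst
  threshold, the running background mean is frozen (it must not absorb
  artifact variance) and the segment is Karcher-combined with the previous
  *burst* covariance instead, accumulating an aligned artifact basis
  across the burst run. Below the threshold the background recursion
  resumes. The gate is itself a Riemannian statistic: the L∞ geodesic
  distance from the calibration covariance, calibrated on clean data.
- **Detection and repair.** Component j of the decomposition is flagged
  when its eigenvalue exceeds Σᵢ(T V_new)²ᵢⱼ. At most `maxdims` top
  components are repairable (`maxdims ≤ 1` is a fraction of channels —
  so the rASR value 1 means *all* dimensions, not one); lower components
  are kept unconditionally. The operator
  R = M ((clean·VᵀM))⁺ Vᵀ is an orthogonal projector when V is the
  calibration basis; for rotated bases the pseudoinverse can amplify, so
  R's singular values are clipped at 1 — correction never adds energy
  (this preserves R's null space, i.e. flagged directions stay
  annihilated). If no component is clean the previous window's operator is
  held. The running covariance is initialised at the calibration
  covariance, so there is no ramp-in of spurious detections.
- **Streaming contract.** `process()` may be called with consecutive
  chunks plus the carried state; outputs concatenated with `flush()` are
  bit-identical to one offline call (the FIR filter state, covariance
  buffers and emission bookkeeping are exact). Latency: half a window plus
  up to one update interval (euclidean) or up to one window (riemannian).

### Pre-stages

The cleaning pipeline order is flatline detection → drift removal →
subspace correction. Flatline channels (a run of ≥ `flatline` seconds with
successive differences < 1e-8 μV) are dropped, not interpolated. Drift
removal is a Kaiser-window FIR high-pass with the configured transition
band (default 0.25–0.95 Hz); the band-limiting filters are 40 Hz low pass
(order 166) and 0.25 Hz high pass (order 3300). Offline filtering is
zero-phase (forward–backward), as standard for ERP work; a causal mode
exists for online use, with the filter's group delay.

## Synthetic sessions

The generator emulates a 24-channel, 250 Hz mobile recording: one clean
60 s calibration stretch and a 240 s task stretch.

- **Background**: c latent 1/f^α sources (α = 1.2, flattened below 1 Hz),
  variances log-spaced over 1.5 decades, mixed through fixed smooth random
  scalp maps; channels normalised to 10 μV RMS; plus 1 μV RMS white
  sensor noise per channel. The noise floor is physical (amplifier noise)
  and keeps the sensor covariance conditioned like real recordings
  (~10³); without it the mixed-source covariance has near-null directions
  (condition ~10⁷) that no amplifier exhibits and that break whitened
  statistics.
- **Blinks**: biphasic generalized-Gaussian bump, 300 ms wide with a 12%
  negative rebound, peak 254.92 μV at Fp1/Fp2 (the mean indoor blink
  amplitude reported for smartphone EEG), ~8% per-blink amplitude jitter,
  ~40/min with ≥ 800 ms refractory gaps, frontal topography decaying
  exponentially toward occipital sites (< 2% at O1/O2).
- **VEPs**: P1 (+6 μV, 100 ms) and N1 (−10 μV, 170 ms) Gaussian
  deflections with a bilateral occipital topography maximal at O1/O2,
  ~10% per-trial gain jitter, inter-stimulus interval ~1.5 s.
- **Linearity**: task = background + blink component + VEP component,
  exactly, with all event times retained — tests can score correction
  against the true artifact and the true signal.

What the generator does **not** model: amplitude nonstationarity (alpha
bursts, drowsiness), gait and cable-sway artifacts, saccades and other
non-stereotypical eye activity, electrode impedance drift. Passing the
benchmark therefore shows that the engines behave as designed under
stationary correlated noise with stereotypical artifacts; it does not
certify performance on ambulatory recordings.

## Evaluation

- Blink detection: moving-average-smoothed mean of Fp1/Fp2, threshold
  median + 3·1.4826·MAD, minimum supra-threshold duration 100 ms, peak
  alignment, 500 ms refractory. On synthetic ground truth recall and
  precision are ≥ 95%; the duration criterion is what rejects brief noise
  excursions in blink-free data.
- Blink epochs span −400…+500 ms with baseline −400…−300 ms — strictly
  before blink onset at −300 ms. (A baseline overlapping the onset
  subtracts a fraction of the blink from every channel and imprints a
  negative copy of the blink map on the corrected topography.)
- VEP epochs span −200…+500 ms, baseline −200…0 ms; N1 is the most
  negative O1/O2-mean value in 120–250 ms, P1 the most positive in
  70–150 ms (typical latency windows); SNR(dB) =
  10·log₁₀(|peak| / SD of the pre-stimulus baseline trace).
- Topography similarity: channel-wise Pearson r between the blink-locked
  scalp maps at the uncorrected peak latency, reported as r, R² and
  Fisher z (r clipped to 1−1e-12 before atanh).
- Efficiency: the instrumented eigendecomposition count — a
  hardware-independent proxy for runtime, since the decomposition is the
  dominant per-update cost.

### Variability of the topography R²

The corrected blink-locked map is the sum of a small systematic leak
(sub-μV to a few μV; set by the angle between the flagged eigenvector and
the true blink direction, which depends on the session's background
covariance) and blink-locked background noise (~0.8 μV per channel at 160
blinks). Because the background is spatially smooth, that noise map has
few effective spatial degrees of freedom and can correlate substantially
with the blink map by chance. Single-session R² values therefore scatter
widely across sessions (we observe ~0.02–0.9 over generator seeds for
both engines, with suppression always ≥ 97%); the packaged regression
checks pin a fixed session, mirroring how such comparisons are made on a
fixed cohort. Conclusions about the *ordering* of methods from one
session's R² alone are not supported.

## Parameters

| name | unit | ASR default | rASR default | meaning |
|------|------|------------|--------------|---------|
| cutoff k | SDs | 5 | 1 | threshold multiplier in μ + k·σ |
| window | s | 0.5 | 0.3 | analysis window; range = round(srate·window) |
| stepsize | samples | 32 | 16 | operator update interval (ASR) / cross-fade and forgetting scale (both) |
| maxdims | fraction/count | 0.66 | 1.0 | top components eligible for repair |
| flatline | s | 5 | 1 | maximum tolerated flat run |
| hp_band | Hz | (0.25, 0.95) | (0.25, 0.95) | drift-removal transition band |

The per-method defaults are the published parameter pairs for this class
of recordings. rASR's aggressive cutoff k = 1 is viable because its
detection statistic is heavily smoothed (w = 1 − 2^(−stepsize/range) ≈
0.14) while bursts bypass the smoothing through the gate; the `burst`
wrapper parameter seen in some configurations duplicates `cutoff` and is
accepted as an alias with `cutoff` taking precedence.

## Numerical choices

- Affine-invariant metric throughout (d(A,B) = ‖log(A^{-1/2}BA^{-1/2})‖_F);
  it underlies the Karcher mean, the geodesic distances and PGA.
- Eigenvalue ordering ascending everywhere.
- SPD regularisation: add ε·trace/c·I with ε = 1e-10 to rank-deficient
  estimates before manifold operations.
- Karcher mean: closed-form geodesic for two matrices; fixed-point
  iteration initialised at the weighted Euclidean mean otherwise, tol
  1e-8 (gradient norm relative to trace scale), max 50 iterations,
  convergence failure raised with the final gradient norm.
- Weiszfeld: tol 1e-8, max 100 iterations, Vardi–Zhang rule when an
  iterate coincides with a data point.
- PGA is the tangent-space (Fletcher) approximation: exact geodesic
  submanifold optimisation changes results only at curvature scale and
  needs a manifold optimiser; the tangent approximation is standard for
  covariance scatter of this size.
- range = round(srate·window) (round-half-away-from-zero), at least 2.
- Fisher z at |r| = 1: r clipped to 1 − 1e-12.

## Problem sizes

The packaged checks run on 60 s calibration + 240 s task at 250 Hz and
24 channels (≈160 blinks, ≈150 VEP trials), manifold property checks on
up to 1000 seeded matrix pairs, and oracle comparisons (numeric
minimisers, closed forms) on 2×2–6×6 instances — sizes at which every
independent oracle is exact and the full suite runs in well under a
minute.

## Known limitations

- The riemannian calibration basis equals the euclidean one up to the
  robust centre used (Karcher mean vs L1 median); the genuinely Riemannian
  machinery lives in the processing loop and in the diagnostics.
- The burst gate is a hard switch; a graded trust schedule (weight as a
  function of geodesic distance) might behave better near the threshold.
- Streaming latency is half a window (euclidean) or one window
  (riemannian); true zero-latency operation would need causal detection
  with trailing windows, which corrects artifacts late (we measured
  roughly an order of magnitude worse blink suppression that way).
- No automatic selection of clean calibration stretches; the caller must
  supply resting data.
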