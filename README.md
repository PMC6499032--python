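# rasr — Artifact Subspace Reconstruction for multichannel EEG

Mobile EEG — a cap, a small amplifier and a phone — picks up eye blinks,
drifts and broadband noise that are orders of magnitude larger than the
brain signals of interest. **Artifact Subspace Reconstruction (ASR)** is an
adaptive correction method built for exactly this setting: it learns the
statistical fingerprint of a clean calibration minute and then, sliding
causally through the recording, detects and repairs short stretches whose
component-space variance exceeds what clean data ever shows. This package
implements classic ASR together with its **Riemannian variant (rASR)**,
which treats the covariance matrices at the heart of the method as points
on the manifold of symmetric positive-definite (SPD) matrices.

## The model

From a clean calibration stretch, windowed sample covariances are reduced
to a robust centre *U* (the Euclidean L1 geometric median for ASR, the
Karcher mean for rASR), giving the mixing matrix *M* = *U*¹ᐟ² and the
component basis *V* (eigenvectors of *U*). Per component, the location μ
and scale σ of windowed RMS amplitudes define the threshold operator

> T = diag(μ + k·σ) · Vᵀ

with cutoff *k*. During processing, each analysis window's covariance is
eigendecomposed (V<sub>new</sub>, D<sub>new</sub>); component *j* is
artifactual when D<sub>new,j</sub> > Σᵢ (T·V<sub>new</sub>)²ᵢⱼ, and the
window is repaired through the calibration mixing matrix:

> X<sub>clean</sub> = M (V<sub>clean</sub>ᵀ M)⁺ Vᵀ X.

The two engines differ exactly where covariance matrices are touched:

|                          | ASR (euclidean)                    | rASR (riemannian)                         |
|--------------------------|------------------------------------|-------------------------------------------|
| per-window estimator     | moving average of outer products   | unbiased estimator X Xᵀ/(t−1) per segment |
| temporal smoothing       | weighted Euclidean average         | two-point Karcher mean along the geodesic |
| decompositions           | one per `stepsize` samples         | **one per analysis window**               |
| published parameters     | cutoff 5, window 0.5 s, stepsize 32, maxdims 0.66 | cutoff 1, window 0.3 s, stepsize 16, maxdims 1 |

Geodesic averaging avoids the *swelling effect* (the determinant of a
Euclidean mean exceeds the geometric mean of the determinants), and the
single decomposition per window is what makes rASR cheap: on identical
input it performs `range/stepsize`-fold fewer eigendecompositions.

The package also ships a synthetic mobile-EEG generator (24-channel 10/20
montage, 250 Hz, 1/f background, ~255 μV frontal eye blinks, occipital
P1/N1 visual-evoked potentials, full ground truth) and the evaluation
metrics used to judge artifact correction: blink-locked peak amplitude and
scalp-map R², VEP N1 amplitude and SNR in dB, and decomposition counts.

## Worked example

```python
from rasr import ASRModel, SessionConfig, generate_session
from rasr.evaluation import score_card, score_card_tsv

session = generate_session(SessionConfig(), seed=1)   # 60 s calibration + 240 s task
res = ASRModel(session.calibration, method="rasr").fit()
print(res.summary())

cleaned = res.process(session.task)
card = score_card(session.task, cleaned, session.blink_times,
                  session.vep_times, injected_n1_uV=-10.0,
                  state=res.last_state)
print(score_card_tsv(card))
```

The summary tabulates the fitted model — per component the eigenvalue of
*M*, the RMS location μ and scale σ in μV, and the resulting amplitude
threshold μ + k·σ (components are sorted by variance; the last rows are
the dominant background components):

```
rASR calibration (24 channels, 250 Hz, cutoff k=1)
================================================================
comp   eigenvalue    mu [uV] sigma [uV]  threshold
----------------------------------------------------------------
   0       1.2580     1.3809     0.1330     1.5139
  ...
  22      16.9110    21.1318     5.9466    27.0784
  23      34.5514    42.4926    11.2805    53.7732
----------------------------------------------------------------
window 0.3 s, stepsize 16, maxdims 1 (24 of 24 reconstructable)
```

and the score card quantifies correction quality (abridged):

```
blink_peak_uncorrected_uV   254.86      # raw blink-locked Fp1/Fp2 peak
blink_peak_corrected_uV     2.93        # after rASR: 98.9% suppression
blink_topography_r2         0.169       # blink map decorrelated
n1_corrected_uV             -9.63       # injected N1 was -10 uV
snr_drop_db                 0.22        # evoked SNR essentially intact
n_eigendecompositions       800         # vs 1875 for euclidean ASR
```

The blink is removed almost entirely while the −10 μV occipital N1
survives within 4% — high sensitivity to artifact with high specificity
for signal, at less than half the decomposition count of classic ASR.

Streaming works chunk by chunk with carried state and reproduces the
offline result exactly:

```python
stream = res.stream()
for chunk in chunks:          # consecutive EEGSegments
    out = stream.process(chunk)
tail = stream.flush()
```

## Command line

```sh
rasr simulate --seed 1 --out sess                 # synthetic session + events
rasr calibrate sess_calibration.npz --method rasr --out calib.json
rasr process sess_task.npz --calibration calib.json --method rasr --out cleaned.npz
rasr evaluate sess_task.npz cleaned.npz --events sess_events.tsv
```

Every run logs its fully resolved parameter set to stderr, so a run can be
replayed bit-identically from its log.

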