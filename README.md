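# ecgid — two-stage ECG biometric identification

`ecgid` implements a closed-set subject-identification pipeline for
single-lead ECG, aimed at biometric verification with consumer/mobile-grade
recordings. The electrocardiogram is a usable biometric because each person's
P-QRS-T complex has a distinctive shape; the difficulty is that mobile ECG is
noisy, drifts with baseline wander, and is sampled at whatever rate the
device uses.

The system combines two complementary feature views of each heartbeat in a
cascade:

1. **Fiducial gate.** Interval, amplitude and angle features measured between
   the P, Q, R, S, T landmarks (and optionally the wave boundaries
   P_on/P_off/T_on/T_off) feed a random-forest classifier. For a query beat
   with feature vector `x_q(l)` the forest yields per-subject probabilities

       P_q1, ..., P_qN = f[ x_q(l) | enrolled feature rows ],

   and every subject with `P_qi > P_th` (default `P_th = 0.15`) enters a
   short candidate list of size K (usually K < 5, K ≪ N).
2. **Wavelet-distance matcher.** The query beat's 5-level Daubechies-3 DWT
   coefficients are compared against each candidate's enrolled template with
   the per-level max-normalised L1 distance

       WDIST(i) = Σ_p ‖D_p^i − D_p^q‖₁ / max|D_p^i|,

   summed over the retained detail levels (default S2 = {D2..D5}); the
   candidate with the smallest distance is declared. With `P_th = 0` the
   cascade reduces exactly to conventional 1-to-N template matching.

The front end shared by both stages: cubic-spline resampling of every record
to a uniform 360 Hz, FFT-domain bandpass 2–50 Hz, hybrid R-peak detection
(adaptive-threshold energy pipeline plus valley-peak refinement), 800-ms beat
windows centred on R, and removal of outlier beats whose correlation with the
mean complex falls below μ − 0.5σ. QT-type intervals are heart-rate corrected
with the Framingham formula `QTc = QT + 0.154 (1 − RR)`.

Because real multi-subject ECG corpora cannot ship with the package, `ecgid`
includes a first-class synthetic cohort generator (sum-of-Gaussians beats
with per-subject morphology, heart-rate variability, baseline wander, 60-Hz
interference, white noise at a set SNR, and multi-session morphology jitter)
with exact R-peak ground truth, so every stage is testable end to end.

## Worked example

```bash
ecgid synth --subjects 10 --sessions 2 --duration 30 --snr-db 15 --seed 2 --out cohort/
ecgid enroll --data cohort/ --db db/          # enrolls session 1
ecgid train  --db db/ --trees 500 --seed 0
ecgid verify --db db/ --record cohort/s003_sess2.csv
ecgid evaluate --db db/ --data cohort/ --mode two-stage --session 2
```

prints

```
wrote 20 records; manifest at cohort/manifest.csv
enrolled 10 subjects into db
trained 500-tree gate over 10 subjects
s003
1.0000
```

`verify` prints the predicted identity of the query record (here correctly
`s003`); `evaluate` prints the closed-set identification accuracy over the
session-2 queries — 1.0000 means all ten queries were attributed to the right
subject. The same workflow is available as library calls
(`ecgid.enroll`, `ecgid.train_gate`, `ecgid.verify`, `ecgid.evaluate`), and
`ecgid ablation` regenerates the single-stage versus two-stage comparison
table over the ML-3/ML-5/ML-9 feature sets and S1/S2/S3 wavelet level sets.

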