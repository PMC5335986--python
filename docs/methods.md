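# Methods

## Pipeline model and assumptions

The package treats subject identification as closed-set classification over N
enrolled identities, one single-lead ECG record per query. The beat — an
800-ms window centred on the R peak — is the unit of information; a subject
is characterised by (a) the joint distribution of fiducial interval /
amplitude / angle features over their beats and (b) the DWT coefficients of
their mean beat. The cascade assumes an upright R wave after filtering (a
config flag rectifies the signal for inverted leads) and that all records
can be brought to a common sampling rate without losing in-band content
(all supported rates are ≥ 128 Hz while the passband ends at 50 Hz, so
cubic-spline up/down-sampling is effectively loss-free for the signal of
interest; no anti-alias prefilter is applied).

## Front end

- **Resampling** (`ecgid.io`): natural cubic spline on the uniform source
  grid, time origin at sample 0, target grid `k / fs_target`. The uniform
  system rate defaults to 360 Hz. Annotations are rescaled and rounded.
  Round-tripping a band-limited record changes interior samples by < 1e-3
  relative RMS.
- **Bandpass** (`ecgid.preprocess`): real-FFT bin zeroing outside the closed
  band [2, 50] Hz. Brick-wall by default — the filter is then an orthogonal
  projection, hence exactly idempotent and linear; an optional raised-cosine
  transition (width 0.5 Hz when enabled) is available for impulsive inputs.
  Bins exactly at the cutoffs are kept.
- **R-peak detection** (`ecgid.rpeak`): derivative → squaring → 150-ms
  moving-window integration → adaptive dual thresholds with eighths-rule
  running signal/noise estimates, 200-ms refractory period, and search-back
  at 1.66× the running mean RR. Each integrated-signal candidate is refined
  to the maximum of the bandpassed signal over the candidate's full
  integration support plus a ±50 ms margin (the integration maximum can sit
  anywhere on its plateau, so a narrower window can miss R), then must show
  an opposite-sign deflection ≥ 5% of the peak within 75 ms (the S valley),
  which suppresses tall T waves. All thresholds are relative, so detection
  is invariant to positive amplitude scaling; window lengths are given in
  milliseconds and converted with `round(ms·fs/1000)`.
- **Delineation** (`ecgid.beats`): half-open windows `[R−half, R+half)` with
  `half = round(0.4·fs)`; beats too near an edge are dropped. Outlier
  removal is single-pass: Pearson correlation of every beat against the
  mean complex (computed over all beats), removal strictly below μ − 0.5σ.
  Zero-variance (flat) beats are assigned correlation 0, which places them
  far below threshold for any real complex distribution.

## Feature views

Fiducial landmarks are constrained extrema (Q/S within ±75 ms of R, P within
[−200, −75] ms, T within (75, 400] ms); boundaries come from the triangle
rule (maximum perpendicular distance to the chord from wave peak to window
far end; windows 100 ms around P, 150/200 ms around T). The feature
catalogue, with ML-3 ⊂ ML-5 ⊂ ML-9 cardinalities 6/15/28, is spelled out in
`ecgid.fiducial`'s module docstring. Every interval ending at T or a
T-boundary is Framingham-corrected, `QTc = QT + 0.154(1 − RR)`. Angles are
measured in the (ms, mV×10) plane; this convention makes ∠QRS small and very
sensitive to QRS width — angle features are therefore the least stable
across sessions (see Limitations).

The wavelet view uses `pywt` with periodized extension, the only standard
extension mode for which the per-level coefficient counts halve exactly
(288 → 144/72/36/18/9 + 9). The default retained level set is S2 = {D2..D5},
covering ≈ 5.6–90 Hz at 360 Hz, which brackets the 2–50 Hz passband. ‖·‖ in
the wavelet distance is read as the per-level L1 norm (switchable to L2),
normalised by the enrolled template's largest absolute coefficient at that
level — deliberately asymmetric.

## Cascade decisions

The gate's probability vector is the average of per-tree leaf class
probabilities (scikit-learn's `predict_proba` implements exactly this).
Candidates are subjects with probability strictly above `P_th` = 0.15;
an empty short-list falls back to the single argmax subject, and `P_th ≤ 0`
passes all N (making the cascade exactly 1-to-N template matching — an
oracle equivalence the tests exercise). Forest defaults: 500 trees, √-of-
features per split, bootstrap on, seeded. The subject template is the DWT of
the mean kept beat (averaged across enrolled sessions). A query is
represented by its single most typical kept beat (highest correlation with
the record's mean complex); multi-beat majority voting exists but is off by
default to match the one-complex protocol. Ties — probability argmax or
distance minimum — break toward the lowest subject id.

## Synthetic cohorts

Each subject is five signed Gaussian bumps (P, Q, R, S, T) with per-subject
amplitudes, widths and offsets drawn uniformly from physiologically sensible
ranges (R 0.9–1.6 mV dominating; Q, S negative; P/T offsets inside the
fiducial search windows; mean RR 0.7–1.1 s). Records add i.i.d. normal RR
intervals truncated at 0.3 s, per-beat ±2% amplitude / ±1% width jitter,
a 0.3-Hz wander sinusoid (0.1 mV) plus a slow random walk, 0.05 mV of 60-Hz
interference, and white noise at a prescribed SNR relative to the clean beat
train (the measured ratio is within 1 dB by construction). Sessions beyond
the first re-draw every morphology parameter with 2% relative jitter. Beat
centres are snapped to integer samples, so with all noise off the annotated
R index is exactly the per-beat argmax. An optional corruption flag replaces
a fraction of beats with inverted or flattened segments to exercise the
outlier filter. The defaults (30 subjects × 2 sessions × 30 s at 360 Hz,
SNR 15 dB) are the package's reference study conditions.

What the generator does **not** emulate: respiration-coupled morphology,
ectopic beats, electrode-motion transients, inter-lead projection, or
realistic coloured noise. Passing tests therefore demonstrate correct
mechanics and parameter recovery under controlled conditions, not clinical
performance on real recordings.

## Numerical choices

Windows in samples via `round(ms·fs/1000)`; half-open index conventions
everywhere; strict inequalities at both decision thresholds (μ − 0.5σ and
P_th) per their definitions; flat search windows yield "missing" boundaries
rather than errors; a level-restricted template cannot be reconstructed or
compared against a differently restricted one (both raise). Randomness flows
from explicit integer seeds: cohorts from a seed sequence, per-record noise
streams keyed by (seed, session, morphology digest), and the forest by its
own seed — identical inputs give bit-identical outputs.

## Benchmark behaviour and limitations

On the reference conditions (five seeds aggregated; sizes chosen so the full
study runs comfortably on a laptop core): R-peak recovery is essentially
perfect (TPR ≈ 1.0, FP ≈ 0), gate-only accuracy ≈ 0.99, two-stage ≈ 0.97
with mean candidate-list size K ≈ 1.1. The wavelet-only 1-to-N matcher is
much weaker here (≈ 0.4): with single-beat queries at 15 dB SNR the in-band
white noise contributes an L1 term comparable to inter-subject coefficient
differences, and because each level is normalised by the *template's*
maximum coefficient the noise floor is template-dependent, biasing the
ungated matcher toward large-amplitude subjects. The cascade is largely
immune because the gate usually passes a single candidate. On low-noise
clinical-grade data the distance matcher is competitive — the noise-free
limit in the test suite reaches accuracy 1.0 in all modes.

Known limitations: angle features (and baseline-referenced small-wave
amplitudes V3/V4) are ill-conditioned under morphology jitter — the
within-session beat baseline sits 400 ms before R, inside the previous
beat's T tail; open-set verification (impostor rejection) is out of scope;
WFDB reading requires the optional `wfdb` dependency.
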