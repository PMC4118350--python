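# Methods

This note documents the models implemented in `caretrace`, the choices made
where the design was genuinely open, what the synthetic generators do and
do not emulate, and the numerical details that matter for reproducing its
behavior.

## Fingerprint localization

The locator is a per-access-point hypothesis test composed into a product
score. Calibration fits, for every (fingerprint, BSSID) pair, the mean,
standard deviation and count of the RSSI readings that survive a 3×IQR
fence (quartiles by linear interpolation between order statistics — the
method is configurable because several conventions exist). The fence is a
single pass: removing an outlier tightens the quartiles, so re-applying the
filter can remove further points; we deliberately do not iterate, and the
property tests assert convergence under iteration rather than idempotence.
If the fences exclude everything (zero IQR), values equal to the median are
retained.

The dispersion is the sample standard deviation (ddof = 1), floored at
`sd_floor` = 0.5 dBm: WiFi radios quantize RSSI to 1 dBm, so an observed
zero variance reflects quantization, not a delta distribution, and an
unfloored sd would make a single off-by-1-dBm reading veto a fingerprint.

A live reading is standardized by `(r − mean)/(sd/√n)`, mirroring the
calibration-phase formula. Dividing a *single* observation by the standard
error of a mean overstates the evidence; the alternative scaling by sd
alone is exposed as `residual_scale = "standard_deviation"`, with the
standard-error form kept as the default because the accuracy on synthetic
flats is insensitive to the choice (both well above the 95% recovery bound)
and it is the form the calibration defines. The significance level is the
two-sided tail of |t| — sidedness is a design choice; two-sided is used
because a reading far *above* the calibrated mean is as anomalous as one
far below. Student-t with n−1 degrees of freedom is used up to n = 30, the
normal beyond; n is the retained count after outlier removal.

The product over access points runs over the model's full BSSID universe:
access points missing from a live scan are informative (absence of a strong
AP argues against the room where it is strong), so the scan is completed
with the imputation floor before scoring. The floor is the most negative
observed RSSI pushed 20% farther from zero (×1.2), giving imputed entries
sd = `sd_floor` and a pseudo-count of 2 (the smallest count with a defined
t tail). Products are accumulated as sums of logs with each α clamped at
1e−300, so a 30-AP environment cannot underflow; the direct and log-domain
paths agree to 1e−10 whenever the direct product is representable. Winner
ties break lexicographically by fingerprint id to keep runs reproducible.

The time-series stabilizer commits a position after k = 3 consecutive wins
by default; k = 1 disables stabilization.

## Step detection and motion gating

One step is one excursion of the force magnitude above 10.3 m/s² followed
by a drop below 9.1 m/s². Inequalities are strict at both thresholds, so a
sample sitting exactly on a threshold neither arms nor fires — relevant for
quantized accelerometers. The step timestamp is the completing (lower)
crossing; the alternative (upper crossing) shifts timestamps by roughly a
half gait cycle and changes nothing else. No smoothing is applied by
default; an optional centered moving average is available
(`smooth_window`). The motion gate reports "moving" iff a step exists in
the half-open window (t − 3 s, t].

## ECG pipeline

The detector follows the energy-envelope tradition: denoise, highpass,
rectify/integrate, adaptive decision.

* Wavelet stage: db4, soft threshold at the universal level
  σ√(2 ln N) with σ from the MAD of the finest detail band; the number of
  decomposed levels is chosen so the thresholded detail bands lie above
  45 Hz (one level at 256 Hz). When the threshold is zero (noise-free
  synthetic input) the stage is skipped.
* Highpass: second-order Butterworth at 5 Hz, zero-phase (`filtfilt`), to
  remove baseline wander without displacing R peaks.
* Non-linear lowpass: squaring followed by a 150 ms moving-average window —
  long enough to merge the Q-R-S deflections into one energy bump, short
  enough not to bridge adjacent beats at 150+ bpm.
* Decision: envelope local maxima above the running threshold
  `tr ← α·γ·peak + (1−α)·tr` with α = 0.1, γ = 0.5, a 200 ms refractory
  period, and tr initialized to γ × max of the first 2 s of envelope.
  Because tr both starts and updates proportionally to the envelope, the
  accepted peak set is invariant under positive rescaling of the input —
  the property that makes the detector robust to electrode gain. Each
  accepted envelope peak is refined to the raw-signal maximum within
  ±50 ms.

Q and S are the raw-signal minima within 60 ms before/after R; P is the
maximum within 200 ms before Q, T the maximum within 400 ms after S. P/T
are reported absent when the window extremum rises less than 0.05 mV above
the window median — a deliberately simple prominence test, consistent with
the package's no-black-box stance for wave location. Beats whose Q/S
windows would cross the record edge are dropped. Feature vectors carry
same-wave inter-beat intervals (undefined for the first beat, or when a
wave is absent) and intra-beat distances, all in ms via the sampling rate,
which is always an explicit input (synthetic fixtures use 256 Hz).

All window lengths and constants above are this package's defaults, chosen
from standard QRS-detector practice; every one is configurable in
`DetectorParams`.

## Anomaly rules

* **Tachycardia**: strict `n·60000/Σ rr > 150` bpm over n = 5 beats. A
  window of exactly 150 bpm does not fire. n and the 50 ms margin below are
  package defaults; the 150 bpm rate and the 1.5 pause ratio are the rule
  family's standard constants.
* **SA block vs sinus pause**: both require a P-P interval more than 1.5×
  its predecessor. The remainder test splits them: a pause that is a
  near-multiple of the preceding P-P cycle (remainder within e = 50 ms) is
  an SA block — the sinus node kept its phase and dropped whole beats —
  while a non-multiple pause is a sinus pause. The remainder is compared
  symmetrically (min(rem, p_prev − rem) < e) so near-multiples are caught
  on both sides of the exact multiple; `symmetric_margin=False` restores
  the one-sided literal form. The split makes the two rules mutually
  exclusive by construction.
* **Sinus arrhythmia**: the package's operationalization of
  respiration-synchronized rate variation. A 16-beat window fires when
  (max − min)/mean exceeds 0.1, every interval lies within
  [median/1.5, median·1.5] (pause-scale outliers and rate steps belong to
  the other rules — physiologic respiratory modulation is a ±10–20% effect,
  never a 2× excursion), and the detrended window's Lomb-Scargle
  periodogram (Lomb-Scargle because beats sample time unevenly) peaks
  inside 0.15–0.4 Hz with normalized power ≥ 0.8. The coherence bound is
  what separates sustained sinusoidal modulation (measured peak power
  ≥ 0.92 for 15% modulation) from incoherent beat-to-beat jitter (99th
  percentile ≈ 0.72 for white 5% jitter among windows that already pass the
  range and band tests). Even so, 5% white jitter remains a tail risk: we
  measured one false arrhythmia alert in 90 clean 30 s records at that
  jitter level. At the 2–3% jitter typical of resting sinus rhythm the
  false-alert rate was zero in all sweeps.

The stream evaluator slides each rule over the beat sequence and
chain-deduplicates: triggers within n beats of the previous same-type
trigger extend the episode without a new alert, so one sustained episode
yields one alert. A rate *recovery* (e.g. 375 ms → 1000 ms at the end of a
tachycardia run) genuinely satisfies the pause rules' ratio test; this
rule-family interaction is inherent to interval-ratio rules and is why the
canned tachycardia scenario runs its episode to the record end.

## Synthetic generators

* **RSSI flats**: 2-D geometry with log-distance path loss
  (P₀ = −40 dBm at 1 m, exponent 2.5, Gaussian shadowing, truncated to
  [−100, −20] dBm, distances floored at 0.1 m). Geometry exists only inside
  the generator — the locator treats fingerprints as opaque — so walls and
  multipath are not modeled. Defaults match the study conditions: 3 access
  points, 6 fingerprints, 50 scans per fingerprint, 2 dBm noise. Real
  indoor shadowing is heavier-tailed and temporally correlated than i.i.d.
  Gaussian noise; passing the 95% recovery bound here shows the estimator
  is correct, not that any real flat will reach that accuracy.
* **Walking traces**: force magnitude 9.81 + A·sin(2π·cadence·t) during the
  bout (A = 1.0 m/s², cadence 2 Hz), 9.81 at rest, carried on the z axis so
  the vector norm is exact; optional Gaussian noise; true step times at the
  cycle troughs. Real gait is non-sinusoidal and device-orientation
  dependent; the trace exercises the threshold logic, not gait realism.
* **ECG**: each beat is five Gaussian bumps (R 1.0 mV/10 ms; Q,S
  −0.15 mV/10 ms at ∓25 ms; P 0.15 mV/25 ms at −160 ms; T 0.3 mV/60 ms at
  +250 ms) at 256 Hz, on an R-R sequence driven by base rate, multiplicative
  jitter and injectable events: a tachycardia episode, a dropped beat
  (exactly doubling one P-P interval), a non-multiple pause (×1.7), and
  sinusoidal respiratory modulation. Overlapping events are rejected.
  Ground truth is the scripted bump centers. The morphology has no QRS
  notching, no T-wave alternans, no baseline wander and no electrode
  artifacts, so detector performance here is an upper bound.

All generators take a single integer seed and are bit-reproducible.

## Evaluation harness

The holdout design draws two independent calibration sets per repetition
and scores every method in both train/test directions, yielding
correct-classification counts (the locator is evaluated without the
time-series stabilizer, which would need temporally ordered test scans).
The naive-Bayes baseline discretizes RSSI into 5 dBm bins anchored at the
imputation floor (64 bins cover the floor-to-0 range) with Laplace
smoothing; the SVM baseline is RBF with standardized inputs and C = 1 —
the bin width and kernel are package defaults since only the method names
are fixed by the design. Count rows are compared with the two-sided
Mann-Whitney U: normal approximation with midrank ties and continuity
correction by default (this is the variant whose p-values match the
packaged reference matrix bit-for-bit), exact permutation behind
`exact=True`.

## Problem sizes

The test suite and acceptance script use 30–60 s ECG records, 300 held-out
RSSI scans and ≤ 40-step walks — sizes at which every statistic under test
(recall/precision bounds, 95% recovery, exact counts) is already stable
across seeds, as the multi-seed sweeps in the tests confirm.

## Known limitations

* The locator assumes per-AP independence (the product form); correlated
  shadowing in real buildings violates this and typically flattens the
  probabilities.
* Single-pass outlier fences are not idempotent (documented above).
* The sinus-arrhythmia rule is a screening heuristic with a measured tail
  false-alert rate at high jitter; none of the rules constitute diagnosis.
* The step detector has no gait-frequency model: any signal crossing both
  thresholds counts, exactly as in the underlying threshold design.
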