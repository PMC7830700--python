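# Methods

## Signal model

The synthetic generator models surface EMG during a sustained contraction as
zero-mean, amplitude-modulated, band-limited Gaussian noise, independently
per channel. White Gaussian noise is shaped in the frequency domain (FFT
bins outside the acquisition band zeroed, 5–50 Hz by default at 250 Hz
sampling) and rescaled so the long-run RMS of each channel equals a
per-motion target amplitude in microvolts. This is the standard surrogate
at the level the pipeline consumes the signal — windowed RMS amplitude —
and matches the acquisition band of the hardware chain being emulated.

What it deliberately does **not** model: motor-unit action-potential
structure, amplitude non-stationarity within a hold, electrode shift
between sessions, fatigue drift, movement artifacts, or cross-channel
correlation. Passing tests therefore demonstrate that the pipeline
machinery (filtering, windowing, training, stream decoding, control) is
correct and deterministic, not that the classifier would reach the same
accuracy on real recordings, where class overlap is substantially larger.

### Default amplitude profiles

No amplitude statistics exist for the study's recordings (undeposited), so
the per-motion profiles are invented and labeled as such. They encode
distinct channel-dominance patterns at physiologically plausible surface
EMG magnitudes (tens of µV):

| motion        | ch1 | ch2 | ch3 | ch4 |
|---------------|-----|-----|-----|-----|
| Extension (E) | 80  | 15  | 12  | 10  |
| Rest (R)      |  8  |  8  |  8  |  8  |
| Spherical (S) | 30  | 60  | 45  | 22  |
| Fist (F)      | 55  | 95  | 80  | 60  |

With 125-sample windows of band-limited noise the window-RMS standard
deviation is roughly 10 % of the amplitude, so inter-class centroid
distances are many standard deviations: the four motions are linearly
separable in 4-channel RMS space ("high separation"). This is the regime
the benchmark accuracy figure is defined on.

### Protocol parameters

Trials: 20 s per trial, 30 trials per motion (10 min of signal per
motion). Sequences: two motions alternating every 5 s, 5 repetitions
(50 s, 10 segments), for the three pairs RE, RS, SF — together covering
every non-trivial allowed transition. The amplitude envelope cross-fades
linearly over 200 ms centered on each switch (muscle onset/offset is not
instantaneous; a nonzero ramp also exercises mixed-label window handling),
while the ground-truth label switches exactly at the segment boundary.
Trial sub-seeds are spawned from the master seed with
`numpy.random.SeedSequence.spawn`, so datasets are reproducible
trial-by-trial.

## Preprocessing

The acquisition-side filters are reproduced as a 4th-order Butterworth
band-pass (5–50 Hz) and a second-order IIR notch at 50 Hz with quality
factor 30, both applied forward–backward (`sosfiltfilt`/`filtfilt`) for
zero phase so per-sample labels stay aligned. The filter family and order
are a design choice (the original filtering happened inside the
acquisition GUI and is unspecified); the chosen orders meet the stated
attenuation contracts (DC rejected, <1 dB ripple within ±10 Hz of the
notch, ≥20 dB at 50 Hz). The first/last 250 ms are flagged in metadata as
transient-affected. Whether stored signals were already filtered upstream
cannot be known; the pipeline applies both filters by default and exposes
switches (`apply_filters`, `notch`) to skip them.

## Features

RMS over adjacent, disjoint 500-ms windows, contiguous from sample 0;
the trailing remainder is discarded (a stated convention — the source
procedure is silent on remainders). At 250 Hz each window holds
N = 125 samples and one second yields two feature vectors. Window labels
are the majority per-sample label, ties broken toward the earlier-starting
label. Single-motion trials produce pure windows by construction; mixed
windows occur only in sequence data around switches.

## Classifier

Architecture 4 → 128 → 32 → 4: ReLU hidden layers, dropout 0.4 after each
hidden layer (its exact placement is a choice; the source diagram does not
localize it), softmax output, categorical cross-entropy, mini-batch SGD
with batch 16 and learning rate 0.01. Implemented directly in numpy —
the network is tiny — with He-normal initialization, inverted dropout, and
Nesterov-free momentum (`v ← μv − lr·g`). One seeded generator drives
initialization, batch shuffling and dropout masks, so training is exactly
reproducible.

* **Standardization.** Inputs are z-scored per channel with training-split
  statistics, stored inside the model; prediction takes raw µV features.
* **Epochs.** 100 by default, no early stopping (unspecified upstream;
  recorded in the config).
* **Momentum/decay.** The reference settings print momentum 1e-6 and decay
  0.9 — transposed relative to conventional SGD practice. Under the printed
  values the schedule `lr_t = lr/(1 + 0.9·t)` collapses the learning rate
  within the first epoch and the network cannot fit even perfectly
  separable data (~67 % train accuracy), so the package defaults to the
  conventional reading (momentum 0.9, decay 1e-6) and keeps the printed
  variant available as `ClassifierConfig.reported_sgd()` for comparison.
* **Ties.** Argmax under the canonical ordering E < R < S < F, so exact
  probability ties resolve to the lowest class index.
* **Split.** Stratified 70/30 via scikit-learn; per-class counts are exact
  to within the global rounding of the splitter.

## State exclusion

The filter compares each new prediction against the previous **filtered**
state (not the previous raw prediction): this is the only reading of
"replace by the earlier one to maintain state" that guarantees the output
stream never contains a forbidden pair. The first element is always
accepted (no prior state exists). Consequences, all property-tested:
output validity, idempotence, and identity on already-valid streams.

The transition model is the 10-pair allowed set
{RR, EE, SS, FF, RE, ER, RS, SR, SF, FS}; its complement
{RF, SE, FR, FE, EF, ES} is forbidden (the glove cannot jump between
extension/fist extremes without passing through intermediate states). The
model is a config value and can be overridden, but all four self-pairs
must remain allowed.

**Loop counting.** "Recognized loop" is formalized as: at least one
consecutive window of A followed by at least one consecutive window of B
(in protocol order), closed by the next A run — which may open the next
episode — or by the end of the stream; any other motion mid-episode breaks
it. A perfect 5-repetition sequence yields 5 loops.

## Control simulation

Preset pressures: worn glove E −2, R 0, S 40, F 70 KPa; unloaded
actuators E −2, R 0, S 30, F 60 KPa (gauge pressure; vacuum negative).
Tolerance x is keyed to the **target** motion's class — 1 KPa when the
target is R or E, 5 KPa when it is S or F — the per-target keying being
the consistent generalization of the per-sequence phrasing upstream.

The plant is a constant slew rate per mode, the simplest model in which
fill time grows with target pressure: each tick (dt = 0.02 s) moves the
current pressure by rate·dt toward the target, capped at the target (no
overshoot beyond one tick). Defaults — supply 35 KPa/s (0→70 KPa in 2 s),
release 50 KPa/s, vacuum 10 KPa/s — are order-of-magnitude choices, not
constrained by any published value. Mode selection: within tolerance →
`closed`; pressure must rise toward a positive target → `supply` (also
from vacuum to positive); rise toward a non-positive target → `release`
(venting the vacuum); fall toward a non-negative target → `release`; fall
below atmospheric → `vacuum`. The exact branching for negative targets is
a stated reconstruction — the original controller logic for the
vacuum/release interplay is not published.

Commands are consumed strictly in order, each held until its target is
reached within tolerance plus a short settle (0.2 s); recognition-to-
actuation timing is deliberately decoupled (the system evaluated here is
offline), so the evaluation compares orderings and plateau pressures,
never latencies. An unreachable target raises a timeout after a
configurable tick budget rather than looping forever.

## Pipeline and determinism

`run_pipeline` chains generate → filter → featurize → split → train →
decode the three sequences → state-filter → evaluate → simulate pressure.
Per-stage seeds (corpus, split, network, one per sequence) are spawned
from the single global seed, so the whole run — including every written
artifact — is a pure function of config + seed. Stage failures propagate
wrapped with the stage name.

The default benchmark sizes (30 × 20 s trials per motion, three 50-s
sequences) run in under ten seconds on one CPU; unit tests use scaled-down
corpora (a few trials of a few seconds) since every property being checked
is scale-invariant.

## Known limitations

* The headline accuracy on the default synthetic benchmark (≈100 %) is a
  property of the separable regime, not a prediction of real-data
  performance; on real multi-subject recordings the same architecture is
  reported in the mid-90s before filtering.
* The state-exclusion filter can lock onto a wrong state for extended
  stretches if the classifier is badly wrong (it holds the previous state
  whenever the new prediction is impossible); it improves accuracy only
  when the underlying classifier is mostly right.
* The plant model has no pump dynamics, leakage, or actuator compliance;
  plateau values and ordering are meaningful, absolute fill times are
  only order-of-magnitude.
* Loop counting is strict about foreign motions mid-episode; alternative
  formalizations could count differently on degenerate streams.
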