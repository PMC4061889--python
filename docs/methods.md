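# Methods

This note records the models, conventions and design choices behind
`respeeg`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Synthetic recordings

The generator produces the study conditions the analysis is designed
for: a ~480 s voluntary-breathing session sampled at 256 Hz with two
scalp channels (C3, C4) and one pneumotachograph airflow channel.

**Airflow.** Each breath cycle is a positive half-sine inspiratory lobe
of duration `insp_fraction × period` followed by a negative half-sine
expiratory lobe for the remainder.  Half-sine lobes are the simplest
biphasic shape with unambiguous zero crossings.  Cycle periods are drawn
from a normal law truncated at ±3 sd (defaults 4.0 ± 0.5 s), which both
guarantees positive periods and ensures the shortest cycle (2.5 s) still
accommodates a 1 s analysis window inside each lobe of typical
proportions.  `insp_fraction` defaults to 0.4 — inspiration is the
shorter phase of a relaxed breath.  White Gaussian noise of sd
`flow_noise_sd` (default 0.05 of the unit lobe amplitude, a clean
pneumotachograph) is added on top.  The recording starts mid-expiration
(the second half of an expiratory lobe leads in), as a recording of
ongoing breathing does; this also means every true onset is an interior
sign change of the noise-free flow, detectable in principle.  True
onsets are the first (zero-valued) sample of each lobe.

**EEG.** Each channel is Gaussian background noise with a `1/f^γ` power
spectrum (γ = 1 by default), synthesised by spectral shaping in the
frequency domain and scaled to `background_scale` µV RMS (default 10 µV,
a typical resting scalp amplitude).  A phase-locked effect
(`EffectSpec`) adds band-limited Gaussian noise on one channel *only
during one breath phase*, over the full half-cycle rather than just the
analysis window, so that downstream epoch-placement choices cannot
manufacture or hide the effect.  The added band power is calibrated
against the expected background band power so that the expected
inspiration/expiration ratio of *total* band power equals
`power_ratio` (ratios below 1 boost expiration instead; ratio 1 adds
nothing).  Gating is abrupt at the phase boundary; the spectral
splatter this causes is ≲1 Hz wide (the envelope varies on a
multi-second scale) and is visible in practice as weak sidebands one
bin outside the nominal band.

**What is not emulated:** cardiac, ocular and muscular artifacts,
nonstationary drift of the background or of the effect, inter-channel
correlation, and any brainstem-source forward model.  Passing tests on
this generator therefore demonstrate correctness of the *analysis* under
its stated assumptions — phase-locked stationary band-power differences
in stationary 1/f noise — not performance on clinical recordings.

## Airflow segmentation

1. **Smoothing:** zero-phase (forward–backward) 6th-order Butterworth
   low-pass, cutoff 20 Hz.  Forward–backward application squares the
   magnitude response, giving ≥20 dB attenuation at 1.25× the cutoff
   with <0.3 dB passband droop below 0.75×, and exactly zero phase so
   onset timing is not delayed.
2. **Zero crossings:** a crossing is the last sample with the old sign
   (exact zeros, within a dead band of 10⁻⁹ of the signal peak, attach
   to the old side — so the reported index is the last zero-valued
   sample before the new lobe).  A crossing counts only once the signal
   has travelled beyond ±`hysteresis` on the new side; the default
   hysteresis is 2% of the 95th percentile of |flow|.  Lobes shorter
   than `min_cycle / 2` (default `min_cycle` 1.5 s) are merged into
   their neighbours.  Both guards exist because a literal zero-crossing
   scan on noisy flow produces chatter; they only remove crossings,
   never add them, so increasing either never increases the cycle count.
3. **Onset refinement:** around each accepted crossing a local template
   — two half-sine arcs meeting at zero, with amplitude and duration
   *fixed* from the flanking lobes (peak value and inter-crossing
   extent; a flank truncated by a recording edge uses twice the
   crossing-to-peak distance as its duration) — is slid over ±0.1 s in
   one-sample steps, the squared error is minimised, and a parabolic
   interpolation gives the sub-sample crossing, rounded to the nearest
   sample.  Because the template's only free parameter is the crossing
   time, the estimator uses nearly all of the local information about
   the crossing and approaches the matched-filter bound: at 10% flow
   noise the onset jitter is ≈6.5 ms sd (worst ≤ ~25 ms over hundreds of
   onsets), versus ≈20 ms sd for the raw crossing of the smoothed
   signal; on noise-free data the refined onsets are exact.  The
   polarity convention is positive flow = inspiration; `invert=True`
   flips a reversed transducer.

Cycles start with inspiration: anything before the first rising
crossing is discarded, and a recording with fewer than one complete
cycle yields an empty result with a warning.

## Epochs

Epochs start exactly at the onset sample ("the beginning of the phase")
and span 1 s by default.  An epoch is dropped if it would run past the
end of the recording or past the next opposite-phase onset — dropping,
not truncating, keeps all epochs the same length and prevents label
contamination.  Class balancing (on by default) truncates the larger
class by removing its latest epochs, reproducing the 120/120 design.
No artifact rejection is applied by default; an optional peak-to-peak
threshold exists but is off, since the reference protocol used raw
Cz-referenced signals.

## Spectral features

Plain DFT with a rectangular window after mean removal; no taper, no
zero padding, no Welch averaging, no log transform — the feature is the
raw power spectrum of the single trial.  Powers are one-sided and
normalised as `|X_k|²/N²`, doubled for `0 < k < N/2`, so a
unit-amplitude sinusoid at an integer bin yields 1/2 regardless of
window length and the powers sum to the demeaned epoch's mean square
(Parseval; asserted to 10⁻⁹ relative error in the tests).  Mean removal
prevents amplifier DC offset from dominating the 0 Hz feature.  With a
1 s window the grid is 1 Hz from 0 to 128 Hz inclusive, 129 bins per
channel, ordered channel-major.  Any consistent normalisation works —
DP ranking is invariant to monotone per-feature transforms and the SVM
standardizes per feature — but the convention is fixed and documented
so that numbers are comparable across runs.

## Discriminative power

`DP(a, b)` is the largest fraction of one class lying strictly beyond
the other class's extreme value, maximised over the four one-sided
rules (either class targeted, either direction).  Strict inequalities
make the zero-false-positive guarantee literal: a value tied with the
opposing extreme counts as a false positive and is excluded.  The
symmetric four-rule maximum is used because neither class nor direction
is privileged in the protocol.  This is a training-sample estimate —
extremes are taken on the data the rule is evaluated on — which is why
the cross-validation recomputes it inside each training fold.  Ties in
the ranking break by ascending feature index, making top-k selection
deterministic.  The implementation is verified against an exhaustive
threshold-scan oracle on 1,000 random instances.

## Classification and cross-validation

Soft-margin linear SVM (hinge loss, L2 penalty, solver tolerance 10⁻⁴)
with C = 1.0, not tuned — the protocol reports no hyperparameter
search, and adding an inner CV would change the question being asked.
Folds are stratified (protecting the 120/120 balance) and shuffled by a
caller-supplied seed; fold construction is otherwise unspecified in the
reference protocol, so results are reported together with the seed.
Per-fold feature standardization (train-fold mean/sd; constant features
pass through unscaled) is applied because raw powers span orders of
magnitude across the 0–128 Hz grid; it is computed strictly on training
rows.  The headline number is the unweighted mean of the per-fold
accuracies.  Reported behaviour on the generator: ≈0.91–0.96 mean
accuracy over seeds for a 15–25 Hz power-ratio-4 effect on C3, chance
(inside the central 99% binomial band around 0.5) for null data.

## Online trigger simulation

The detector is the same feature/selection/SVM stack trained on one
session, slid over a continuous recording with a given step (default
125 ms).  A trigger fires when the predicted phase switches from
expiration to inspiration, with two guards: a refractory period
(default 1.5 s — a breath cannot restart faster than the shortest
credible cycle) and an optional `confirm` count requiring the switch to
be sustained over consecutive windows.  Single-window decisions carry a
few percent error even on strongly separable data, so `confirm=2` is
the practical setting for clean one-trigger-per-breath behaviour; the
decision latency is bounded by `window + confirm × step` for breaths
whose first windows carry the effect, and can occasionally extend
further into the inspiratory phase when the band-limited effect starts
weak in a particular cycle.  A step larger than the refractory period
is rejected: such a scan cannot resolve individual cycles.

## Feature stability and parameter recovery

`feature_stability` counts how often each feature is selected across
folds.  Two facts matter when reading it: (i) with 10 folds any two
training sets share 8/9 of the trials, so even on effect-free data the
chance DP ranking is strongly correlated across folds and ~20–25
features are typically selected in all 10 folds; (ii) what
distinguishes a real effect is not the existence of stable features but
their *concentration* — with an injected band the always-selected set
concentrates on the injected channel/band, while on null data it
scatters over the whole (channel, frequency) grid.  The
parameter-recovery check therefore uses a strong wide-band effect
(C3, 8–48 Hz, ratio 8), whose width is comparable to the 60 selection
slots: ≥80% of always-selected features then fall inside the injected
band (measured 0.85–0.95 across seeds).  With a narrow 11-bin band the
fold-stable chance features cap that fraction near 40% regardless of
effect strength — a property of the selection protocol, not a failure
of recovery.

## File formats

EDF reading goes through `mne`; writing uses a minimal built-in 16-bit
EDF encoder (one data record per second, per-channel physical scaling,
fixed header date so seeded runs are byte-identical; recordings are
truncated to whole seconds, as EDF has no partial records).  Round-trip
error is bounded by the per-channel quantization step
`(max − min)/(2¹⁶ − 1)`.  Cycles, features and rankings are TSV; epochs
are NPZ (bit-exact round-trip); CV results and experiment reports are
JSON without timestamps, so re-running a seeded experiment reproduces
the report byte for byte.

## Problem sizes

Default experiments use 120 breath cycles (~8 min of signal, 240
epochs) — the size of the design the pipeline reproduces.  Property
tests that only need statistical power, not the exact design, run at 30
to 60 cycles; the calibration test for the effect ratio uses 160 cycles
(do not shorten it: the phase-conditioned Welch estimate needs ≥600 s to
come within 15% of the target ratio).
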