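# respeeg

Can the inspiratory and expiratory periods of voluntary breathing be told
apart from scalp EEG?  If they can, a brain signal — rather than airway
pressure or flow — could one day trigger a mechanical ventilator, helping
patients whose effort the machine fails to sense.  `respeeg` implements the
complete offline analysis needed to ask that question of a recording in
which EEG (e.g. C3 and C4 referenced to Cz, 256 Hz) is acquired
simultaneously with a pneumotachograph airflow signal, plus a synthetic
airflow + EEG generator with known ground truth so that every stage of the
analysis can be validated quantitatively.

It is intended for researchers in neurophysiological signal processing and
brain-computer interfacing who want a tested, reproducible baseline for
respiratory-phase EEG classification.

## Method

1. **Airflow segmentation.** The flow signal is smoothed by a zero-phase
   low-pass below 20 Hz; inspiratory/expiratory cycles are identified from
   the zero crossings of the smoothed flow (with a hysteresis noise guard
   and a minimum-lobe-duration rule), and each phase onset is the zero
   preceding the positive (inspiration) or negative (expiration) lobe,
   refined by a local sine-template fit.
2. **Epochs.** One-second EEG windows are cut starting exactly at each
   onset and labelled by phase: with ~120 cycles this gives the balanced
   240-trial design (120 inspiration + 120 expiration).
3. **Features.** Each epoch/channel is demeaned and Fourier transformed;
   the features are the one-sided DFT powers
   `P_k = 2 |X_k|^2 / N^2` on a 1 Hz grid from 0 Hz to the Nyquist
   frequency (128 Hz) — 258 features for two channels.
4. **Feature ranking.** Each feature's *discriminative power* (DP) is the
   best true-positive rate a single-feature threshold rule can reach with
   zero false positives on the training sample:
   `DP(a, b) = max( |{a < min b}|/|a|, |{a > max b}|/|a|, |{b < min a}|/|b|, |{b > max a}|/|b| )`.
5. **Classification.** The top-60 features by DP feed a soft-margin linear
   SVM (hinge loss, C = 1); performance is the correct-classification rate
   averaged over stratified 10-fold cross-validation, with the DP ranking,
   top-60 selection and feature standardization all recomputed inside each
   training fold so that no information leaks from the held-out trials.

A small online demo (`simulate_online_triggers`) slides the trained
classifier over a continuous recording and fires a trigger at each
expiration-to-inspiration switch — the decision loop a neurally triggered
ventilator would run.

## Worked example

```python
from respeeg import (CVConfig, EffectSpec, GeneratorConfig, crossvalidate,
                     extract_epochs, generate_recording, rank_features,
                     segment_airflow, spectral_features)

syn = generate_recording(
    GeneratorConfig(seed=1, effects=(EffectSpec("C3", 15, 25, 4.0),)))
epochset = extract_epochs(syn.recording,
                          segment_airflow(syn.recording.flow_trace()))
feats = spectral_features(epochset)
print(rank_features(feats).to_frame().head(5).to_string(index=False))
cv = crossvalidate(feats, CVConfig(seed=1))
print(f"mean CV accuracy: {cv.mean_accuracy:.3f}")
```

prints

```
 rank  feature  name  dp_score
    0       23 C3:23  0.333333
    1       17 C3:17  0.300000
    2       16 C3:16  0.275000
    3       25 C3:25  0.266667
    4       20 C3:20  0.225000
mean CV accuracy: 0.921
```

The generator injected four-fold extra 15–25 Hz power on C3 during
inspiration; the DP ranking puts exactly those bins on top (a DP of 0.33
means the best zero-false-positive threshold on that single feature
already captures a third of one class), and the cross-validated linear SVM
recognises the breath phase of 92% of held-out one-second trials.
See `examples/` for one narrative script per capability, including EDF
import/export and the online trigger simulation.

## Command line

Each stage is also a subcommand of the `respeeg` console script —
`synthgen`, `flowseg`, `epochs`, `features`, `dpselect`, `classify`, and
`run` (full experiment from a YAML config); intermediates travel between
stages as EDF/TSV/NPZ/JSON files.  `respeeg <command> --help` shows the
options.

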