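"""Rank features by discriminative power and cross-validate a linear SVM.

The discriminative power (DP) of a feature is the best true-positive
rate a single-feature threshold rule can reach at *zero* false
positives on the training sample.  The top 60 features — re-selected
inside every training fold to avoid selection bias — feed a linear SVM
evaluated by stratified 10-fold cross-validation.
"""

from respeeg import (
    CVConfig,
    EffectSpec,
    GeneratorConfig,
    crossvalidate,
    extract_epochs,
    generate_recording,
    rank_features,
    segment_airflow,
    spectral_features,
)

syn = generate_recording(
    GeneratorConfig(seed=1, effects=(EffectSpec("C3", 15, 25, 4.0),))
)
epochset = extract_epochs(syn.recording, segment_airflow(syn.recording.flow_trace()))
feats = spectral_features(epochset)

ranking = rank_features(feats)
print("top 5 features by discriminative power:")
print(ranking.to_frame().head(5).to_string(index=False))
print("(all inside the injected C3 band — the ranking recovers the effect)")

cv = crossvalidate(feats, CVConfig(seed=1))
print(f"\nfold accuracies: {[round(float(a), 3) for a in cv.fold_accuracies]}")
print(f"mean CV accuracy: {cv.mean_accuracy:.3f}")
print("(fraction of held-out epochs whose breath phase the SVM predicts"
      " correctly, averaged over the 10 folds)")
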