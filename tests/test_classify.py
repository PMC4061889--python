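"""Linear SVM training, nested cross-validation, and the online trigger demo."""

import numpy as np
import pytest

from respeeg import (
    CVConfig,
    EffectSpec,
    FeatureMatrix,
    GeneratorConfig,
    crossvalidate,
    extract_epochs,
    fit_detector,
    generate_recording,
    segment_airflow,
    simulate_online_triggers,
    spectral_features,
    train_linear_classifier,
)
from respeeg.epochs import EXPIRATION, INSPIRATION

from conftest import run_pipeline


def gaussian_clouds(n=100, d=2, sep=10.0, spread=0.5, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(scale=spread, size=(n, d))
    b = rng.normal(scale=spread, size=(n, d))
    a[:, 0] += sep / 2
    b[:, 0] -= sep / 2
    X = np.vstack([a, b])
    y = np.array([INSPIRATION] * n + [EXPIRATION] * n, dtype=object)
    return X, y


class TestLinearClassifier:
    def test_separable_clouds_perfect_training_accuracy(self):
        X, y = gaussian_clouds()
        model = train_linear_classifier(X, y)
        assert np.mean(model.predict(X).astype(str) == y.astype(str)) == 1.0

    def test_weight_vector_aligned_with_separating_axis(self):
        """For symmetric clouds split along axis 0 the max-margin normal
        is that axis; the fitted weights should be within 5 degrees."""
        X, y = gaussian_clouds(sep=8.0, spread=0.4, seed=1)
        model = train_linear_classifier(X, y)
        w = model.weights / np.linalg.norm(model.weights)
        cos = abs(w[0])
        assert np.degrees(np.arccos(min(cos, 1.0))) < 5.0

    def test_duplicated_points_leave_boundary_unchanged(self):
        X, y = gaussian_clouds(seed=2)
        m1 = train_linear_classifier(X, y)
        m2 = train_linear_classifier(np.vstack([X, X]), np.concatenate([y, y]))
        w1 = np.append(m1.weights, m1.bias)
        w2 = np.append(m2.weights, m2.bias)
        assert np.allclose(w1 / np.linalg.norm(w1), w2 / np.linalg.norm(w2), atol=1e-3)

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        y = np.array([INSPIRATION] * 5, dtype=object)
        with pytest.raises(ValueError, match="two classes"):
            train_linear_classifier(X, y)


class TestCrossValidation:
    def test_every_epoch_tested_exactly_once(self, strong_pipeline):
        _, _, _, feats, cv = strong_pipeline
        assert cv.fold_assignment.size == 240
        assert np.all(cv.fold_assignment >= 0)
        counts = np.bincount(cv.fold_assignment, minlength=10)
        assert counts.tolist() == [24] * 10  # near-equal stratified folds

    def test_mean_is_mean_of_fold_accuracies(self, strong_pipeline):
        _, _, _, _, cv = strong_pipeline
        assert cv.mean_accuracy == pytest.approx(np.mean(cv.fold_accuracies), abs=1e-12)

    def test_each_fold_selects_k_features(self, strong_pipeline):
        _, _, _, _, cv = strong_pipeline
        assert len(cv.fold_feature_sets) == 10
        for selected in cv.fold_feature_sets:
            assert selected.size == 60
            assert np.unique(selected).size == 60

    def test_deterministic_given_seed(self, strong_pipeline):
        _, _, _, feats, cv = strong_pipeline
        again = crossvalidate(feats, CVConfig(seed=1))
        assert np.array_equal(again.fold_accuracies, cv.fold_accuracies)
        assert np.array_equal(again.fold_assignment, cv.fold_assignment)
        for a, b in zip(again.fold_feature_sets, cv.fold_feature_sets):
            assert np.array_equal(a, b)

    def test_no_leakage_from_test_fold(self, strong_pipeline):
        """Replacing a test fold's values with garbage must not change that
        fold's feature selection: the selector sees training rows only.
        (The perturbed rows are training rows for every *other* fold, so
        only the perturbed fold's own selection is claimed invariant.)"""
        _, _, _, feats, cv = strong_pipeline
        for fold in (0, 3, 7):
            mask = cv.fold_assignment == fold
            perturbed = feats.values.copy()
            perturbed[mask] = (
                1e6 * np.random.default_rng(fold).normal(size=perturbed[mask].shape) ** 2
            )
            fm = FeatureMatrix(perturbed, feats.index, feats.labels)
            cv2 = crossvalidate(fm, CVConfig(seed=1))
            assert np.array_equal(cv2.fold_assignment, cv.fold_assignment)
            assert np.array_equal(cv2.fold_feature_sets[fold], cv.fold_feature_sets[fold])

    def test_permuted_labels_give_chance_accuracy(self, strong_pipeline):
        """Label permutation destroys the phase information: accuracy must
        fall inside the central 99% binomial interval around 0.5."""
        _, _, _, feats, _ = strong_pipeline
        rng = np.random.default_rng(42)
        fm = FeatureMatrix(feats.values, feats.index, feats.labels[rng.permutation(240)])
        cv = crossvalidate(fm, CVConfig(seed=1))
        half_width = 2.576 * np.sqrt(0.25 / 240)
        assert abs(cv.mean_accuracy - 0.5) <= half_width

    def test_more_folds_than_epochs_rejected(self, strong_pipeline):
        _, _, _, feats, _ = strong_pipeline
        with pytest.raises(ValueError):
            crossvalidate(feats, CVConfig(n_folds=500))

    def test_accuracy_monotone_in_effect_strength(self):
        """Mean CV accuracy (10-seed batch mean) is non-decreasing in the
        injected power ratio, allowing one adjacent inversion."""
        ratios = [1.0, 1.5, 2.0, 4.0]
        batch = np.zeros((10, len(ratios)))
        for s, seed in enumerate(range(1, 11)):
            for r, ratio in enumerate(ratios):
                effects = () if ratio == 1.0 else (EffectSpec("C3", 15, 25, ratio),)
                cfg = GeneratorConfig(seed=seed, n_cycles=60, effects=effects)
                *_, cv = run_pipeline(cfg)
                batch[s, r] = cv.mean_accuracy
        means = batch.mean(axis=0)
        inversions = sum(a > b for a, b in zip(means, means[1:]))
        assert inversions <= 1
        assert means[-1] > means[0] + 0.2  # the strong effect clearly helps


@pytest.fixture(scope="module")
def detector_and_recording():
    effect = EffectSpec("C3", 15, 25, 16.0)
    train_cfg = GeneratorConfig(seed=2, effects=(effect,), flow_noise_sd=0.0)
    syn = generate_recording(train_cfg)
    rec = syn.recording
    epochset = extract_epochs(rec, segment_airflow(rec.flow_trace()))
    detector = fit_detector(
        spectral_features(epochset), rec.channel_names, epochset.window, rec.rate
    )
    test_cfg = GeneratorConfig(seed=33, n_cycles=40, effects=(effect,), flow_noise_sd=0.0)
    return detector, generate_recording(test_cfg)


class TestOnlineTriggers:
    def test_one_trigger_per_inspiratory_onset(self, detector_and_recording):
        detector, syn = detector_and_recording
        out = simulate_online_triggers(
            detector,
            syn.recording,
            step=0.125,
            confirm=2,
            refractory=2.0,
            true_insp_onsets=syn.true_insp_onsets,
        )
        assert out["n_triggers"] == syn.true_insp_onsets.size
        assert np.unique(out["matched_onsets"]).size == syn.true_insp_onsets.size
        # decisions confirm within the inspiratory phase; most by the first
        # window that fits entirely inside it
        assert out["latency_max"] <= 0.5 * 4.0
        assert float(np.median(out["latencies"])) <= 1.0 + 2 * 0.125

    def test_null_recording_triggers_at_baseline_rate(self):
        cfg = GeneratorConfig(seed=5, n_cycles=30)
        syn = generate_recording(cfg)
        rec = syn.recording
        epochset = extract_epochs(rec, segment_airflow(rec.flow_trace()))
        feats = spectral_features(epochset)
        detector = fit_detector(feats, rec.channel_names, epochset.window, rec.rate)
        probe = generate_recording(GeneratorConfig(seed=55, n_cycles=30)).recording
        observed = simulate_online_triggers(detector, probe, step=0.25)["n_triggers"]
        # permutation baseline: detectors trained on label-shuffled epochs
        rng = np.random.default_rng(99)
        baseline = []
        from respeeg import FeatureMatrix

        for _ in range(10):
            fm = FeatureMatrix(
                feats.values, feats.index, feats.labels[rng.permutation(len(feats.labels))]
            )
            det = fit_detector(fm, rec.channel_names, epochset.window, rec.rate)
            baseline.append(simulate_online_triggers(det, probe, step=0.25)["n_triggers"])
        lo, hi = np.min(baseline), np.max(baseline)
        spread = max(hi - lo, 5)
        assert lo - spread <= observed <= hi + spread

    def test_oversized_step_rejected(self, detector_and_recording):
        detector, syn = detector_and_recording
        with pytest.raises(ValueError, match="step"):
            simulate_online_triggers(detector, syn.recording, step=5.0)

    def test_channel_mismatch_rejected(self, detector_and_recording):
        detector, syn = detector_and_recording
        rec = syn.recording
        from respeeg import Recording

        renamed = Recording(rec.eeg, ["F3", "F4"], rec.flow, rec.rate)
        with pytest.raises(ValueError, match="channel"):
            simulate_online_triggers(detector, renamed)
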