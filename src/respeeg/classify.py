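"""Linear-SVM classification with nested feature selection.

The evaluation protocol is 10-fold cross-validation in which everything
learned from data — the discriminative-power feature ranking, the top-k
selection, and the per-feature standardization statistics — is computed
on the nine training folds only, then applied frozen to the held-out
fold.  The reported figure is the correct-classification rate averaged
over the folds.

A small online demo (:func:`simulate_online_triggers`) slides a window
over a continuous recording, classifies each position with a trained
detector, and emits a trigger whenever the predicted phase switches
from expiration to inspiration — the decision loop a brain-driven
ventilator trigger would run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .dpselect import rank_features, select_top
from .epochs import EXPIRATION, INSPIRATION, Recording
from .features import FeatureMatrix

__all__ = [
    "CVConfig",
    "CVResult",
    "LinearModel",
    "OnlineDetector",
    "train_linear_classifier",
    "crossvalidate",
    "fit_detector",
    "simulate_online_triggers",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol parameters.

    ``k_features`` is the number of top-DP features passed to the SVM in
    each fold; ``regularization`` is the soft-margin constant C (not
    tuned — no inner CV); ``standardize`` controls per-feature z-scoring
    with train-fold statistics.
    """

    n_folds: int = 10
    k_features: int = 60
    regularization: float = 1.0
    standardize: bool = True
    stratified: bool = True
    seed: int = 0

    def validate(self, n_epochs: int) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_folds > n_epochs:
            raise ValueError(
                f"cannot make {self.n_folds} folds from {n_epochs} epochs"
            )
        if self.regularization <= 0:
            raise ValueError("regularization must be positive")
        if self.k_features < 1:
            raise ValueError("k_features must be at least 1")


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: np.ndarray
    mean_accuracy: float
    fold_feature_sets: list[np.ndarray]  # per fold, selected feature indices
    fold_assignment: np.ndarray  # per epoch, its test-fold id
    feature_index: list[tuple[str, float]] | None = None

    def to_dict(self) -> dict:
        out = {
            "mean_accuracy": float(self.mean_accuracy),
            "fold_accuracies": [float(x) for x in self.fold_accuracies],
            "fold_assignment": self.fold_assignment.tolist(),
            "fold_feature_sets": [f.tolist() for f in self.fold_feature_sets],
        }
        if self.feature_index is not None:
            out["fold_feature_names"] = [
                [f"{self.feature_index[j][0]}:{self.feature_index[j][1]:g}" for j in f]
                for f in self.fold_feature_sets
            ]
        return out

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass(frozen=True)
class LinearModel:
    """Affine decision rule: predict class 1 when ``w @ x + b > 0``."""

    weights: np.ndarray
    bias: float
    classes: tuple[str, str]  # (negative, positive)

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        pos = self.decision(X) > 0
        return np.where(pos, self.classes[1], self.classes[0]).astype(object)


_SVM_TOL = 1e-4


def train_linear_classifier(
    X: np.ndarray, y, regularization: float = 1.0
) -> LinearModel:
    """Fit a soft-margin linear SVM (hinge loss, L2 penalty).

    ``X`` is expected to be restricted to the selected features and, if
    desired, already standardized.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = np.unique(y.astype(str))
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.tolist()}")
    svc = SVC(kernel="linear", C=regularization, tol=_SVM_TOL)
    svc.fit(X, y.astype(str))
    return LinearModel(
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        classes=(str(svc.classes_[0]), str(svc.classes_[1])),
    )


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant features pass through unscaled
    return mean, sd


def crossvalidate(
    features: FeatureMatrix, config: CVConfig | None = None
) -> CVResult:
    """k-fold cross-validation with per-fold feature selection.

    Folds are near-equal, stratified by label when configured, and
    shuffled by the config seed.  Within each fold the DP ranking,
    top-k selection and standardization statistics are learned on the
    training folds only.
    """
    if config is None:
        config = CVConfig()
    X, y = features.values, features.labels
    n = X.shape[0]
    config.validate(n)
    if np.unique(y.astype(str)).size != 2:
        raise ValueError("exactly two classes required")

    if config.stratified:
        splitter = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
    else:
        splitter = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)

    fold_acc = np.empty(config.n_folds)
    fold_sets: list[np.ndarray] = []
    assignment = np.full(n, -1, dtype=np.int64)
    for f, (train, test) in enumerate(splitter.split(X, y.astype(str))):
        if np.unique(y[train].astype(str)).size != 2:
            raise ValueError(f"training fold {f} contains a single class")
        ranking = rank_features(X[train], y[train])
        selected = select_top(ranking, config.k_features)
        Xtr, Xte = X[train][:, selected], X[test][:, selected]
        if config.standardize:
            mean, sd = _standardize_params(Xtr)
            Xtr = (Xtr - mean) / sd
            Xte = (Xte - mean) / sd
        model = train_linear_classifier(Xtr, y[train], config.regularization)
        pred = model.predict(Xte)
        fold_acc[f] = float(np.mean(pred.astype(str) == y[test].astype(str)))
        fold_sets.append(np.asarray(selected, dtype=np.int64))
        assignment[test] = f

    return CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(fold_acc.mean()),
        fold_feature_sets=fold_sets,
        fold_assignment=assignment,
        feature_index=features.index,
    )


# ---------------------------------------------------------------------------
# online trigger simulation


@dataclass(frozen=True)
class OnlineDetector:
    """A trained phase detector bound to its feature bookkeeping."""

    model: LinearModel
    selected: np.ndarray  # indices into the full (channel, Hz) feature grid
    feature_index: list[tuple[str, float]]
    channel_names: list[str]
    window: float
    rate: float
    mean: np.ndarray | None  # standardization statistics (None if off)
    sd: np.ndarray | None


def fit_detector(
    features: FeatureMatrix,
    channel_names: list[str],
    window: float,
    rate: float,
    config: CVConfig | None = None,
) -> OnlineDetector:
    """Train an online detector on a full feature matrix (no held-out set)."""
    if config is None:
        config = CVConfig()
    ranking = rank_features(features)
    selected = select_top(ranking, config.k_features)
    X = features.values[:, selected]
    mean = sd = None
    if config.standardize:
        mean, sd = _standardize_params(X)
        X = (X - mean) / sd
    model = train_linear_classifier(X, features.labels, config.regularization)
    return OnlineDetector(
        model=model,
        selected=np.asarray(selected, dtype=np.int64),
        feature_index=features.index,
        channel_names=list(channel_names),
        window=window,
        rate=rate,
        mean=mean,
        sd=sd,
    )


def _window_features(segment: np.ndarray) -> np.ndarray:
    """One-sided DFT power of one window, matching ``spectral_features``."""
    n = segment.shape[1]
    demeaned = segment - segment.mean(axis=1, keepdims=True)
    power = np.abs(np.fft.rfft(demeaned, axis=1)) ** 2 / n**2
    power[:, 1:] *= 2.0
    if n % 2 == 0:
        power[:, -1] /= 2.0
    return power.ravel()


def simulate_online_triggers(
    detector: OnlineDetector,
    recording: Recording,
    step: float = 0.125,
    refractory: float = 1.5,
    confirm: int = 1,
    true_insp_onsets: np.ndarray | None = None,
) -> dict:
    """Slide the detector over a recording and emit inspiration triggers.

    A trigger fires at the end of the first window whose prediction
    switches from expiration to inspiration; subsequent switches within
    ``refractory`` seconds are suppressed (a breath cannot restart
    faster than the shortest credible cycle).  ``confirm > 1`` debounces
    the decision: the switch must be sustained for that many consecutive
    windows before the trigger fires (at the end of the confirming
    window, adding ``(confirm - 1) * step`` latency).  When ground-truth
    inspiratory onsets are supplied, each trigger is matched to the
    nearest preceding onset and the latency summary is reported.

    Returns a dict with ``trigger_times`` (seconds, decision time =
    window end), ``n_triggers``, and — when truth is given —
    ``latencies`` and ``latency_mean``/``latency_max``.
    """
    if list(recording.channel_names) != list(detector.channel_names):
        raise ValueError(
            f"channel mismatch: detector {detector.channel_names}, "
            f"recording {recording.channel_names}"
        )
    if abs(recording.rate - detector.rate) > 1e-9:
        raise ValueError("sampling-rate mismatch between detector and recording")
    if step <= 0:
        raise ValueError("step must be positive")
    if step > refractory:
        raise ValueError(
            f"step ({step} s) exceeds the refractory period ({refractory} s); "
            "a slower scan cannot resolve individual breath cycles"
        )
    n_win = int(round(detector.window * recording.rate))
    n_step = max(int(round(step * recording.rate)), 1)
    starts = np.arange(0, recording.n_samples - n_win + 1, n_step)

    if confirm < 1:
        raise ValueError("confirm must be at least 1")
    triggers: list[float] = []
    last_trigger = -np.inf
    armed = True  # becomes True again once an expiration window is seen
    run = 0  # consecutive inspiration windows since arming
    for s in starts:
        x = _window_features(recording.eeg[:, s : s + n_win])[detector.selected]
        if detector.mean is not None:
            x = (x - detector.mean) / detector.sd
        label = str(detector.model.predict(x[None, :])[0])
        t_decision = (s + n_win) / recording.rate
        if label == INSPIRATION:
            run += 1
            if armed and run >= confirm and t_decision - last_trigger >= refractory:
                triggers.append(t_decision)
                last_trigger = t_decision
                armed = False
        else:
            run = 0
            armed = True

    out: dict = {"trigger_times": np.asarray(triggers), "n_triggers": len(triggers)}
    if true_insp_onsets is not None and len(triggers):
        onset_times = np.asarray(true_insp_onsets, dtype=float) / recording.rate
        latencies = []
        matched = []
        for t in triggers:
            prior = onset_times[onset_times <= t]
            if prior.size:
                latencies.append(t - prior[-1])
                matched.append(int(np.searchsorted(onset_times, t, side="right") - 1))
        out["latencies"] = np.asarray(latencies)
        out["matched_onsets"] = np.asarray(matched, dtype=np.int64)
        if latencies:
            out["latency_mean"] = float(np.mean(latencies))
            out["latency_max"] = float(np.max(latencies))
    return out
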