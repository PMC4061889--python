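"""End-to-end experiment orchestration.

``run_experiment`` executes generate-or-load → segment → epoch →
featurize → cross-validate under a single config, persists every
intermediate artifact in a standard format, and emits a machine-readable
JSON report plus a short human-readable summary.  The report contains
no timestamps, so re-running an identical (seeded) config produces a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import epochs as _epochs
from . import synthgen as _synthgen
from .classify import CVConfig, CVResult, crossvalidate
from .epochs import EXPIRATION, INSPIRATION, Recording, extract_epochs, read_recording
from .features import FeatureMatrix, spectral_features, write_features
from .flowseg import segment_airflow
from .synthgen import GeneratorConfig, SyntheticRecording, generate_recording

__all__ = [
    "SegmentationConfig",
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "feature_stability",
]

log = logging.getLogger("respeeg")


@dataclass(frozen=True)
class SegmentationConfig:
    cutoff: float = 20.0
    hysteresis: float | None = None  # None = automatic noise guard
    min_cycle: float = 1.5
    invert: bool = False


@dataclass(frozen=True)
class ExperimentConfig:
    """One experiment: either a generator config or a recording path."""

    generator: GeneratorConfig | None = None
    recording_path: str | None = None
    recording_format: str | None = None
    flow_channel: str = "Flow"
    rate: float | None = None  # required for delimited recordings
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    window: float = 1.0
    balance: bool = True
    cv: CVConfig = field(default_factory=CVConfig)

    def validate(self) -> None:
        if (self.generator is None) == (self.recording_path is None):
            raise ValueError(
                "exactly one input mode must be set: generator or recording_path"
            )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            effects = tuple(
                _synthgen.EffectSpec(**e) for e in gen.pop("effects", [])
            )
            gen = GeneratorConfig(effects=effects, **gen)
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        cv = CVConfig(**raw.pop("cv", {}))
        return cls(generator=gen, segmentation=seg, cv=cv, **raw)


@dataclass(frozen=True)
class ExperimentReport:
    n_cycles: int
    epoch_counts: dict[str, int]
    n_features: int
    fold_accuracies: list[float]
    mean_accuracy: float
    top_recurrent_features: list[tuple[str, int]]
    config: dict
    onset_errors_ms: dict | None = None  # only for synthetic inputs

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def summary(self) -> str:
        lines = [
            f"cycles detected:        {self.n_cycles}",
            f"epochs per class:       "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.epoch_counts.items())),
            f"features per epoch:     {self.n_features}",
            f"fold accuracies:        "
            + " ".join(f"{a:.3f}" for a in self.fold_accuracies),
            f"mean CV accuracy:       {self.mean_accuracy:.3f}",
            "most recurrent features (feature, folds selected):",
        ]
        for name, count in self.top_recurrent_features[:10]:
            lines.append(f"  {name:>12s}  {count}")
        if self.onset_errors_ms is not None:
            lines.append(
                "onset error vs truth:   max |{max_abs:.1f}| ms, sd {sd:.1f} ms".format(
                    **self.onset_errors_ms
                )
            )
        return "\n".join(lines)


def feature_stability(
    fold_feature_sets: list[np.ndarray],
    feature_index: list[tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Count how many folds selected each feature, sorted descending."""
    counts: dict[int, int] = {}
    for fold in fold_feature_sets:
        for j in fold:
            counts[int(j)] = counts.get(int(j), 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    names = [
        f"{feature_index[j][0]}:{feature_index[j][1]:g}" if feature_index else str(j)
        for j, _ in rows
    ]
    return pd.DataFrame(
        {
            "feature": [j for j, _ in rows],
            "name": names,
            "folds_selected": [c for _, c in rows],
        }
    )


def _config_echo(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))  # make YAML/JSON-safe


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentReport:
    """Run all stages and (optionally) persist intermediates + report.

    Stage errors are re-raised with the stage name attached.  With
    ``out_dir`` the persisted artifacts are: ``cycles.tsv``,
    ``epochs.npz``, ``features.tsv``, ``cv.json``,
    ``feature_stability.tsv``, ``report.json`` and ``report.txt``.
    """
    config.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    truth: SyntheticRecording | None = None

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
        return result

    def _load() -> Recording:
        nonlocal truth
        if config.generator is not None:
            truth = generate_recording(config.generator)
            return truth.recording
        return read_recording(
            config.recording_path,
            format=config.recording_format,
            flow_channel=config.flow_channel,
            rate=config.rate,
        )

    recording = stage("input", _load)
    log.debug("config: %s", _config_echo(config))

    seg = config.segmentation
    cycles = stage(
        "segment",
        lambda: segment_airflow(
            recording.flow_trace(),
            cutoff=seg.cutoff,
            hysteresis=seg.hysteresis,
            min_cycle=seg.min_cycle,
            invert=seg.invert,
        ),
    )
    epochset = stage(
        "epochs",
        lambda: extract_epochs(
            recording, cycles, window=config.window, balance=config.balance
        ),
    )
    feats = stage("features", lambda: spectral_features(epochset))
    cv = stage("classify", lambda: crossvalidate(feats, config.cv))
    stability = feature_stability(cv.fold_feature_sets, feats.index)

    onset_errors = None
    if truth is not None and len(cycles) == truth.true_insp_onsets.size:
        err = np.concatenate(
            [
                cycles.insp_onsets - truth.true_insp_onsets,
                cycles.exp_onsets - truth.true_exp_onsets,
            ]
        ) / recording.rate * 1000.0
        onset_errors = {
            "max_abs": float(np.max(np.abs(err))),
            "sd": float(np.std(err)),
        }

    report = ExperimentReport(
        n_cycles=len(cycles),
        epoch_counts={k: int(v) for k, v in epochset.n_per_class.items()},
        n_features=feats.n_features,
        fold_accuracies=[float(a) for a in cv.fold_accuracies],
        mean_accuracy=float(cv.mean_accuracy),
        top_recurrent_features=[
            (str(r["name"]), int(r["folds_selected"]))
            for _, r in stability.head(20).iterrows()
        ],
        config=_config_echo(config),
        onset_errors_ms=onset_errors,
    )

    if out is not None:
        cycles.write(out / "cycles.tsv")
        _epochs.write_epochs(epochset, out / "epochs.npz")
        write_features(feats, out / "features.tsv")
        cv.write(out / "cv.json")
        stability.to_csv(out / "feature_stability.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        (out / "report.txt").write_text(report.summary() + "\n")
        if truth is not None:
            _synthgen.write_truth(truth, out / "truth.tsv")
    return report
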