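"""Recordings and onset-locked, labelled EEG epochs.

A :class:`Recording` holds time-aligned scalp EEG (channels x samples,
microvolts) and one pneumotachograph airflow channel at a common
sampling rate.  :func:`extract_epochs` cuts fixed-length windows that
start exactly at each inspiratory/expiratory onset of a
:class:`~respeeg.flowseg.BreathCycleSet` and labels them with the phase
of their onset, dropping windows that would leave the recording or run
into the next opposite-phase onset, and optionally balancing the two
classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flowseg import AirflowTrace, BreathCycleSet

__all__ = [
    "INSPIRATION",
    "EXPIRATION",
    "Recording",
    "EpochSet",
    "extract_epochs",
    "read_recording",
    "write_epochs",
    "read_epochs",
]

INSPIRATION = "inspiration"
EXPIRATION = "expiration"


@dataclass(frozen=True)
class Recording:
    """Time-aligned multichannel EEG (µV) plus airflow at one rate."""

    eeg: np.ndarray  # channels x samples, µV
    channel_names: list[str]
    flow: np.ndarray  # flow units, positive = inspiration
    rate: float

    def __post_init__(self) -> None:
        eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        flow = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "eeg", eeg)
        object.__setattr__(self, "flow", flow)
        object.__setattr__(self, "channel_names", list(self.channel_names))
        if eeg.shape[0] != len(self.channel_names):
            raise ValueError("one channel name per EEG row required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if eeg.shape[1] != flow.size:
            raise ValueError(
                f"EEG ({eeg.shape[1]} samples) and flow ({flow.size}) must be aligned"
            )
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.flow.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def flow_trace(self) -> AirflowTrace:
        return AirflowTrace(self.flow, self.rate)


@dataclass(frozen=True)
class EpochSet:
    """Fixed-length onset-locked EEG windows with phase labels."""

    data: np.ndarray  # epochs x channels x window samples, µV
    labels: np.ndarray  # of {"inspiration", "expiration"}
    onsets: np.ndarray  # sample index of each epoch start in the source recording
    window: float  # seconds
    rate: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        onsets = np.asarray(self.onsets, dtype=np.int64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "channel_names", list(self.channel_names))
        if data.ndim != 3:
            raise ValueError("epoch data must be epochs x channels x samples")
        if not (data.shape[0] == labels.size == onsets.size):
            raise ValueError("labels and onsets must match the epoch count")
        if data.shape[2] != int(round(self.window * self.rate)):
            raise ValueError("window samples must equal round(window * rate)")

    def __len__(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_per_class(self) -> dict[str, int]:
        values, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


def extract_epochs(
    recording: Recording,
    cycles: BreathCycleSet,
    window: float = 1.0,
    balance: bool = True,
    reject_peak_to_peak: float | None = None,
) -> EpochSet:
    """Cut one EEG epoch per breath-phase onset.

    Each epoch starts exactly at its onset sample and spans ``window``
    seconds.  An epoch is dropped when it would extend past the end of
    the recording or past the next opposite-phase onset (which would mix
    the two phases inside one window).  With ``balance`` the larger
    class is truncated to the size of the smaller by dropping its latest
    epochs.  ``reject_peak_to_peak`` optionally drops epochs whose
    peak-to-peak amplitude on any channel exceeds the given µV value
    (off by default).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if abs(cycles.rate - recording.rate) > 1e-9:
        raise ValueError(
            f"rate mismatch: cycles at {cycles.rate} Hz, recording at {recording.rate} Hz"
        )
    n_win = int(round(window * recording.rate))
    n_total = recording.n_samples

    events: list[tuple[int, str]] = []
    insp, exp = cycles.insp_onsets, cycles.exp_onsets
    for i in range(len(cycles)):
        # inspiratory epoch must end before (or at) this cycle's expiratory onset
        if insp[i] + n_win <= exp[i] and insp[i] + n_win <= n_total:
            events.append((int(insp[i]), INSPIRATION))
        next_insp = insp[i + 1] if i + 1 < len(cycles) else n_total
        if exp[i] + n_win <= next_insp and exp[i] + n_win <= n_total:
            events.append((int(exp[i]), EXPIRATION))

    data, labels, onsets = [], [], []
    for onset, label in events:
        seg = recording.eeg[:, onset : onset + n_win]
        if reject_peak_to_peak is not None:
            if np.any(seg.max(axis=1) - seg.min(axis=1) > reject_peak_to_peak):
                continue
        data.append(seg)
        labels.append(label)
        onsets.append(onset)

    data_arr = (
        np.stack(data) if data else np.empty((0, recording.eeg.shape[0], n_win))
    )
    labels_arr = np.array(labels, dtype=object)
    onsets_arr = np.array(onsets, dtype=np.int64)

    if balance and len(data) > 0:
        keep = np.ones(len(data), dtype=bool)
        counts = {
            lab: int(np.sum(labels_arr == lab)) for lab in (INSPIRATION, EXPIRATION)
        }
        n_min = min(counts.values())
        for lab in (INSPIRATION, EXPIRATION):
            extra = counts[lab] - n_min
            if extra > 0:  # drop the latest epochs of the larger class
                idx = np.flatnonzero(labels_arr == lab)[counts[lab] - extra :]
                keep[idx] = False
        data_arr, labels_arr, onsets_arr = (
            data_arr[keep],
            labels_arr[keep],
            onsets_arr[keep],
        )

    return EpochSet(
        data_arr, labels_arr, onsets_arr, window, recording.rate, recording.channel_names
    )


def read_recording(
    path,
    format: str | None = None,
    flow_channel: str = "Flow",
    rate: float | None = None,
    eeg_channels: list[str] | None = None,
    invert_flow: bool = False,
) -> Recording:
    """Load a Recording from EDF or delimited text.

    EDF files are read with :mod:`mne`; the sampling rate comes from the
    file header.  Delimited text must have a header row of channel names
    and one column per channel (a leading ``time`` column is ignored),
    and requires an explicit ``rate``.  All non-flow channels are taken
    as EEG unless ``eeg_channels`` is given.
    """
    path = str(path)
    if format is None:
        format = "edf" if path.lower().endswith(".edf") else "delimited"

    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        names = raw.ch_names
        if flow_channel not in names:
            raise ValueError(
                f"flow channel {flow_channel!r} not in EDF; available: {names}"
            )
        rate_file = float(raw.info["sfreq"])
        picks_eeg = eeg_channels or [n for n in names if n != flow_channel]
        missing = [n for n in picks_eeg if n not in names]
        if missing:
            raise ValueError(f"EEG channels {missing} not in EDF; available: {names}")
        # mne scales channels to SI units by type; request µV / raw units back
        eeg = raw.get_data(picks=picks_eeg, units="uV")
        flow = raw.get_data(picks=[flow_channel])[0]
        ch_names = picks_eeg
        rate = rate_file
    elif format == "delimited":
        if rate is None:
            raise ValueError("a sampling rate is required for delimited recordings")
        df = pd.read_csv(path, sep=None, engine="python")
        cols = [c for c in df.columns if c.lower() != "time"]
        if flow_channel not in cols:
            raise ValueError(
                f"flow channel {flow_channel!r} not in file; available: {cols}"
            )
        ch_names = eeg_channels or [c for c in cols if c != flow_channel]
        missing = [n for n in ch_names if n not in cols]
        if missing:
            raise ValueError(f"EEG channels {missing} not in file; available: {cols}")
        eeg = df[ch_names].to_numpy().T
        flow = df[flow_channel].to_numpy()
    else:
        raise ValueError(f"unknown recording format {format!r}")

    if invert_flow:
        flow = -flow
    return Recording(eeg, list(ch_names), flow, float(rate))


def write_recording_delimited(recording: Recording, path) -> None:
    """Write a recording as TSV: time column + one column per channel."""
    t = np.arange(recording.n_samples) / recording.rate
    df = pd.DataFrame({"time": t})
    for i, name in enumerate(recording.channel_names):
        df[name] = recording.eeg[i]
    df["Flow"] = recording.flow
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_epochs(epochset: EpochSet, path) -> None:
    """Persist an EpochSet as an NPZ archive (lossless round-trip)."""
    if len(epochset) == 0:
        raise ValueError("refusing to write an empty epoch set")
    np.savez(
        path,
        data=epochset.data,
        labels=epochset.labels.astype(str),
        onsets=epochset.onsets,
        window=np.float64(epochset.window),
        rate=np.float64(epochset.rate),
        channel_names=np.array(epochset.channel_names, dtype=str),
    )


def read_epochs(path) -> EpochSet:
    with np.load(path, allow_pickle=False) as npz:
        return EpochSet(
            data=npz["data"],
            labels=npz["labels"].astype(object),
            onsets=npz["onsets"],
            window=float(npz["window"]),
            rate=float(npz["rate"]),
            channel_names=[str(n) for n in npz["channel_names"]],
        )
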