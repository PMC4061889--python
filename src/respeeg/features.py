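"""Epoch-wise spectral power features via the plain DFT.

Each epoch/channel is demeaned, transformed with a rectangular-window
DFT, and reduced to one-sided power values

    P_0   = |X_0|^2 / N^2                      (zero after demeaning)
    P_k   = 2 |X_k|^2 / N^2    for 0 < k < N/2
    P_N/2 = |X_{N/2}|^2 / N^2

so that a unit-amplitude sinusoid at an integer bin yields 1/2
regardless of window length, and the powers sum to the mean square of
the demeaned epoch (Parseval).  For a one-second window the bins sit on
a 1 Hz grid from 0 Hz up to and including the Nyquist frequency.
Features are ordered channel-major, frequency-ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = ["FeatureMatrix", "spectral_features", "write_features", "read_features"]


@dataclass(frozen=True)
class FeatureMatrix:
    """Epochs x (channel, frequency-bin) spectral power values."""

    values: np.ndarray  # epochs x features, µV²
    index: list[tuple[str, float]]  # per column: (channel name, frequency Hz)
    labels: np.ndarray  # carried through from the EpochSet

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "index", [(str(c), float(f)) for c, f in self.index])
        if values.ndim != 2 or values.shape[1] != len(self.index):
            raise ValueError("values must be epochs x len(index)")
        if labels.size != values.shape[0]:
            raise ValueError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.values.shape[1])

    def column_names(self) -> list[str]:
        return [f"{ch}:{freq:g}" for ch, freq in self.index]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names())
        df.insert(0, "label", self.labels.astype(str))
        return df


def spectral_features(epochset: EpochSet) -> FeatureMatrix:
    """Compute the DFT power-spectrum feature matrix of an epoch set."""
    if len(epochset) == 0:
        raise ValueError("cannot featurize an empty epoch set")
    data = epochset.data  # epochs x channels x samples
    n = data.shape[2]
    demeaned = data - data.mean(axis=2, keepdims=True)
    spectrum = np.fft.rfft(demeaned, axis=2)
    power = np.abs(spectrum) ** 2 / n**2
    power[..., 1:] *= 2.0
    if n % 2 == 0:  # the Nyquist bin is not doubled
        power[..., -1] /= 2.0

    n_epochs, n_ch, n_bins = power.shape
    values = power.reshape(n_epochs, n_ch * n_bins)
    freqs = np.fft.rfftfreq(n, 1.0 / epochset.rate)
    index = [
        (ch, float(f)) for ch in epochset.channel_names for f in freqs
    ]
    return FeatureMatrix(values, index, epochset.labels.copy())


def write_features(features: FeatureMatrix, path) -> None:
    """Write the feature matrix as TSV (header ``channel:frequency``)."""
    features.to_frame().to_csv(path, sep="\t", index=False)


def read_features(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t")
    labels = df.pop("label").to_numpy(dtype=object)
    index = []
    for col in df.columns:
        ch, _, freq = col.rpartition(":")
        index.append((ch, float(freq)))
    return FeatureMatrix(df.to_numpy(), index, labels)
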