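"""Synthetic airflow + EEG recordings with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a quasi-periodic biphasic airflow signal (half-sine inspiratory
and expiratory lobes, cycle periods drawn from a truncated normal law),
and EEG channels made of 1/f-spectrum Gaussian background noise plus,
optionally, respiratory-phase-locked band-limited activity.

Each :class:`EffectSpec` adds band-limited Gaussian noise to one channel
*only during one phase of the breath cycle*, calibrated so that the
expected total band power in that band during inspiration divided by the
one during expiration equals ``power_ratio``.  ``power_ratio = 1`` is
the null effect (nothing is added).  The effect spans the full
half-cycle, not just the analysis window, so downstream epoch-placement
choices cannot create artificial train/test structure.

Ground truth (true onset samples and the (channel, Hz) bins covered by
each effect at the 1 Hz resolution of one-second epochs) is carried
alongside the signals for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _stats

from .epochs import Recording

__all__ = [
    "EffectSpec",
    "GeneratorConfig",
    "SyntheticRecording",
    "generate_airflow",
    "generate_eeg",
    "generate_recording",
]


@dataclass(frozen=True)
class EffectSpec:
    """A respiratory-phase-locked band-power modulation on one channel.

    ``power_ratio`` is the expected inspiration/expiration band-power
    ratio of the *total* signal in ``[band_low, band_high]`` Hz;
    ratios > 1 boost inspiration, ratios < 1 boost expiration.
    """

    channel: str
    band_low: float
    band_high: float
    power_ratio: float

    def validate(self, nyquist: float) -> None:
        if not 0 <= self.band_low < self.band_high <= nyquist:
            raise ValueError(
                f"effect band [{self.band_low}, {self.band_high}] must lie in "
                f"[0, {nyquist}] Hz with band_low < band_high"
            )
        if self.power_ratio <= 0:
            raise ValueError("power_ratio must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic recording.

    Defaults emulate the target recording setup: two sensorimotor
    channels (C3, C4, Cz-referenced) and one airflow channel at 256 Hz,
    ~120 self-paced breath cycles of ~4 s.  ``background_scale`` is the
    RMS amplitude of the 1/f background in µV (10 µV is a typical
    resting scalp EEG amplitude); ``flow_amplitude`` sets the half-sine
    lobe peak in arbitrary flow units.
    """

    sampling_rate: float = 256.0
    n_cycles: int = 120
    cycle_period_mean: float = 4.0
    cycle_period_sd: float = 0.5
    insp_fraction: float = 0.4
    flow_amplitude: float = 1.0
    flow_noise_sd: float = 0.05
    eeg_channels: tuple[str, ...] = ("C3", "C4")
    background_exponent: float = 1.0
    background_scale: float = 10.0
    effects: tuple[EffectSpec, ...] = ()
    line_noise_amplitude: float = 0.0
    line_noise_freq: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "eeg_channels", tuple(self.eeg_channels))
        object.__setattr__(self, "effects", tuple(self.effects))

    def validate(self, window: float = 1.0) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be at least 1")
        if not 0 < self.insp_fraction < 1:
            raise ValueError("insp_fraction must lie in (0, 1)")
        if self.flow_amplitude <= 0:
            raise ValueError("flow_amplitude must be positive")
        if self.flow_noise_sd < 0 or self.background_scale < 0:
            raise ValueError("noise scales must be non-negative")
        if self.cycle_period_sd < 0:
            raise ValueError("cycle_period_sd must be non-negative")
        shortest = self.cycle_period_mean - 3 * self.cycle_period_sd
        if shortest <= window:
            raise ValueError(
                f"cycle_period_mean - 3*cycle_period_sd = {shortest:.3f} s must "
                f"exceed the {window} s epoch window"
            )
        for eff in self.effects:
            eff.validate(self.sampling_rate / 2)
            if eff.channel not in self.eeg_channels:
                raise ValueError(
                    f"effect channel {eff.channel!r} not in {self.eeg_channels}"
                )


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated recording bundled with its ground truth."""

    recording: Recording
    true_insp_onsets: np.ndarray
    true_exp_onsets: np.ndarray
    effect_bins: frozenset  # of (channel, frequency Hz) pairs, 1 Hz grid


def generate_airflow(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthesize the airflow channel.

    Each cycle is a positive half-sine lobe of duration
    ``insp_fraction * period`` followed by a negative half-sine lobe for
    the remainder; periods are drawn from a normal law truncated at
    ±3 sd.  White Gaussian noise of sd ``flow_noise_sd`` is added on
    top.  The recording starts mid-expiration (the second half of an
    expiratory lobe leads in), as a real recording of ongoing breathing
    would, so every true onset is an interior sign change.  Returns
    ``(flow, insp_onsets, exp_onsets)`` where the onsets are the
    sign-change samples of the noise-free component (the first,
    zero-valued sample of each lobe).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs, amp = config.sampling_rate, config.flow_amplitude

    if config.cycle_period_sd == 0:
        periods = np.full(config.n_cycles, config.cycle_period_mean)
    else:
        periods = _stats.truncnorm.rvs(
            -3.0,
            3.0,
            loc=config.cycle_period_mean,
            scale=config.cycle_period_sd,
            size=config.n_cycles,
            random_state=rng,
        )

    # lead-in: second half of an expiratory lobe at the mean period
    n_lead_lobe = int(round((1.0 - config.insp_fraction) * config.cycle_period_mean * fs))
    lead = -amp * np.sin(np.pi * np.arange(n_lead_lobe) / n_lead_lobe)[n_lead_lobe // 2 :]
    lobes: list[np.ndarray] = [lead]
    insp_onsets, exp_onsets = [], []
    start = lead.size
    for period in periods:
        n_cycle = int(round(period * fs))
        n_insp = int(round(config.insp_fraction * period * fs))
        n_insp = min(max(n_insp, 1), n_cycle - 1)
        n_exp = n_cycle - n_insp
        insp_onsets.append(start)
        exp_onsets.append(start + n_insp)
        lobes.append(amp * np.sin(np.pi * np.arange(n_insp) / n_insp))
        lobes.append(-amp * np.sin(np.pi * np.arange(n_exp) / n_exp))
        start += n_cycle

    flow = np.concatenate(lobes)
    if config.flow_noise_sd > 0:
        flow = flow + rng.normal(0.0, config.flow_noise_sd, flow.size)
    return flow, np.asarray(insp_onsets, dtype=np.int64), np.asarray(exp_onsets, dtype=np.int64)


def _background_shape(n: int, fs: float, exponent: float) -> np.ndarray:
    """Amplitude profile over the rfft grid for 1/f^exponent power."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.zeros(freqs.size)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    return shape


def _band_power_fraction(shape: np.ndarray, freqs: np.ndarray, lo: float, hi: float) -> float:
    """Fraction of background power expected inside [lo, hi] Hz."""
    total = float(np.sum(shape**2))
    if total == 0:
        return 0.0
    band = (freqs >= lo) & (freqs <= hi)
    return float(np.sum(shape[band] ** 2)) / total


def _phase_masks(
    insp_onsets: np.ndarray, exp_onsets: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    insp = np.zeros(n, dtype=bool)
    for i, onset in enumerate(insp_onsets):
        insp[onset : exp_onsets[i]] = True
    exp = np.zeros(n, dtype=bool)
    for i, onset in enumerate(exp_onsets):
        end = insp_onsets[i + 1] if i + 1 < insp_onsets.size else n
        exp[onset:end] = True
    return insp, exp


def generate_eeg(
    config: GeneratorConfig,
    insp_onsets: np.ndarray,
    exp_onsets: np.ndarray,
    n_samples: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize the EEG channels (channels x samples, µV).

    Each channel is 1/f-shaped Gaussian background noise scaled to
    ``background_scale`` µV RMS, plus per-effect band-limited Gaussian
    noise gated to one breath phase (see :class:`EffectSpec`), plus
    optional sinusoidal line noise.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if insp_onsets.size and (insp_onsets.max() >= n_samples or exp_onsets.max() >= n_samples):
        raise ValueError("onsets must lie inside the recording")
    fs = config.sampling_rate
    n_ch = len(config.eeg_channels)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = _background_shape(n_samples, fs, config.background_exponent)
    insp_mask, exp_mask = _phase_masks(insp_onsets, exp_onsets, n_samples)

    eeg = np.zeros((n_ch, n_samples))
    for c, name in enumerate(config.eeg_channels):
        if config.background_scale > 0:
            spec = shape * (
                rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
            )
            spec[0] = 0.0
            if n_samples % 2 == 0:
                spec[-1] = spec[-1].real
            bg = np.fft.irfft(spec, n_samples)
            bg *= config.background_scale / np.std(bg)
            eeg[c] = bg
        for eff in config.effects:
            if eff.channel != name or eff.power_ratio == 1.0:
                continue
            band = (freqs >= eff.band_low) & (freqs <= eff.band_high) & (freqs > 0)
            if not np.any(band):
                raise ValueError(
                    f"effect band [{eff.band_low}, {eff.band_high}] Hz contains no "
                    f"frequency bin at this recording length"
                )
            bspec = np.zeros(freqs.size, dtype=complex)
            bspec[band] = rng.standard_normal(int(band.sum())) + 1j * rng.standard_normal(
                int(band.sum())
            )
            burst = np.fft.irfft(bspec, n_samples)
            burst /= np.std(burst)
            # expected background power inside the band
            p_band = config.background_scale**2 * _band_power_fraction(
                shape, freqs, eff.band_low, eff.band_high
            )
            if eff.power_ratio > 1.0:
                extra, mask = (eff.power_ratio - 1.0) * p_band, insp_mask
            else:
                extra, mask = (1.0 / eff.power_ratio - 1.0) * p_band, exp_mask
            eeg[c, mask] += np.sqrt(extra) * burst[mask]
        if config.line_noise_amplitude > 0:
            t = np.arange(n_samples) / fs
            eeg[c] += config.line_noise_amplitude * np.sin(
                2 * np.pi * config.line_noise_freq * t
            )
    return eeg


def generate_recording(config: GeneratorConfig) -> SyntheticRecording:
    """Generate a complete synthetic recording with ground truth.

    A single seeded generator drives airflow and EEG in a fixed order,
    so identical configs yield identical recordings.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    flow, insp_onsets, exp_onsets = generate_airflow(config, rng)
    eeg = generate_eeg(config, insp_onsets, exp_onsets, flow.size, rng)
    recording = Recording(eeg, list(config.eeg_channels), flow, config.sampling_rate)

    bins: set[tuple[str, float]] = set()
    for eff in config.effects:
        if eff.power_ratio == 1.0:
            continue
        lo = int(np.ceil(eff.band_low))
        hi = int(np.floor(eff.band_high))
        bins.update((eff.channel, float(f)) for f in range(lo, hi + 1))
    return SyntheticRecording(
        recording=recording,
        true_insp_onsets=insp_onsets,
        true_exp_onsets=exp_onsets,
        effect_bins=frozenset(bins),
    )


def write_truth(synthetic: SyntheticRecording, path) -> None:
    """Write ground-truth onsets as TSV (sample_index, phase)."""
    import pandas as pd

    rows = [(int(i), "inspiration") for i in synthetic.true_insp_onsets]
    rows += [(int(i), "expiration") for i in synthetic.true_exp_onsets]
    rows.sort()
    pd.DataFrame(rows, columns=["sample_index", "phase"]).to_csv(
        path, sep="\t", index=False
    )
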