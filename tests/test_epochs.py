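"""Epoch extraction, balancing, and recording/epoch file round-trips."""

import numpy as np
import pytest

from respeeg import (
    BreathCycleSet,
    EXPIRATION,
    GeneratorConfig,
    INSPIRATION,
    Recording,
    extract_epochs,
    generate_recording,
    read_epochs,
    read_recording,
    segment_airflow,
    write_epochs,
)
from respeeg.edf import write_edf
from respeeg.epochs import write_recording_delimited


def truth_cycles(syn) -> BreathCycleSet:
    pairs = np.column_stack([syn.true_insp_onsets, syn.true_exp_onsets])
    return BreathCycleSet(pairs, syn.recording.rate)


class TestExtraction:
    def test_120_cycles_give_240_balanced_epochs(self, null_synthetic):
        cycles = segment_airflow(null_synthetic.recording.flow_trace())
        epochset = extract_epochs(null_synthetic.recording, cycles)
        assert len(epochset) == 240
        assert epochset.n_per_class == {INSPIRATION: 120, EXPIRATION: 120}

    def test_epoch_near_recording_end_dropped(self):
        syn = generate_recording(GeneratorConfig(seed=2, flow_noise_sd=0.0))
        rec = syn.recording
        # truncate so the last expiratory onset is only 0.5 s from the end
        cut = int(syn.true_exp_onsets[-1] + 0.5 * rec.rate)
        short = Recording(rec.eeg[:, :cut], rec.channel_names, rec.flow[:cut], rec.rate)
        cycles = truth_cycles(syn)
        unbalanced = extract_epochs(short, cycles, balance=False)
        assert unbalanced.n_per_class == {INSPIRATION: 120, EXPIRATION: 119}
        balanced = extract_epochs(short, cycles, balance=True)
        assert balanced.n_per_class == {INSPIRATION: 119, EXPIRATION: 119}

    def test_labels_match_source_phase(self, null_synthetic):
        syn = null_synthetic
        epochset = extract_epochs(syn.recording, truth_cycles(syn))
        insp = set(syn.true_insp_onsets.tolist())
        exp = set(syn.true_exp_onsets.tolist())
        for onset, label in zip(epochset.onsets, epochset.labels):
            assert (label == INSPIRATION) == (int(onset) in insp)
            assert (label == EXPIRATION) == (int(onset) in exp)

    def test_epochs_start_at_onset_sample(self, null_synthetic):
        syn = null_synthetic
        epochset = extract_epochs(syn.recording, truth_cycles(syn))
        k = 5
        onset = int(epochset.onsets[k])
        assert np.array_equal(
            epochset.data[k], syn.recording.eeg[:, onset : onset + 256]
        )

    def test_no_epoch_crosses_opposite_phase_onset(self, null_synthetic):
        syn = null_synthetic
        epochset = extract_epochs(syn.recording, truth_cycles(syn))
        n_win = int(epochset.window * epochset.rate)
        opposite = {
            INSPIRATION: np.sort(syn.true_exp_onsets),
            EXPIRATION: np.sort(syn.true_insp_onsets),
        }
        for onset, label in zip(epochset.onsets, epochset.labels):
            others = opposite[label]
            inside = (others > onset) & (others < onset + n_win)
            assert not np.any(inside)

    def test_short_inspiratory_lobe_dropped(self):
        """A window longer than the inspiratory lobe would mix phases."""
        syn = generate_recording(GeneratorConfig(seed=0, flow_noise_sd=0.0, n_cycles=10))
        epochset = extract_epochs(syn.recording, truth_cycles(syn), window=2.0, balance=False)
        # inspiratory lobes last ~1.6 s < 2 s, so only expiratory epochs survive
        assert INSPIRATION not in epochset.n_per_class
        assert epochset.n_per_class[EXPIRATION] > 0

    def test_rate_mismatch_rejected(self, null_synthetic):
        cycles = BreathCycleSet(truth_cycles(null_synthetic).cycles, 512.0)
        with pytest.raises(ValueError, match="rate mismatch"):
            extract_epochs(null_synthetic.recording, cycles)

    def test_nonpositive_window_rejected(self, null_synthetic):
        with pytest.raises(ValueError, match="window"):
            extract_epochs(null_synthetic.recording, truth_cycles(null_synthetic), window=0.0)

    def test_deterministic(self, null_synthetic):
        syn = null_synthetic
        a = extract_epochs(syn.recording, truth_cycles(syn))
        b = extract_epochs(syn.recording, truth_cycles(syn))
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.onsets, b.onsets)


class TestRecordingIO:
    def test_edf_roundtrip_within_quantization(self, tmp_path):
        syn = generate_recording(GeneratorConfig(seed=3, n_cycles=10))
        rec = syn.recording
        path = tmp_path / "rec.edf"
        write_edf(
            path,
            np.vstack([rec.eeg, rec.flow]),
            rec.channel_names + ["Flow"],
            rec.rate,
            physical_dims=["uV", "uV", "AU"],
        )
        back = read_recording(path)
        n = back.n_samples  # EDF holds whole seconds; the sub-second tail is dropped
        assert rec.n_samples - n < rec.rate
        assert back.rate == rec.rate
        assert back.channel_names == rec.channel_names
        for i in range(2):
            quant = (rec.eeg[i, :n].max() - rec.eeg[i, :n].min()) / (2**16 - 1)
            assert np.max(np.abs(back.eeg[i] - rec.eeg[i, :n])) <= quant * 1.01
        quant_flow = (rec.flow[:n].max() - rec.flow[:n].min()) / (2**16 - 1)
        assert np.max(np.abs(back.flow - rec.flow[:n])) <= quant_flow * 1.01

    def test_edf_byte_identical_on_rerun(self, tmp_path):
        rec = generate_recording(GeneratorConfig(seed=5, n_cycles=5)).recording
        p1, p2 = tmp_path / "a.edf", tmp_path / "b.edf"
        for p in (p1, p2):
            write_edf(p, np.vstack([rec.eeg, rec.flow]), rec.channel_names + ["Flow"], rec.rate)
        assert p1.read_bytes() == p2.read_bytes()

    def test_delimited_roundtrip_and_missing_rate(self, tmp_path):
        rec = generate_recording(GeneratorConfig(seed=1, n_cycles=3)).recording
        path = tmp_path / "rec.tsv"
        write_recording_delimited(rec, path)
        back = read_recording(path, rate=256.0)
        assert back.channel_names == rec.channel_names
        assert np.allclose(back.flow, rec.flow, atol=1e-6)
        with pytest.raises(ValueError, match="rate"):
            read_recording(path)

    def test_missing_flow_channel_names_alternatives(self, tmp_path):
        rec = generate_recording(GeneratorConfig(seed=1, n_cycles=3)).recording
        path = tmp_path / "rec.edf"
        write_edf(path, rec.eeg, rec.channel_names, rec.rate)
        with pytest.raises(ValueError, match="C3"):
            read_recording(path, flow_channel="Pneumo")


class TestEpochIO:
    def test_lossless_roundtrip(self, tmp_path, null_synthetic):
        syn = null_synthetic
        epochset = extract_epochs(syn.recording, truth_cycles(syn))
        path = tmp_path / "epochs.npz"
        write_epochs(epochset, path)
        back = read_epochs(path)
        assert np.array_equal(back.data, epochset.data)
        assert np.array_equal(back.labels.astype(str), epochset.labels.astype(str))
        assert np.array_equal(back.onsets, epochset.onsets)
        assert back.window == epochset.window
        assert back.channel_names == epochset.channel_names
        assert len(back) == 240

    def test_empty_set_refused(self, null_synthetic):
        rec = null_synthetic.recording
        empty = extract_epochs(
            rec, BreathCycleSet(np.empty((0, 2), dtype=int), rec.rate)
        )
        with pytest.raises(ValueError, match="empty"):
            write_epochs(empty, "unused.npz")

    def test_corrupted_file_raises(self, tmp_path):
        path = tmp_path / "epochs.npz"
        path.write_bytes(b"PK\x03\x04 this is not a real archive")
        with pytest.raises(Exception):
            read_epochs(path)
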