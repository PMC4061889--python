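"""Minimal EDF (European Data Format) writing.

Only what the package needs: continuous multichannel recordings with a
common integer sampling rate, one data record per second, 16-bit
samples.  Reading goes through :mod:`mne` (see
:func:`respeeg.epochs.read_recording`); this writer exists because no
EDF writer ships with the scientific stack this package builds on, and
the format is a fixed-layout ASCII header followed by little-endian
int16 records.

The header start date/time is fixed (01.01.2000) so that re-running a
seeded generator produces byte-identical files.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> bytes:
    """Format a physical min/max into an 8-char EDF field."""
    for fmt in (f"{x:.6g}", f"{x:.4g}", f"{x:.2g}"):
        if len(fmt) <= width:
            return _ascii(fmt, width)
    raise ValueError(f"cannot format {x} in {width} chars")


def write_edf(
    path,
    data: np.ndarray,
    channel_names: list[str],
    rate: float,
    physical_dims: list[str] | None = None,
) -> None:
    """Write channels x samples ``data`` as a 16-bit EDF file.

    ``rate`` must be a positive integer (samples per one-second data
    record).  The signal is truncated to a whole number of seconds; EDF
    has no partial data records.  Each channel is scaled to its own
    physical min/max, so quantization error is at most
    ``(max - min) / (2**16 - 1)`` per channel.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("one channel name per row required")
    if rate <= 0 or abs(rate - round(rate)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {rate}")
    rate = int(round(rate))
    n_records = n_samp // rate
    if n_records < 1:
        raise ValueError("need at least one second of data")
    if physical_dims is None:
        physical_dims = ["uV"] * n_ch
    n_samp = n_records * rate
    data = data[:, :n_samp]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # degenerate (constant) channels still need a non-empty physical range
    flat = phys_max - phys_min <= 0
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)

    header = b"".join(
        [
            _ascii("0", 8),  # version
            _ascii("X X X X", 80),  # patient id (anonymous)
            _ascii("Startdate 01-JAN-2000 X X X", 80),  # recording id
            _ascii("01.01.00", 8),  # start date
            _ascii("00.00.00", 8),  # start time
            _ascii(256 * (1 + n_ch), 8),  # header length
            _ascii("", 44),  # reserved (plain EDF)
            _ascii(n_records, 8),
            _ascii(1, 8),  # record duration, seconds
            _ascii(n_ch, 4),
        ]
    )
    fields = [
        [_ascii(name, 16) for name in channel_names],
        [_ascii("", 80)] * n_ch,  # transducer
        [_ascii(dim, 8) for dim in physical_dims],
        [_fmt_float(v) for v in phys_min],
        [_fmt_float(v) for v in phys_max],
        [_ascii(_DIG_MIN, 8)] * n_ch,
        [_ascii(_DIG_MAX, 8)] * n_ch,
        [_ascii("", 80)] * n_ch,  # prefiltering
        [_ascii(rate, 8)] * n_ch,
        [_ascii("", 32)] * n_ch,  # reserved
    ]
    header += b"".join(b"".join(col) for col in fields)

    # re-parse the formatted physical range so the stored gain matches the header
    pmin = np.array([float(f.decode()) for f in fields[3]])
    pmax = np.array([float(f.decode()) for f in fields[4]])
    gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - pmin[:, None]) / gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # record-major layout: for each second, each channel's samples
        blocks = digital.reshape(n_ch, n_records, rate)
        fh.write(np.ascontiguousarray(blocks.transpose(1, 0, 2)).tobytes())
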