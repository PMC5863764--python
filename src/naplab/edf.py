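"""Minimal EDF+ (16-bit European Data Format) writer.

Writes continuous multi-channel signals with a 1-second record length.
Physical units are microvolts; each channel is scaled to the full signed
16-bit digital range, so the quantization step is (2 * max |x|) / 65534.
Reading is delegated to ``mne.io.read_raw_edf`` elsewhere in the package;
this module only exists because signal fixtures must be materialized as
standard EDF files.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

DIG_MAX = 32767
DIG_MIN = -32767


def _ascii_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, signal_uv: np.ndarray, sampling_rate: float,
              channel_labels: list[str], patient: str = "X",
              recording: str = "naplab synthetic") -> None:
    """Write ``signal_uv`` (channels x samples, microvolts) to an EDF file.

    The number of samples must be an integer multiple of the sampling rate
    (whole seconds) and the sampling rate must be an integer, so that
    1-second data records tile the signal exactly and the round trip is
    lossless up to 16-bit quantization.
    """
    path = Path(path)
    signal_uv = np.asarray(signal_uv, dtype=float)
    if signal_uv.ndim != 2:
        raise ValueError("signal must be 2-D (channels x samples)")
    n_ch, n_samp = signal_uv.shape
    if len(channel_labels) != n_ch:
        raise ValueError("channel_labels length does not match signal")
    fs = int(round(sampling_rate))
    if abs(fs - sampling_rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if n_samp % fs != 0:
        raise ValueError("signal length must be a whole number of seconds")
    n_records = n_samp // fs

    # integer physical range: the 8-char ASCII header field then encodes the
    # scale exactly, keeping the round trip within one quantization step
    phys_max = np.ceil(np.maximum(np.max(np.abs(signal_uv), axis=1), 1.0)
                       ).astype(int) + 1
    scale = DIG_MAX / phys_max
    digital = np.clip(np.round(signal_uv * scale[:, None]), DIG_MIN, DIG_MAX)
    digital = digital.astype("<i2")

    now = datetime.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(patient, 80),
        _ascii_field(recording, 80),
        _ascii_field(now.strftime("%d.%m.%y"), 8),
        _ascii_field(now.strftime("%H.%M.%S"), 8),
        _ascii_field(str(256 * (1 + n_ch)), 8),
        _ascii_field("EDF+C", 44),
        _ascii_field(str(n_records), 8),
        _ascii_field("1", 8),          # record duration, seconds
        _ascii_field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_ascii_field(lab, 16) for lab in channel_labels),
        b"".join(_ascii_field("AgAgCl electrode", 80) for _ in channel_labels),
        b"".join(_ascii_field("uV", 8) for _ in channel_labels),
        b"".join(_ascii_field(str(-m), 8) for m in phys_max),
        b"".join(_ascii_field(str(m), 8) for m in phys_max),
        b"".join(_ascii_field(str(DIG_MIN), 8) for _ in channel_labels),
        b"".join(_ascii_field(str(DIG_MAX), 8) for _ in channel_labels),
        b"".join(_ascii_field("", 80) for _ in channel_labels),
        b"".join(_ascii_field(str(fs), 8) for _ in channel_labels),
        b"".join(_ascii_field("", 32) for _ in channel_labels),
    ])

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # records: per record, all samples of channel 1, then channel 2, ...
        reshaped = digital.reshape(n_ch, n_records, fs)
        for r in range(n_records):
            reshaped[:, r, :].tofile(fh)


def quantization_step(signal_uv: np.ndarray) -> np.ndarray:
    """Per-channel quantization step (microvolts) of the written file."""
    phys_max = np.ceil(np.maximum(np.max(np.abs(signal_uv), axis=1), 1.0)
                       ).astype(int) + 1
    return 2 * phys_max / (DIG_MAX - DIG_MIN)
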