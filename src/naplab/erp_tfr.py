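"""Cue-locked ERPs and Hanning-taper time-frequency representations.

The TFR uses frequency-adaptive sliding windows: at each frequency f the
signal is convolved with a 5-cycle Hanning-tapered complex exponential
(window length 5/f seconds, e.g. 333 ms at 15 Hz). Power is the squared
magnitude of the amplitude estimate, evaluated on the sample grid (5 ms at
200 Hz) from 4 to 30 Hz in 0.5 Hz steps. Times whose window would extend
beyond the epoch are reported as missing (NaN), never zero-padded, so a
pre-cue baseline cannot be contaminated by wrap-around of post-stimulus
activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .io_core import EpochSet

DEFAULT_FREQS = np.arange(4.0, 30.0 + 1e-9, 0.5)
TFR_BASELINE = (-0.3, -0.1)
ERP_BASELINE = (-0.2, 0.0)


@dataclass
class TFR:
    """Time-frequency power: (trials,) channels x frequencies x times."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    units: str = "uV^2"  # or "percent"

    @property
    def is_average(self) -> bool:
        return self.power.ndim == 3

    def average(self) -> "TFR":
        if self.is_average:
            return self
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN edges
            return replace(self, power=np.nanmean(self.power, axis=0))


def taper_length(freq: float, fs: float, n_cycles: float = 5.0) -> int:
    """Window length in samples for an n-cycle taper at ``freq`` (odd)."""
    n = int(round(n_cycles / freq * fs))
    return n + 1 - n % 2


def compute_erp(epochs: EpochSet, conditions=None,
                collapse_channels: bool = False) -> np.ndarray:
    """Arithmetic mean over retained trials; optionally collapse channels."""
    sel = epochs.select(conditions=conditions)
    if sel.n_trials == 0:
        raise ValueError("no retained trial matches the requested conditions")
    erp = sel.data.mean(axis=0)
    return erp.mean(axis=0) if collapse_channels else erp


def compute_tfr(epochs: EpochSet, freqs: np.ndarray | None = None,
                n_cycles: float = 5.0, average: bool = True) -> TFR:
    """Hanning-tapered sliding-window spectral power for retained trials."""
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    fs = epochs.sampling_rate
    if freqs.max() >= fs / 2:
        raise ValueError("requested frequency at or above Nyquist")
    sel = epochs.select()
    if sel.n_trials == 0:
        raise ValueError("no retained trials")
    data = sel.data
    n_trials, n_ch, n_t = data.shape
    flat = data.reshape(n_trials * n_ch, n_t)
    power = np.empty((n_trials, n_ch, freqs.size, n_t))
    t = None
    for fi, f in enumerate(freqs):
        wlen = taper_length(f, fs, n_cycles)
        half = wlen // 2
        if wlen > n_t:
            power[:, :, fi, :] = np.nan
            continue
        win = np.hanning(wlen)
        tt = (np.arange(wlen) - half) / fs
        kernel = win * np.exp(-2j * np.pi * f * tt)
        # amplitude calibration: a unit sinusoid at f yields |conv| ~ sum(win)/2
        est = fftconvolve(flat, kernel[None, ::-1].conj(), mode="same", axes=1)
        amp = np.abs(est) * 2.0 / win.sum()
        p = amp ** 2
        p[:, :half] = np.nan
        p[:, n_t - half:] = np.nan
        power[:, :, fi, :] = p.reshape(n_trials, n_ch, n_t)
    out = TFR(power=power, freqs=freqs, times=sel.times.copy())
    return out.average() if average else out


def percent_change(tfr: TFR, baseline: tuple[float, float] = TFR_BASELINE) -> TFR:
    """Convert power to percent change relative to a pre-cue baseline.

    The baseline is the power averaged over the window (trials are averaged
    before the division, so the reference is the trial-mean baseline
    spectrum). Cells with zero baseline power become missing.
    """
    avg = tfr.average()
    t0, t1 = baseline
    sel = (avg.times >= t0) & (avg.times <= t1)
    if not sel.any():
        raise ValueError("baseline window outside the TFR time axis")
    base = np.nanmean(avg.power[:, :, sel], axis=2, keepdims=True)
    if np.isnan(base).any():
        raise ValueError("baseline window contains no valid estimate at some "
                         "frequency; widen the epoch or shrink the window")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (avg.power - base) / base
    if (base == 0).any():
        warnings.warn("zero baseline power; affected cells set to missing")
        pct[np.broadcast_to(base == 0, pct.shape)] = np.nan
    return TFR(power=pct, freqs=avg.freqs, times=avg.times, units="percent")
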