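"""Recordings, cue-locked epochs, and the two-step artifact rejection.

The pipeline entry point is a :class:`Recording` (continuous multi-channel
EEG in microvolts with a 30-s hypnogram and cue events), read from an EDF
file plus TSV sidecars. Cue-locked epochs span [-1, 3) s around cue onset.
Artifact rejection proceeds in two steps: an automatic criterion flags
trials whose amplitude or sample-to-sample gradient falls outside
median +/- 3.5 IQR of all trials, and an outlier screen flags trials with
robust-z outliers in variance or kurtosis. Flags are sticky: each step can
only add flags, never remove them.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .filters import highpass

logger = logging.getLogger(__name__)

EPOCH_TMIN = -1.0
EPOCH_TMAX = 3.0  # half-open: the sample at +3 s is excluded
HYPNO_EPOCH_S = 30.0
STAGES = ("W", "N1", "N2", "N3", "REM")
CHANNELS_8 = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")
LEFT_HEMISPHERE = ("F3", "C3", "P3", "O1")

EVENT_COLUMNS = ["onset_s", "condition", "category", "adjective_id", "round"]
CONDITIONS = ("old-object", "old-scene", "control")


@dataclass
class Recording:
    """Continuous polysomnography signal with sidecar annotations.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        EEG in microvolts.
    sampling_rate : float
        Samples per second.
    channel_labels : list of str
    hypnogram : ndarray of str
        One stage label per 30-s epoch, covering the whole recording.
    events : DataFrame
        Columns ``onset_s, condition, category, adjective_id, round``.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    hypnogram: np.ndarray
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.hypnogram = np.asarray(self.hypnogram, dtype=object)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels do not match signal")
        needed = int(np.ceil(self.duration / HYPNO_EPOCH_S))
        if len(self.hypnogram) < needed:
            raise ValueError(
                f"hypnogram covers {len(self.hypnogram) * HYPNO_EPOCH_S:.0f} s "
                f"but the recording lasts {self.duration:.0f} s")
        bad = set(self.hypnogram) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages in hypnogram: {sorted(bad)}")
        if len(self.events):
            on = self.events["onset_s"].to_numpy(float)
            if on.min() < 0 or on.max() >= self.duration:
                raise ValueError("event onset outside recording bounds")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def stage_mask(self, stages: tuple[str, ...] = ("N2", "N3")) -> np.ndarray:
        """Boolean per-sample mask, True where the hypnogram stage is in ``stages``."""
        mask = np.zeros(self.n_samples, dtype=bool)
        spe = int(round(HYPNO_EPOCH_S * self.sampling_rate))
        for k, stage in enumerate(self.hypnogram):
            if stage in stages:
                mask[k * spe:(k + 1) * spe] = True
        return mask[:self.n_samples]


@dataclass
class EpochSet:
    """Cue-locked trials (trials x channels x time) with per-trial metadata.

    ``metadata`` carries one row per trial with the cue condition, category,
    adjective id, cueing round, the cue onset in recording time, and a
    sticky ``artifact_flag``. ``retained`` is the complement of the flag.
    """

    data: np.ndarray
    times: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x time")
        if self.data.shape[2] != self.times.size:
            raise ValueError("time axis does not match data")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata does not match trial count")
        if "artifact_flag" not in self.metadata:
            self.metadata = self.metadata.assign(artifact_flag=False)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def retained(self) -> np.ndarray:
        return ~self.metadata["artifact_flag"].to_numpy(bool)

    def select(self, conditions=None, retained_only: bool = True) -> "EpochSet":
        """Subset trials by condition and/or artifact status."""
        keep = np.ones(self.n_trials, dtype=bool)
        if conditions is not None:
            if isinstance(conditions, str):
                conditions = [conditions]
            keep &= self.metadata["condition"].isin(conditions).to_numpy()
        if retained_only:
            keep &= self.retained
        return replace(self, data=self.data[keep],
                       metadata=self.metadata.loc[keep].reset_index(drop=True))

    def with_flags(self, new_flags: np.ndarray) -> "EpochSet":
        """Return a copy with ``new_flags`` OR-ed into the sticky flag set."""
        meta = self.metadata.copy()
        meta["artifact_flag"] = meta["artifact_flag"].to_numpy(bool) | np.asarray(new_flags, bool)
        return replace(self, metadata=meta)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, data=self.data, times=self.times,
            sampling_rate=self.sampling_rate,
            channel_labels=np.array(self.channel_labels, dtype=object),
            metadata_json=self.metadata.to_json(orient="records"))

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with np.load(path, allow_pickle=True) as z:
            meta = pd.read_json(_io.StringIO(str(z["metadata_json"])),
                                orient="records")
            return cls(data=z["data"], times=z["times"],
                       sampling_rate=float(z["sampling_rate"]),
                       channel_labels=list(z["channel_labels"]),
                       metadata=meta)


# ---------------------------------------------------------------------------
# reading

def read_recording(edf_path: str | Path, events_path: str | Path,
                   hypnogram_path: str | Path,
                   expected_labels: tuple[str, ...] | None = None) -> Recording:
    """Read an EDF signal file with events and hypnogram TSV sidecars.

    Signals are returned in microvolts. ``expected_labels``, when given,
    must match the EDF channel labels exactly (order included); a mismatch
    raises with the offending channel named.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    if expected_labels is not None:
        for k, (got, want) in enumerate(zip(labels, expected_labels)):
            if got != want:
                raise ValueError(
                    f"channel {k}: EDF has {got!r} but configuration expects {want!r}")
        if len(labels) != len(expected_labels):
            raise ValueError(
                f"EDF has {len(labels)} channels, expected {len(expected_labels)}")
    signal_uv = raw.get_data() * 1e6
    fs = float(raw.info["sfreq"])

    events = pd.read_csv(events_path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"events TSV lacks columns {sorted(missing)}")
    hyp = pd.read_csv(hypnogram_path, sep="\t")
    hypnogram = hyp["stage"].to_numpy(object)

    return Recording(signal=signal_uv, sampling_rate=fs, channel_labels=labels,
                     hypnogram=hypnogram, events=events[EVENT_COLUMNS].copy())


# ---------------------------------------------------------------------------
# epoching

def extract_epochs(rec: Recording, tmin: float = EPOCH_TMIN,
                   tmax: float = EPOCH_TMAX) -> EpochSet:
    """Cut cue-locked epochs spanning [tmin, tmax) around each cue onset.

    Cues too close to the recording edges for a full epoch are dropped with
    a warning; zero surviving cues is an error.
    """
    fs = rec.sampling_rate
    n_pre = int(round(-tmin * fs))
    n_post = int(round(tmax * fs))
    times = np.arange(-n_pre, n_post) / fs

    rows, trials = [], []
    for _, ev in rec.events.iterrows():
        onset_idx = int(round(ev["onset_s"] * fs))
        lo, hi = onset_idx - n_pre, onset_idx + n_post
        if lo < 0 or hi > rec.n_samples:
            warnings.warn(
                f"cue at {ev['onset_s']:.2f} s too close to the recording edge; dropped")
            continue
        trials.append(rec.signal[:, lo:hi])
        rows.append(ev)
    if not trials:
        raise ValueError("no cue survives the epoch bounds")
    metadata = pd.DataFrame(rows).reset_index(drop=True)
    metadata["artifact_flag"] = False
    return EpochSet(data=np.stack(trials), times=times, sampling_rate=fs,
                    channel_labels=list(rec.channel_labels), metadata=metadata)


# ---------------------------------------------------------------------------
# artifact rejection

def _iqr_bounds(values: np.ndarray, n_iqr: float) -> tuple[float, float]:
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return med - n_iqr * iqr, med + n_iqr * iqr


def reject_artifacts_auto(epochs: EpochSet, n_iqr: float = 3.5) -> EpochSet:
    """Automatic artifact rejection on amplitude and gradient statistics.

    Per trial, two summary statistics are taken over all channels: the
    maximum absolute amplitude and the maximum absolute difference between
    adjacent samples (gradient). Trials whose statistic lies strictly
    outside median +/- ``n_iqr`` * IQR of all trials are flagged.
    """
    if epochs.n_trials < 4:
        raise ValueError("need at least 4 trials for quartile-based rejection")
    amp = np.max(np.abs(epochs.data), axis=(1, 2))
    grad = np.max(np.abs(np.diff(epochs.data, axis=2)), axis=(1, 2))
    flags = np.zeros(epochs.n_trials, dtype=bool)
    for stat in (amp, grad):
        lo, hi = _iqr_bounds(stat, n_iqr)
        flags |= (stat < lo) | (stat > hi)
    if flags.all():
        raise ValueError(
            "every trial was flagged by the amplitude/gradient criterion; "
            "review the rejection threshold")
    out = epochs.with_flags(flags)
    _log_rejection(out, "auto amplitude/gradient")
    return out


def screen_outliers(epochs: EpochSet, z_cut: float = 5.0) -> EpochSet:
    """Outlier screen on per-trial variance and kurtosis (robust z-scores).

    Statistics are computed over unflagged trials only (the screen runs
    after the automatic step); a trial is flagged when its robust z-score
    (median/MAD) exceeds ``z_cut`` on either metric. A degenerate metric
    (MAD = 0) is skipped with a warning.
    """
    kept = epochs.retained
    if kept.sum() < 4:
        raise ValueError("need at least 4 unflagged trials for the outlier screen")
    var = np.max(np.var(epochs.data, axis=2), axis=1)
    kurt = np.max(stats.kurtosis(epochs.data, axis=2, fisher=True), axis=1)
    flags = np.zeros(epochs.n_trials, dtype=bool)
    for name, metric in (("variance", var), ("kurtosis", kurt)):
        ref = metric[kept]
        med = np.median(ref)
        mad = stats.median_abs_deviation(ref, scale="normal")
        if mad == 0:
            warnings.warn(f"MAD of {name} is zero; metric skipped")
            continue
        flags |= (metric - med) / mad > z_cut
    out = epochs.with_flags(flags & kept)  # only add flags on previously clean trials
    _log_rejection(out, "variance/kurtosis screen")
    return out


def _log_rejection(epochs: EpochSet, step: str) -> None:
    counts = (epochs.metadata.loc[epochs.metadata["artifact_flag"], "condition"]
              .value_counts().to_dict())
    logger.info("after %s: flagged trials per condition: %s", step, counts or "{}")


# ---------------------------------------------------------------------------
# filtering and baselining

def highpass_baseline(epochs: EpochSet, hp: float = 0.5,
                      baseline: tuple[float, float] = (-0.2, 0.0)) -> EpochSet:
    """Zero-phase high-pass filter then subtract the baseline-window mean.

    The baseline mean is computed per trial and channel over
    ``baseline[0] <= t <= baseline[1]`` and subtracted, so the corrected
    baseline mean is exactly zero.
    """
    if hp >= epochs.sampling_rate / 2:
        raise ValueError("high-pass edge at or above Nyquist")
    t0, t1 = baseline
    if t0 < epochs.times[0] or t1 > epochs.times[-1]:
        raise ValueError("baseline window outside the epoch span")
    data = highpass(epochs.data, epochs.sampling_rate, hp, axis=2)
    sel = (epochs.times >= t0) & (epochs.times <= t1)
    data = data - data[:, :, sel].mean(axis=2, keepdims=True)
    return replace(epochs, data=data)


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def write_hypnogram_tsv(hypnogram: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({
        "epoch_start_s": np.arange(len(hypnogram)) * HYPNO_EPOCH_S,
        "stage": hypnogram,
    }).to_csv(path, sep="\t", index=False)
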