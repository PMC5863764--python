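"""Detection of discrete sleep spindles and slow oscillations.

Spindles: per channel, the signal is band-pass filtered (fast band
13-16 Hz by default), the amplitude envelope is taken as the magnitude of
the analytic signal, and a per-channel threshold is set at
mean + 1.25 * SD of the envelope over all eligible samples (N2/N3 sleep,
artifact samples padded by +/- 1 s excluded). Supra-threshold runs lasting
0.5-3 s are events; runs separated by less than 0.1 s are merged before
the duration gate.

Slow oscillations: the signal is filtered 0.5-2 Hz, positive-to-negative
zero crossings are located, and successive crossing pairs 0.8-2 s apart
form candidates. Candidates whose trough amplitude AND trough-to-peak
amplitude both strictly exceed mean + 1.25 * SD of the respective metric
over all candidates on that channel are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filters import bandpass, envelope
from .io_core import LEFT_HEMISPHERE, EpochSet, Recording

FAST_SPINDLE_BAND = (13.0, 16.0)
SLOW_SPINDLE_BAND = (10.0, 13.0)
SO_BAND = (0.5, 2.0)
SPINDLE_DURATION = (0.5, 3.0)
SO_DURATION = (0.8, 2.0)
THRESHOLD_SD = 1.25
ARTIFACT_PAD_S = 1.0
MERGE_GAP_S = 0.1


@dataclass
class DetectedEvent:
    """One detected spindle or slow oscillation on a single channel.

    ``peak_s`` is the envelope maximum for spindles and the trough for
    SOs. ``amplitude`` holds the envelope maximum (spindles) or the trough
    magnitude (SOs); SOs additionally carry ``trough_uv`` (signed) and
    ``ptp_uv`` (trough-to-peak).
    """

    kind: str
    channel: str
    start_s: float
    end_s: float
    peak_s: float
    amplitude: float
    trough_uv: float | None = None
    ptp_uv: float | None = None


def events_to_frame(events: list[DetectedEvent]) -> pd.DataFrame:
    cols = ["channel", "start_s", "end_s", "peak_s", "kind", "amplitude",
            "trough_uv", "ptp_uv"]
    if not events:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([e.__dict__ for e in events])[cols]


def frame_to_events(df: pd.DataFrame) -> list[DetectedEvent]:
    out = []
    for _, r in df.iterrows():
        out.append(DetectedEvent(
            kind=r["kind"], channel=r["channel"], start_s=r["start_s"],
            end_s=r["end_s"], peak_s=r["peak_s"], amplitude=r["amplitude"],
            trough_uv=r.get("trough_uv"), ptp_uv=r.get("ptp_uv")))
    return out


def eligible_mask(rec: Recording, stages: tuple[str, ...] = ("N2", "N3"),
                  artifact_mask: np.ndarray | None = None,
                  pad_s: float = ARTIFACT_PAD_S) -> np.ndarray:
    """Samples usable for detection: requested stages minus padded artifacts."""
    mask = rec.stage_mask(stages)
    if artifact_mask is not None:
        art = np.asarray(artifact_mask, bool)
        if art.size != rec.n_samples:
            raise ValueError("artifact mask length does not match the recording")
        pad = int(round(pad_s * rec.sampling_rate))
        if art.any() and pad > 0:
            idx = np.flatnonzero(art)
            grown = np.zeros_like(art)
            for i in idx:  # artifacts are sparse; direct dilation is fine
                grown[max(0, i - pad):i + pad + 1] = True
            art = grown
        mask &= ~art
    return mask


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]


SMOOTH_S = 0.2


def _smooth(x: np.ndarray, fs: float, smooth_s: float) -> np.ndarray:
    k = int(round(smooth_s * fs))
    if k <= 1:
        return x
    return np.convolve(x, np.ones(k) / k, mode="same")


def detect_spindles(rec: Recording, band: tuple[float, float] = FAST_SPINDLE_BAND,
                    stages: tuple[str, ...] = ("N2", "N3"),
                    artifact_mask: np.ndarray | None = None,
                    duration: tuple[float, float] = SPINDLE_DURATION,
                    threshold_sd: float = THRESHOLD_SD,
                    merge_gap_s: float = MERGE_GAP_S,
                    smooth_s: float = SMOOTH_S) -> list[DetectedEvent]:
    """Envelope-threshold spindle detection, one pass per channel.

    The analytic-signal envelope is smoothed with a ``smooth_s`` moving
    average before thresholding (the convention of most published
    spindle detectors); without it, beating between the carrier and
    in-band noise splits marginal events into sub-criterion fragments.
    """
    if band[0] >= band[1]:
        raise ValueError(f"inverted band {band}")
    fs = rec.sampling_rate
    elig = eligible_mask(rec, stages, artifact_mask)
    if not elig.any():
        raise ValueError("no eligible N2/N3 artifact-free data")
    if elig.sum() / fs < 60.0:
        raise ValueError("less than 60 s of eligible data")
    kind = "spindle_fast" if band[0] >= 12.5 else "spindle_slow"
    gap = int(round(merge_gap_s * fs))

    out: list[DetectedEvent] = []
    for ci, label in enumerate(rec.channel_labels):
        env = _smooth(envelope(bandpass(rec.signal[ci], fs, *band)), fs, smooth_s)
        ref = env[elig]
        thr = ref.mean() + threshold_sd * ref.std()
        supra = (env > thr) & elig
        runs = _runs(supra)
        # merge runs separated by a short sub-threshold gap (eligible gap only)
        merged: list[tuple[int, int]] = []
        for a, b in runs:
            if merged and a - merged[-1][1] < gap and elig[merged[-1][1]:a].all():
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        for a, b in merged:
            dur = (b - a) / fs
            if duration[0] <= dur <= duration[1]:
                peak = a + int(np.argmax(env[a:b]))
                out.append(DetectedEvent(
                    kind=kind, channel=label, start_s=a / fs, end_s=b / fs,
                    peak_s=peak / fs, amplitude=float(env[peak])))
    return out


def detect_sos(rec: Recording, stages: tuple[str, ...] = ("N2", "N3"),
               artifact_mask: np.ndarray | None = None,
               band: tuple[float, float] = SO_BAND,
               duration: tuple[float, float] = SO_DURATION,
               threshold_sd: float = THRESHOLD_SD) -> list[DetectedEvent]:
    """Zero-crossing slow-oscillation detection with dual amplitude criteria."""
    fs = rec.sampling_rate
    elig = eligible_mask(rec, stages, artifact_mask)
    if not elig.any():
        raise ValueError("no eligible N2/N3 artifact-free data")

    out: list[DetectedEvent] = []
    for ci, label in enumerate(rec.channel_labels):
        filt = bandpass(rec.signal[ci], fs, *band)
        pos = filt > 0
        down = np.flatnonzero(pos[:-1] & ~pos[1:])  # positive-to-negative
        if down.size < 2:
            continue
        cands = []
        for a, b in zip(down[:-1], down[1:]):
            span = (b - a) / fs
            if not duration[0] <= span <= duration[1]:
                continue
            if not elig[a:b + 1].all():
                continue  # artifact-padded or out-of-stage candidates dropped
            seg = filt[a:b + 1]
            ti = int(np.argmin(seg))
            trough = float(seg[ti])
            peak = float(seg[ti:].max())
            cands.append((int(a), int(b), a + ti, trough, peak - trough))
        if not cands:
            continue
        tr = np.array([abs(c[3]) for c in cands])
        ptp = np.array([c[4] for c in cands])
        # strict exceedance with a relative tolerance, so exactly degenerate
        # candidate sets (SD = 0 up to float noise) yield no events
        thr_tr = tr.mean() + threshold_sd * tr.std()
        thr_tr += 1e-9 * max(1.0, abs(thr_tr))
        thr_ptp = ptp.mean() + threshold_sd * ptp.std()
        thr_ptp += 1e-9 * max(1.0, abs(thr_ptp))
        for (a, b, ti, trough, p2p), t_m, p_m in zip(cands, tr, ptp):
            if t_m > thr_tr and p_m > thr_ptp:
                out.append(DetectedEvent(
                    kind="so", channel=label, start_s=a / fs, end_s=b / fs,
                    peak_s=ti / fs, amplitude=float(t_m),
                    trough_uv=trough, ptp_uv=float(p2p)))
    return out


def count_events_window(events: list[DetectedEvent], epochs: EpochSet,
                        window: tuple[float, float] = (1.5, 2.5),
                        channels: tuple[str, ...] = LEFT_HEMISPHERE) -> dict:
    """Count detected events per trial in a post-cue window (closed interval).

    Events are counted when their ``peak_s`` lies in
    ``[onset + window[0], onset + window[1]]`` (edges included) on one of
    the requested channels. Returns per-condition mean counts over retained
    trials and the old-minus-control mean difference.
    """
    if window[0] < epochs.times[0] or window[1] > epochs.times[-1]:
        raise ValueError("counting window outside the epoch span")
    chans = set(channels)
    peaks = np.array([e.peak_s for e in events if e.channel in chans])
    meta = epochs.metadata
    counts = np.zeros(epochs.n_trials, dtype=int)
    for i, onset in enumerate(meta["onset_s"].to_numpy(float)):
        if peaks.size:
            counts[i] = int(np.sum((peaks >= onset + window[0]) &
                                   (peaks <= onset + window[1])))
    kept = epochs.retained
    per_condition = {}
    for cond in meta["condition"].unique():
        sel = kept & (meta["condition"] == cond).to_numpy()
        per_condition[cond] = float(counts[sel].mean()) if sel.any() else np.nan
    old_sel = kept & meta["condition"].isin(["old-object", "old-scene"]).to_numpy()
    ctrl_sel = kept & (meta["condition"] == "control").to_numpy()
    old_mean = float(counts[old_sel].mean()) if old_sel.any() else np.nan
    ctrl_mean = float(counts[ctrl_sel].mean()) if ctrl_sel.any() else np.nan
    return {
        "per_trial": pd.DataFrame({"condition": meta["condition"],
                                   "count": counts, "retained": kept}),
        "per_condition": per_condition,
        "old_minus_control": old_mean - ctrl_mean,
    }


def grand_average_event(rec: Recording, events: list[DetectedEvent],
                        half_width: float = 1.5) -> tuple[np.ndarray, np.ndarray]:
    """Average raw multi-channel segments aligned to event peaks.

    Returns ``(times, average)`` where ``average`` is channels x time.
    Events whose segment would be clipped by the recording edges are
    skipped; all segments clipped is an error.
    """
    fs = rec.sampling_rate
    half = int(round(half_width * fs))
    segs = []
    for ev in events:
        c = int(round(ev.peak_s * fs))
        if c - half < 0 or c + half + 1 > rec.n_samples:
            continue
        segs.append(rec.signal[:, c - half:c + half + 1])
    if not segs:
        raise ValueError("no event has a full segment inside the recording")
    times = np.arange(-half, half + 1) / fs
    return times, np.mean(segs, axis=0)
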