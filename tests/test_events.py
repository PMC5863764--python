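"""Spindle and slow-oscillation detection against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from naplab.events import (DetectedEvent, count_events_window, detect_sos,
                           detect_spindles, eligible_mask, events_to_frame,
                           grand_average_event, _smooth)
from naplab.filters import bandpass, envelope
from naplab.io_core import Recording
from conftest import make_epochs

FS = 200.0


def _recording(signal, hypnogram=None, labels=None, events=None):
    n_ep = int(np.ceil(signal.shape[1] / FS / 30))
    hyp = hypnogram if hypnogram is not None else \
        np.array(["N2"] * n_ep, dtype=object)
    ev = events if events is not None else pd.DataFrame(
        columns=["onset_s", "condition", "category", "adjective_id", "round"])
    return Recording(signal=signal, sampling_rate=FS,
                     channel_labels=labels or
                     [f"ch{i}" for i in range(signal.shape[0])],
                     hypnogram=hyp, events=ev)


def _noise(n, seed, rms=10.0):
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0)
    f[0] = f[1]
    x = np.fft.irfft(spec / np.sqrt(f), n)
    return x * rms / x.std()


# ---------------------------------------------------------------------------
# independent oracles (straight-line reimplementations)

def oracle_spindles(sig, elig, band, smooth_s=0.2, merge_gap=0.1,
                    dur=(0.5, 3.0)):
    env = envelope(bandpass(sig, FS, *band))
    k = int(round(smooth_s * FS))
    if k > 1:
        env = np.convolve(env, np.ones(k) / k, mode="same")
    thr = env[elig].mean() + 1.25 * env[elig].std()
    supra = (env > thr) & elig
    events, start = [], None
    runs = []
    for i, s in enumerate(supra):
        if s and start is None:
            start = i
        elif not s and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, supra.size))
    merged = []
    for a, b in runs:
        if merged and a - merged[-1][1] < merge_gap * FS \
                and all(elig[merged[-1][1]:a]):
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    for a, b in merged:
        if dur[0] <= (b - a) / FS <= dur[1]:
            peak = a + int(np.argmax(env[a:b]))
            events.append((a / FS, b / FS, peak / FS, env[peak]))
    return events


def oracle_sos(sig, elig, band=(0.5, 2.0), dur=(0.8, 2.0)):
    filt = bandpass(sig, FS, *band)
    downs = [i for i in range(filt.size - 1)
             if filt[i] > 0 and filt[i + 1] <= 0]
    cands = []
    for a, b in zip(downs[:-1], downs[1:]):
        if not dur[0] <= (b - a) / FS <= dur[1]:
            continue
        if not all(elig[a:b + 1]):
            continue
        seg = filt[a:b + 1]
        ti = int(np.argmin(seg))
        cands.append((a, b, a + ti, abs(seg[ti]), seg[ti:].max() - seg[ti]))
    if not cands:
        return []
    tr = np.array([c[3] for c in cands])
    ptp = np.array([c[4] for c in cands])
    thr_tr = tr.mean() + 1.25 * tr.std()
    thr_ptp = ptp.mean() + 1.25 * ptp.std()
    return [(a / FS, b / FS, t / FS, m_tr, m_ptp)
            for (a, b, t, m_tr, m_ptp) in cands
            if m_tr > thr_tr and m_ptp > thr_ptp]


class TestSpindleDetection:
    def test_single_burst_detected_once_containing_midpoint(self):
        n = int(120 * FS)
        sig = _noise(n, 0, rms=10.0)[None, :]
        t = np.arange(int(1.0 * FS)) / FS
        burst = (5 * 10.0) * np.hanning(t.size) * np.cos(2 * np.pi * 14 * t)
        mid = 60.0
        a = int((mid - 0.5) * FS)
        sig[0, a:a + t.size] += burst
        events = detect_spindles(_recording(sig))
        assert len(events) == 1
        assert events[0].start_s < mid < events[0].end_s
        assert events[0].kind == "spindle_fast"

    def test_sub_criterion_burst_ignored(self):
        # a burst whose supra-threshold run lasts well under 0.5 s
        n = int(120 * FS)
        sig = _noise(n, 1, rms=10.0)[None, :]
        t = np.arange(int(0.35 * FS)) / FS
        sig[0, int(60 * FS):int(60 * FS) + t.size] += \
            8.0 * np.hanning(t.size) * np.cos(2 * np.pi * 14 * t)
        rec = _recording(sig)
        env = _smooth(envelope(bandpass(sig[0], FS, 13, 16)), FS, 0.2)
        elig = eligible_mask(rec)
        thr = env[elig].mean() + 1.25 * env[elig].std()
        around = slice(int(59.5 * FS), int(61 * FS))
        assert 0 < (env[around] > thr).sum() / FS < 0.5  # precondition
        near_burst = [e for e in detect_spindles(rec)
                      if abs(0.5 * (e.start_s + e.end_s) - 60.17) < 0.8]
        assert near_burst == []

    def test_matches_bruteforce_oracle_exactly(self):
        n = int(180 * FS)
        rng = np.random.default_rng(2)
        sig = _noise(n, 2, rms=10.0)
        for c in [30.0, 70.0, 110.0, 150.0]:
            t = np.arange(int(rng.uniform(0.8, 1.2) * FS)) / FS
            sig[int(c * FS):int(c * FS) + t.size] += \
                40.0 * np.hanning(t.size) * np.cos(2 * np.pi * 14.5 * t)
        rec = _recording(sig[None, :])
        got = detect_spindles(rec)
        elig = eligible_mask(rec)
        want = oracle_spindles(sig, elig, (13.0, 16.0))
        assert len(got) == len(want) > 0
        for g, (a, b, p, amp) in zip(got, want):
            assert g.start_s == a and g.end_s == b and g.peak_s == p
            assert np.isclose(g.amplitude, amp)

    def test_dc_offset_invariance(self):
        n = int(120 * FS)
        sig = _noise(n, 3, rms=10.0)
        t = np.arange(int(1.0 * FS)) / FS
        sig[int(60 * FS):int(60 * FS) + t.size] += \
            40.0 * np.hanning(t.size) * np.cos(2 * np.pi * 14 * t)
        ev1 = detect_spindles(_recording(sig[None, :]))
        ev2 = detect_spindles(_recording(sig[None, :] + 500.0))
        assert [(e.start_s, e.end_s) for e in ev1] == \
               [(e.start_s, e.end_s) for e in ev2]

    def test_no_event_overlaps_padded_artifact(self):
        n = int(180 * FS)
        sig = _noise(n, 4, rms=10.0)
        t = np.arange(int(1.0 * FS)) / FS
        burst = 40.0 * np.hanning(t.size) * np.cos(2 * np.pi * 14 * t)
        for c in [40.0, 90.0, 140.0]:
            sig[int(c * FS):int(c * FS) + t.size] += burst
        art = np.zeros(n, bool)
        art[int(90.2 * FS):int(90.4 * FS)] = True  # artifact inside one burst
        rec = _recording(sig[None, :])
        events = detect_spindles(rec, artifact_mask=art)
        pad_lo, pad_hi = 90.2 - 1.0, 90.4 + 1.0
        for e in events:
            assert e.end_s <= pad_lo or e.start_s >= pad_hi

    def test_inverted_band_rejected(self, quiet_recording):
        rec, _ = quiet_recording
        with pytest.raises(ValueError, match="band"):
            detect_spindles(rec, band=(16.0, 13.0))


class TestSoDetection:
    def test_uniform_sinusoid_yields_no_events(self):
        # all candidates share identical metrics: none strictly exceeds
        # mean + 1.25 * (SD = 0)
        n = int(180 * FS)
        t = np.arange(n) / FS
        sig = (40 * np.sin(2 * np.pi * 1.0 * t))[None, :]
        hyp = np.array(["W"] * 2 + ["N2"] * 2 + ["W"] * 2, dtype=object)
        rec = _recording(sig, hypnogram=hyp)
        assert detect_sos(rec) == []

    def test_single_scaled_cycle_detected(self):
        n = int(180 * FS)
        t = np.arange(n) / FS
        sig = 20 * np.sin(2 * np.pi * 1.0 * t)
        a = int(60 * FS)
        sig[a:a + int(FS)] *= 3.0  # one cycle at triple amplitude
        hyp = np.array(["W"] + ["N2"] * 4 + ["W"], dtype=object)
        rec = _recording(sig[None, :], hypnogram=hyp)
        events = detect_sos(rec)
        assert len(events) >= 1
        assert any(abs(e.peak_s - 60.75) < 0.3 for e in events)
        # oracle agreement
        elig = eligible_mask(rec)
        want = oracle_sos(sig, elig)
        got = [(e.start_s, e.end_s, e.peak_s) for e in events]
        assert got == [(a, b, p) for a, b, p, *_ in want]

    def test_fast_oscillation_out_of_duration_gate(self):
        n = int(180 * FS)
        t = np.arange(n) / FS
        sig = (40 * np.sin(2 * np.pi * 3.0 * t))[None, :]
        rec = _recording(sig)
        assert detect_sos(rec) == []  # crossing spacing ~0.33 s < 0.8 s

    def test_matches_bruteforce_oracle_on_noise(self, quiet_recording):
        rec, _ = quiet_recording
        got = [e for e in detect_sos(rec) if e.channel == "F3"]
        elig = eligible_mask(rec)
        want = oracle_sos(rec.signal[0], elig)
        assert len(got) == len(want) > 0
        for g, (a, b, p, tr, ptp) in zip(got, want):
            assert (g.start_s, g.end_s, g.peak_s) == (a, b, p)
            assert np.isclose(g.amplitude, tr)
            assert np.isclose(g.ptp_uv, ptp)


class TestCounting:
    def _epochs(self, onsets, conditions):
        n = len(onsets)
        return make_epochs(np.zeros((n, 1, 800)), onsets=onsets,
                           conditions=conditions)

    def test_no_events_all_counts_zero(self):
        ep = self._epochs([10.0, 20.0], ["old-object", "control"])
        res = count_events_window([], ep)
        assert res["per_condition"]["old-object"] == 0
        assert res["old_minus_control"] == 0

    def test_boundary_peak_counted_closed_interval(self):
        ep = self._epochs([10.0], ["old-object"])
        ev = [DetectedEvent(kind="spindle_fast", channel="C3", start_s=11.0,
                            end_s=12.0, peak_s=11.5, amplitude=1.0)]
        for peak, expect in [(11.5, 1), (12.5, 1), (11.49, 0), (12.51, 0)]:
            ev[0].peak_s = peak
            res = count_events_window(ev, ep, window=(1.5, 2.5))
            assert res["per_condition"]["old-object"] == expect

    def test_channels_filter_respected(self):
        ep = self._epochs([10.0], ["old-object"])
        ev = [DetectedEvent(kind="spindle_fast", channel="F4", start_s=11.0,
                            end_s=12.0, peak_s=11.8, amplitude=1.0)]
        res = count_events_window(ev, ep)  # left hemisphere default
        assert res["per_condition"]["old-object"] == 0

    def test_window_outside_epoch_rejected(self):
        ep = self._epochs([10.0], ["old-object"])
        with pytest.raises(ValueError, match="window"):
            count_events_window([], ep, window=(2.0, 5.0))


class TestGrandAverage:
    def test_identical_bursts_average_to_one_burst(self):
        n = int(120 * FS)
        sig = np.zeros((1, n))
        t = np.arange(int(1.0 * FS)) / FS
        burst = 30 * np.hanning(t.size) * np.cos(2 * np.pi * 14 * t)
        centers = [30.0, 60.0, 90.0]
        events = []
        for c in centers:
            a = int((c - 0.5) * FS)
            sig[0, a:a + t.size] += burst
            peak = (a + int(np.argmax(np.abs(burst)))) / FS
            events.append(DetectedEvent(kind="spindle_fast", channel="ch0",
                                        start_s=c - 0.5, end_s=c + 0.5,
                                        peak_s=peak, amplitude=30.0))
        rec = _recording(sig)
        times, avg = grand_average_event(rec, events, half_width=1.0)
        single = grand_average_event(rec, events[:1], half_width=1.0)[1]
        np.testing.assert_allclose(avg, single, atol=1e-12)

    def test_all_segments_clipped_is_error(self):
        rec = _recording(np.zeros((1, int(120 * FS))))
        ev = [DetectedEvent(kind="spindle_fast", channel="ch0", start_s=0.0,
                            end_s=1.0, peak_s=0.5, amplitude=1.0)]
        with pytest.raises(ValueError):
            grand_average_event(rec, ev, half_width=2.0)

    def test_events_frame_roundtrip(self):
        ev = [DetectedEvent(kind="so", channel="F3", start_s=1.0, end_s=2.2,
                            peak_s=1.3, amplitude=30.0, trough_uv=-30.0,
                            ptp_uv=55.0)]
        df = events_to_frame(ev)
        assert list(df["channel"]) == ["F3"]
        assert events_to_frame([]).shape[0] == 0
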