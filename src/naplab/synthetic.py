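"""Synthetic polysomnography with ground truth for every pipeline stage.

The generator emulates the ingredients the analysis is sensitive to, each
with a known injected truth:

* 1/f ("pink") background noise per channel, matching the broadband
  spectral shape of sleep EEG without modeling sources;
* discrete slow oscillations (SOs): Hann-windowed 5-cycle slow-wave
  trains whose full-amplitude central cycle (trough before peak, 1-1.5 s
  period) is the detectable event, with a frontal-dominant channel
  gradient;
* fast-spindle bursts (13-16 Hz, flat-topped with SO-periodic flanking
  bumps) whose amplitude maximum sits at a configured SO phase with von
  Mises jitter;
* a cue schedule (ISI 4 s +/- 0.2 s) confined to N2/N3 sleep, with a
  stereotyped evoked SO/k-complex after every cue and an extra coupled
  spindle 1.5-2.5 s post-cue whose probability is multiplied by
  ``evoked_spindle_gain_old`` for old (memory) cues;
* category-specific spatiotemporal patterns: channel-weighted slow
  (<4 Hz) waveforms added in a fixed post-cue window for old-object and
  old-scene trials, scaled by ``category_pattern_snr``;
* behavioral retention tables in which the cued-minus-non-cued retention
  difference equals ``behavior_effect`` scaled by the subject's pattern
  distinctiveness.

Coupling phase convention: ``coupling_phase`` is expressed in the analysis
convention fixed by the coupling module (spindle amplitude peaking at the
SO trough -> 180 deg, at the SO up-state peak -> 0 deg, a quarter cycle
after the up-state -> -90 deg). Internally the burst center is therefore
placed where the SO cosine phase equals minus the configured angle.

All randomness derives from ``(config.seed, subject)`` through named
substreams, so each component can be regenerated independently and every
output is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf
from .io_core import (CHANNELS_8, EVENT_COLUMNS, HYPNO_EPOCH_S, Recording,
                      write_events_tsv, write_hypnogram_tsv)

# relative per-channel gains: SOs frontal-dominant, spindles centro-parietal
SO_TOPOGRAPHY = {"F3": 1.0, "F4": 1.0, "C3": 0.9, "C4": 0.9,
                 "P3": 0.8, "P4": 0.8, "O1": 0.7, "O2": 0.7}
SPINDLE_TOPOGRAPHY = {"F3": 0.75, "F4": 0.75, "C3": 1.0, "C4": 1.0,
                      "P3": 0.95, "P4": 0.95, "O1": 0.7, "O2": 0.7}

_STREAMS = {"background": 0, "so": 1, "spindle": 2, "cue": 3,
            "pattern": 4, "profile": 5, "behavior": 6}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults follow the recorded study conditions: 8 scalp channels sampled
    at 200 Hz, a 90-min nap, cueing with ISI 4 s +/- 200 ms, fast spindles
    at 13-16 Hz coupled near the SO up-state, category patterns in the
    1.7-2.3 s post-cue window, and 50 encoded items per category with an
    inclusion criterion of >= 14 correctly recalled items per category.
    """

    n_subjects: int = 27
    n_channels: int = 8
    channel_labels: tuple[str, ...] = CHANNELS_8
    sampling_rate: float = 200.0
    duration: float = 5400.0            # seconds
    background_exponent: float = 1.0    # 1/f slope of the noise spectrum
    background_rms: float = 15.0        # microvolts
    so_rate: float = 4.0                # events per eligible minute
    so_amplitude: float = 75.0          # microvolts (trough depth)
    spindle_rate: float = 3.0           # events per eligible minute
    spindle_freq: float = 14.0          # Hz, fast-spindle carrier
    spindle_amplitude: float = 20.0     # microvolts (envelope peak)
    spindle_duration: tuple[float, float] = (0.7, 1.3)   # seconds
    coupling_phase: float = 0.0         # degrees, analysis convention
    coupling_concentration: float = 4.0  # von Mises kappa
    cue_isi: float = 4.0                # seconds
    cue_isi_jitter: float = 0.2         # seconds, uniform +/-
    n_adjectives_per_category: int = 13
    n_rounds: int = 5
    evoked_spindle_prob: float = 0.25   # baseline per-cue probability
    evoked_spindle_gain_old: float = 2.0
    evoked_so_latency: tuple[float, float] = (0.8, 1.3)  # trough latency, s post-cue
    category_pattern_snr: float = 1.0   # pattern RMS / background RMS
    pattern_window: tuple[float, float] = (1.7, 2.3)     # seconds post-cue
    subject_sd: float = 0.35            # lognormal sigma of subject scaling
    behavior_effect: float = 0.2        # cued minus non-cued T3 retention
    n_items_per_category: int = 50
    t1_accuracy: float = 0.55
    t2_retention: float = 0.8
    t3_base_retention: float = 0.5
    categorisation_error: float = 0.035
    discrimination_yes_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = ["so_rate", "spindle_rate", "so_amplitude", "spindle_amplitude",
                  "background_rms", "category_pattern_snr",
                  "coupling_concentration", "evoked_spindle_prob"]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -180.0 < self.coupling_phase <= 180.0:
            raise ValueError("coupling_phase must lie in (-180, 180] degrees")
        if not 13.0 <= self.spindle_freq <= 16.0:
            raise ValueError("spindle_freq must lie in the fast band [13, 16] Hz")
        if self.sampling_rate <= 2 * self.spindle_freq:
            raise ValueError("sampling_rate must exceed twice the spindle frequency")
        if self.n_channels != len(self.channel_labels):
            raise ValueError("n_channels does not match channel_labels")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class GroundTruth:
    """Injected events and latent per-subject quantities for one subject.

    ``so_events`` / ``spindle_events`` list every injected event with its
    timing, channel gains applied, and (for spindles) the injected SO phase
    in the analysis convention. ``true_distinctiveness`` is the subject's
    realized pattern signal-to-noise; ``true_benefit`` the subject's
    expected cued-minus-non-cued retention difference.
    """

    subject: int
    so_events: pd.DataFrame = field(repr=False)
    spindle_events: pd.DataFrame = field(repr=False)
    cues: pd.DataFrame = field(repr=False)
    pattern_weights: dict = field(repr=False)
    true_distinctiveness: float = 0.0
    true_benefit: float = 0.0
    subject_scale: float = 1.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subject": self.subject,
            "so_events": self.so_events.to_dict(orient="list"),
            "spindle_events": self.spindle_events.to_dict(orient="list"),
            "cues": self.cues.to_dict(orient="list"),
            "pattern_weights": {k: np.asarray(v).tolist()
                                for k, v in self.pattern_weights.items()},
            "true_distinctiveness": self.true_distinctiveness,
            "true_benefit": self.true_benefit,
            "subject_scale": self.subject_scale,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(subject=d["subject"],
                   so_events=pd.DataFrame(d["so_events"]),
                   spindle_events=pd.DataFrame(d["spindle_events"]),
                   cues=pd.DataFrame(d["cues"]),
                   pattern_weights={k: np.asarray(v)
                                    for k, v in d["pattern_weights"].items()},
                   true_distinctiveness=d["true_distinctiveness"],
                   true_benefit=d["true_benefit"],
                   subject_scale=d["subject_scale"])


def _rng(config: SimConfig, subject: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(subject, _STREAMS[stream]))
    return np.random.default_rng(ss)


def subject_profile(config: SimConfig, subject: int) -> dict:
    """Latent per-subject quantities, independent of the signal synthesis.

    ``scale`` is lognormal with mean 1 (sigma = ``subject_sd``) and drives
    both the subject's pattern SNR and the subject's true cueing benefit,
    making distinctiveness and behavior positively linked by construction.
    """
    rng = _rng(config, subject, "profile")
    sd = config.subject_sd
    scale = float(np.exp(rng.normal(-sd ** 2 / 2, sd)))
    snr = config.category_pattern_snr * scale
    return {"scale": scale, "snr": snr,
            "true_benefit": config.behavior_effect * scale,
            "true_distinctiveness": snr}


# ---------------------------------------------------------------------------
# signal ingredients

def pink_noise(n: int, exponent: float, rms: float,
               rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    spec /= f ** (exponent / 2.0)
    x = np.fft.irfft(spec, n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


SO_TRAIN_CYCLES = 5      # Hann-windowed slow-wave train around the main cycle
SPINDLE_AM_CYCLES = 5    # envelope modulation span, flat over the central cycle


def so_train(duration_s: float, amplitude: float, fs: float) -> np.ndarray:
    """A slow-oscillation event: a 5-cycle Hann-windowed slow-wave train.

    ``duration_s`` is the period of the central (full-amplitude) cycle,
    which runs trough first, then peak. The immediately flanking cycles
    reach ~65% amplitude (SOs travel in trains, not as isolated single
    periods) and the outermost cycles under 10%. The tapered train gives
    the 0.5-2 Hz band a coherent instantaneous phase across the event
    neighbourhood, which the coupling estimator relies on; an isolated
    single-cycle transient would leave the phase ill-defined over most of
    the +/- 1.5 s coupling segment.
    """
    n = int(round(SO_TRAIN_CYCLES * duration_s * fs))
    u = np.arange(n) / fs
    mid = (SO_TRAIN_CYCLES - 1) / 2 * duration_s
    return -amplitude * np.hanning(n) * np.sin(2 * np.pi * (u - mid) / duration_s)


def spindle_burst(duration_s: float, amplitude: float, freq: float, fs: float,
                  carrier_phase: float) -> np.ndarray:
    """Gaussian-windowed sinusoid; envelope max at the burst center.

    Used for uncoupled (standalone) spindles only; coupled spindles are
    amplitude-modulated by the host SO phase instead.
    """
    n = int(round(duration_s * fs))
    t = (np.arange(n) - n / 2) / fs
    env = np.exp(-0.5 * (t / (duration_s / 6.0)) ** 2)
    return amplitude * env * np.cos(2 * np.pi * freq * t + carrier_phase)


def coupled_spindle(so_duration_s: float, amplitude: float, freq: float,
                    fs: float, carrier_phase: float,
                    central_frac: float = 1.3, side_level: float = 0.35
                    ) -> tuple[np.ndarray, int]:
    """Spindle burst shaped to recur at the host SO train's period.

    The envelope is a flat-topped (Tukey) central burst of
    ``central_frac`` * SO period, flanked one SO period to each side by
    bumps at ``side_level`` relative amplitude (spindle activity waxes
    and wanes with the slow oscillation). The flat top keeps the
    supra-threshold run of a near-threshold event longer than the 0.5 s
    duration criterion, and the flanking bumps give the spindle-band
    amplitude envelope a periodic component at the SO frequency, which
    the coupling estimator's envelope-phase extraction relies on. The
    central burst must stay shorter than ~1.5 SO periods or the
    envelope's fundamental at the SO frequency inverts.

    Returns ``(waveform, peak_index)``; the caller places ``peak_index``
    (the envelope maximum, at the array center) at the time where the
    host SO phase equals the target coupling phase.
    """
    from scipy.signal.windows import tukey

    d = so_duration_s
    n_c = int(round(central_frac * d * fs))
    n = int(round(3.4 * d * fs))
    env = np.zeros(n)
    center = n // 2
    w_c = tukey(n_c, 0.6)
    a = center - n_c // 2
    env[a:a + n_c] = np.maximum(env[a:a + n_c], w_c)
    n_s = int(round(0.9 * d * fs))
    w_s = side_level * tukey(n_s, 0.6)
    for sign in (-1, 1):
        a = center + sign * int(round(d * fs)) - n_s // 2
        b = a + n_s
        a2, b2 = max(a, 0), min(b, n)
        env[a2:b2] = np.maximum(env[a2:b2], w_s[a2 - a:n_s - (b - b2)])
    env *= amplitude
    u = np.arange(n) / fs
    return env * np.cos(2 * np.pi * freq * u + carrier_phase), center


def make_hypnogram(duration_s: float) -> np.ndarray:
    """Deterministic stage sequence: brief W/N1 onset, then N2/N3 cycling."""
    n_ep = int(np.ceil(duration_s / HYPNO_EPOCH_S))
    stages = ["W", "W", "N1", "N1"]
    block = ["N2"] * 10 + ["N3"] * 14 + ["N2"] * 8 + ["REM"] * 4
    while len(stages) < n_ep:
        stages.extend(block)
    return np.array(stages[:n_ep], dtype=object)


def _eligible_blocks(mask: np.ndarray, fs: float,
                     margin_s: float = 2.0) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` shrunk by ``margin_s`` on both sides."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    margin = int(round(margin_s * fs))
    blocks = []
    for lo, hi in zip(idx[::2], idx[1::2]):
        lo, hi = lo + margin, hi - margin
        if hi > lo:
            blocks.append((int(lo), int(hi)))
    return blocks


# ---------------------------------------------------------------------------
# main generators

def generate_recording(config: SimConfig, subject: int = 0
                       ) -> tuple[Recording, GroundTruth]:
    """Synthesize one subject's recording and its ground truth."""
    fs = config.sampling_rate
    n_samples = int(round(config.duration * fs))
    n_ch = config.n_channels
    labels = list(config.channel_labels)
    profile = subject_profile(config, subject)

    hypnogram = make_hypnogram(config.duration)
    rec_stub = Recording(signal=np.zeros((1, n_samples)), sampling_rate=fs,
                         channel_labels=["x"], hypnogram=hypnogram,
                         events=pd.DataFrame(columns=EVENT_COLUMNS))
    sleep_mask = rec_stub.stage_mask(("N2", "N3"))
    blocks = _eligible_blocks(sleep_mask, fs)
    eligible_s = sum(hi - lo for lo, hi in blocks) / fs
    if eligible_s < 60.0:
        raise ValueError(
            f"duration {config.duration:.0f} s leaves only {eligible_s:.0f} s of "
            "eligible N2/N3 sleep; too short to place the requested events")

    rng_bg = _rng(config, subject, "background")
    signal = np.stack([
        pink_noise(n_samples, config.background_exponent, config.background_rms,
                   rng_bg)
        for _ in range(n_ch)])

    so_gain = np.array([SO_TOPOGRAPHY.get(l, 1.0) for l in labels])
    sp_gain = np.array([SPINDLE_TOPOGRAPHY.get(l, 1.0) for l in labels])

    # --- background SOs -----------------------------------------------------
    rng_so = _rng(config, subject, "so")
    n_so = int(round(config.so_rate * eligible_s / 60.0))
    so_rows = _place_sos(signal, n_so, blocks, config, rng_so, so_gain, fs,
                         evoked=False, cue_index=-1)

    # --- background spindles, coupled to the background SOs -----------------
    rng_sp = _rng(config, subject, "spindle")
    n_sp = int(round(config.spindle_rate * eligible_s / 60.0))
    sp_rows = []
    if so_rows and n_sp:
        # at most one spindle per host SO; the spindle rate is capped by the
        # SO rate, which exceeds it under the default conditions
        hosts = rng_sp.permutation(len(so_rows))[:min(n_sp, len(so_rows))]
        for h in np.atleast_1d(hosts):
            row = _add_coupled_spindle(signal, so_rows[h], config, rng_sp,
                                       sp_gain, fs, evoked=False, cue_index=-1)
            if row is not None:
                sp_rows.append(row)

    # --- cue schedule --------------------------------------------------------
    rng_cue = _rng(config, subject, "cue")
    cues = _schedule_cues(config, blocks, fs, rng_cue)

    # --- cue-evoked k-complexes and spindle surge ---------------------------
    p_ctrl = config.evoked_spindle_prob
    p_old = p_ctrl * config.evoked_spindle_gain_old
    if p_old > 1.0:
        warnings.warn("evoked spindle probability for old cues clipped to 1")
        p_old = 1.0
    for ci, cue in cues.iterrows():
        onset = cue["onset_s"]
        lat = rng_cue.uniform(*config.evoked_so_latency)
        d = rng_cue.uniform(1.0, 1.4)
        # the drawn latency anchors the central trough of the evoked train
        start = int(round((onset + lat - 2.25 * d) * fs))
        row = _inject_so(signal, start, d, 0.8 * config.so_amplitude,
                         config, so_gain, fs, evoked=True, cue_index=ci)
        if row is not None:
            so_rows.append(row)
        p = p_old if cue["condition"] in ("old-object", "old-scene") else p_ctrl
        if rng_cue.random() < p:
            center = onset + rng_cue.uniform(1.6, 2.4)
            d2 = rng_cue.uniform(1.0, 1.5)
            theta = np.radians(config.coupling_phase) + \
                rng_cue.vonmises(0.0, config.coupling_concentration)
            # align the host train so the spindle envelope max lands at center
            peak_off = 2 * d2 + \
                d2 * ((-theta - np.pi / 2) % (2 * np.pi)) / (2 * np.pi)
            so_start = center - peak_off
            host = _inject_so(signal, int(round(so_start * fs)), d2,
                              config.so_amplitude, config, so_gain, fs,
                              evoked=True, cue_index=ci)
            if host is not None:
                row = _add_coupled_spindle(signal, host, config, rng_cue,
                                           sp_gain, fs, evoked=True,
                                           cue_index=ci, theta=theta)
                if row is not None:
                    sp_rows.append(row)

    # --- category patterns ---------------------------------------------------
    rng_pat = _rng(config, subject, "pattern")
    weights = _pattern_weights(n_ch, rng_pat)
    amp = profile["snr"] * config.background_rms
    w0, w1 = config.pattern_window
    n_pat = int(round((w1 - w0) * fs))
    tp = np.arange(n_pat) / fs
    window = np.hanning(n_pat)
    for cat in ("object", "scene"):
        prof = np.zeros(n_pat)
        for f_hz in (1.5, 3.0):
            prof += np.sin(2 * np.pi * f_hz * tp + rng_pat.uniform(0, 2 * np.pi))
        prof *= window
        rms = np.sqrt(np.mean(prof ** 2))
        weights[f"profile_{cat}"] = prof / rms if rms > 0 else prof
    for ci, cue in cues.iterrows():
        if cue["condition"] == "control":
            continue
        cat = cue["category"]
        start = int(round((cue["onset_s"] + w0) * fs))
        if start < 0 or start + n_pat > n_samples:
            continue
        pattern = amp * np.outer(weights[f"w_{cat}"], weights[f"profile_{cat}"])
        signal[:, start:start + n_pat] += pattern

    so_df = pd.DataFrame(so_rows) if so_rows else pd.DataFrame(
        columns=["channel_ref", "start_s", "trough_s", "peak_s", "end_s",
                 "duration_s", "amplitude", "evoked", "cue_index"])
    sp_df = pd.DataFrame(sp_rows) if sp_rows else pd.DataFrame(
        columns=["channel_ref", "start_s", "center_s", "end_s", "duration_s",
                 "amplitude", "freq", "so_phase_deg", "evoked", "cue_index"])

    rec = Recording(signal=signal, sampling_rate=fs, channel_labels=labels,
                    hypnogram=hypnogram, events=cues)
    truth = GroundTruth(subject=subject, so_events=so_df, spindle_events=sp_df,
                        cues=cues.copy(), pattern_weights=weights,
                        true_distinctiveness=profile["true_distinctiveness"],
                        true_benefit=profile["true_benefit"],
                        subject_scale=profile["scale"])
    return rec, truth


def _pattern_weights(n_ch: int, rng: np.random.Generator) -> dict:
    w_obj = rng.standard_normal(n_ch)
    w_obj /= np.linalg.norm(w_obj)
    w_sce = rng.standard_normal(n_ch)
    w_sce -= w_obj * (w_obj @ w_sce)  # orthogonal categories
    w_sce /= np.linalg.norm(w_sce)
    return {"w_object": w_obj, "w_scene": w_sce}


def _inject_so(signal: np.ndarray, start: int, duration_s: float,
               amplitude: float, config: SimConfig, gains: np.ndarray,
               fs: float, evoked: bool, cue_index: int) -> dict | None:
    """Add a 3-cycle SO train starting at sample ``start``.

    The recorded event times describe the central (detectable) cycle:
    ``start_s``/``end_s`` are its zero crossings, ``trough_s``/``peak_s``
    its extrema. ``wave_start_s`` keeps the full train origin for
    alignment of coupled spindles.
    """
    wave = so_train(duration_s, amplitude, fs)
    n = wave.size
    if start < 0 or start + n > signal.shape[1]:
        return None
    signal[:, start:start + n] += gains[:, None] * wave
    d = duration_s
    t0 = start / fs
    return {"channel_ref": "all", "wave_start_s": t0,
            "start_s": t0 + 2 * d, "trough_s": t0 + 2.25 * d,
            "peak_s": t0 + 2.75 * d, "end_s": t0 + 3 * d,
            "duration_s": d, "amplitude": amplitude,
            "evoked": evoked, "cue_index": cue_index}


def _place_sos(signal: np.ndarray, n_so: int, blocks: list, config: SimConfig,
               rng: np.random.Generator, gains: np.ndarray, fs: float,
               evoked: bool, cue_index: int) -> list[dict]:
    rows: list[dict] = []
    if not blocks or n_so == 0:
        return rows
    weights = np.array([hi - lo for lo, hi in blocks], dtype=float)
    weights /= weights.sum()
    occupied: list[tuple[float, float]] = []
    attempts = 0
    while len(rows) < n_so and attempts < 50 * max(n_so, 1):
        attempts += 1
        b = rng.choice(len(blocks), p=weights)
        lo, hi = blocks[b]
        d = rng.uniform(1.0, 1.5)
        n = int(round(SO_TRAIN_CYCLES * d * fs))
        if hi - lo <= n:
            continue
        start = int(rng.integers(lo, hi - n))
        # track only the central 3 cycles; the weak outer tapers may overlap
        s0, s1 = (start + d * fs) / fs, (start + 4 * d * fs) / fs
        if any(s0 < e + 1.0 and s1 > s - 1.0 for s, e in occupied):
            continue
        row = _inject_so(signal, start, d, config.so_amplitude, config, gains,
                         fs, evoked, cue_index)
        if row is not None:
            rows.append(row)
            occupied.append((s0, s1))
    if len(rows) < n_so:
        raise ValueError(
            f"could only place {len(rows)}/{n_so} slow oscillations; "
            "the recording is too short for the requested event rates")
    return rows


def _coupled_center(so_row: dict, theta: float) -> float:
    """Time at which the host SO cosine phase equals -theta (central cycle).

    The analysis sign convention flips the SO phase, so the envelope
    maximum is placed where the cosine phase is s = -theta; the template
    -sin(2 pi u / d) has cosine phase 2 pi u / d + pi / 2 within the
    central cycle starting two periods into the train.
    """
    d = so_row["duration_s"]
    s = -theta
    return so_row["wave_start_s"] + 2 * d + \
        d * ((s - np.pi / 2) % (2 * np.pi)) / (2 * np.pi)


def _add_coupled_spindle(signal: np.ndarray, so_row: dict, config: SimConfig,
                         rng: np.random.Generator, gains: np.ndarray, fs: float,
                         evoked: bool, cue_index: int,
                         theta: float | None = None) -> dict | None:
    """Add a spindle whose envelope maximum sits at the injected SO phase."""
    if theta is None:
        theta = np.radians(config.coupling_phase) + \
            rng.vonmises(0.0, config.coupling_concentration)
    d = so_row["duration_s"]
    wave, peak_idx = coupled_spindle(d, config.spindle_amplitude,
                                     config.spindle_freq, fs,
                                     rng.uniform(0, 2 * np.pi))
    n = wave.size
    start = int(round(_coupled_center(so_row, theta) * fs)) - peak_idx
    if start < 0 or start + n > signal.shape[1]:
        return None
    signal[:, start:start + n] += gains[:, None] * wave
    theta_deg = float(np.degrees(np.angle(np.exp(1j * theta))))
    return {"channel_ref": "all", "start_s": start / fs,
            "center_s": (start + peak_idx) / fs, "end_s": (start + n) / fs,
            "duration_s": d, "amplitude": config.spindle_amplitude,
            "freq": config.spindle_freq, "so_phase_deg": theta_deg,
            "evoked": evoked, "cue_index": cue_index}


def _schedule_cues(config: SimConfig, blocks: list, fs: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Present the TMR set round by round with jittered ISI inside N2/N3."""
    n_cat = config.n_adjectives_per_category
    n_ctrl = max(1, (2 * n_cat + 1) // 2)  # control set = half the cued set
    adjectives = (
        [("old-object", "object", i) for i in range(n_cat)] +
        [("old-scene", "scene", n_cat + i) for i in range(n_cat)] +
        [("control", "control", 2 * n_cat + i) for i in range(n_ctrl)])

    # walk through eligible blocks, leaving room for a full epoch around cues
    rows = []
    block_iter = iter(sorted(blocks))
    try:
        lo, hi = next(block_iter)
    except StopIteration:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    t = lo / fs + 1.5
    for rnd in range(config.n_rounds):
        order = rng.permutation(len(adjectives))
        for k in order:
            cond, cat, adj = adjectives[k]
            while t + 3.5 > hi / fs:
                try:
                    lo, hi = next(block_iter)
                except StopIteration:
                    return pd.DataFrame(rows, columns=EVENT_COLUMNS) if rows \
                        else pd.DataFrame(columns=EVENT_COLUMNS)
                t = lo / fs + 1.5
            rows.append({"onset_s": round(t, 4), "condition": cond,
                         "category": cat, "adjective_id": adj, "round": rnd})
            t += config.cue_isi + rng.uniform(-config.cue_isi_jitter,
                                              config.cue_isi_jitter)
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# behavior

def generate_behavior(config: SimConfig, truths) -> pd.DataFrame:
    """Per-item recall outcomes at T1/T2/T3 for one or many subjects.

    For each subject, items recalled at T1 are split half/half into cued
    and non-cued (balanced within category). T3 retention of T2-recalled
    items is ``t3_base_retention`` for non-cued items and that plus the
    subject's true benefit for cued items, so the expected cohort-mean
    cued-minus-non-cued difference equals ``behavior_effect``.
    """
    if isinstance(truths, GroundTruth):
        truths = [truths]
    frames = [_behavior_one(config, t) for t in truths]
    return pd.concat(frames, ignore_index=True)


def _behavior_one(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    rng = _rng(config, truth.subject, "behavior")
    n = config.n_items_per_category
    p_cued = config.t3_base_retention + truth.true_benefit
    if not 0.0 <= p_cued <= 1.0:
        warnings.warn("cued T3 retention probability clipped into [0, 1]")
        p_cued = float(np.clip(p_cued, 0.0, 1.0))

    rows = []
    for cat in ("object", "scene"):
        # enforce the >= 14 correctly recalled items inclusion criterion
        for _ in range(1000):
            t1 = rng.random(n) < config.t1_accuracy
            if t1.sum() >= 14:
                break
        correct_idx = np.flatnonzero(t1)
        cued = np.zeros(n, dtype=bool)
        half = rng.permutation(correct_idx)[:len(correct_idx) // 2 +
                                            int(rng.random() < 0.5) *
                                            (len(correct_idx) % 2)]
        cued[half] = True
        catcheck = rng.random(n) >= config.categorisation_error
        t2 = t1 & (rng.random(n) < config.t2_retention)
        p3 = np.where(cued, p_cued, config.t3_base_retention)
        t3 = t2 & (rng.random(n) < p3)
        disc = rng.random(n) < config.discrimination_yes_rate
        for i in range(n):
            rows.append({
                "subject": truth.subject, "category": cat,
                "item_id": f"{cat}_{i}", "cued": bool(cued[i]),
                "t1_correct": bool(t1[i]), "t2_correct": bool(t2[i]),
                "t3_correct": bool(t3[i]),
                "categorisation_correct": bool(catcheck[i]),
                "discrimination_yes": bool(disc[i]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures on disk

def write_fixture(recording: Recording, truth: GroundTruth,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write EDF signal, events TSV, hypnogram TSV, and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": out / f"sub-{truth.subject:02d}_sleep.edf",
        "events": out / f"sub-{truth.subject:02d}_events.tsv",
        "hypnogram": out / f"sub-{truth.subject:02d}_hypnogram.tsv",
        "truth": out / f"sub-{truth.subject:02d}_truth.json",
    }
    edf.write_edf(paths["edf"], recording.signal, recording.sampling_rate,
                  recording.channel_labels)
    write_events_tsv(recording.events, paths["events"])
    write_hypnogram_tsv(recording.hypnogram, paths["hypnogram"])
    truth.to_json(paths["truth"])
    return paths
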