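"""Generator contracts: determinism, ground-truth consistency, fixtures."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from naplab import (GroundTruth, SimConfig, generate_behavior,
                    generate_recording, subject_profile, write_fixture)
from naplab import behavior as beh
from naplab.filters import bandpass, envelope
from naplab.io_core import read_recording
from naplab.edf import quantization_step


def _profile_truth(cfg, s):
    prof = subject_profile(cfg, s)
    return GroundTruth(subject=s, so_events=None, spindle_events=None,
                       cues=None, pattern_weights={},
                       true_distinctiveness=prof["true_distinctiveness"],
                       true_benefit=prof["true_benefit"],
                       subject_scale=prof["scale"])


class TestRecordingGeneration:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(duration=240.0, seed=11, n_rounds=1,
                        n_adjectives_per_category=3)
        rec1, tr1 = generate_recording(cfg, 0)
        rec2, tr2 = generate_recording(cfg, 0)
        np.testing.assert_array_equal(rec1.signal, rec2.signal)
        pd.testing.assert_frame_equal(tr1.spindle_events, tr2.spindle_events)
        pd.testing.assert_frame_equal(tr1.so_events, tr2.so_events)
        pd.testing.assert_frame_equal(rec1.events, rec2.events)

    def test_subjects_and_seeds_differ(self):
        cfg = SimConfig(duration=240.0, seed=11, n_rounds=0)
        rec_a, _ = generate_recording(cfg, 0)
        rec_b, _ = generate_recording(cfg, 1)
        rec_c, _ = generate_recording(SimConfig(duration=240.0, seed=12,
                                                n_rounds=0), 0)
        assert not np.array_equal(rec_a.signal, rec_b.signal)
        assert not np.array_equal(rec_a.signal, rec_c.signal)

    def test_no_events_requested_means_none_injected(self):
        cfg = SimConfig(duration=300.0, seed=2, so_rate=0.0, spindle_rate=0.0,
                        n_rounds=0, category_pattern_snr=0.0)
        rec, truth = generate_recording(cfg, 0)
        assert len(truth.so_events) == 0
        assert len(truth.spindle_events) == 0
        # 13-16 Hz envelope stays within plain background statistics
        elig = rec.stage_mask(("N2", "N3"))
        env = envelope(bandpass(rec.signal[2], cfg.sampling_rate, 13, 16))[elig]
        assert env.max() < env.mean() + 8 * env.std()

    def test_degenerate_von_mises_concentration(self):
        cfg = SimConfig(duration=600.0, seed=3, coupling_phase=0.0,
                        coupling_concentration=1e6, n_rounds=0)
        _, truth = generate_recording(cfg, 0)
        phases = np.radians(truth.spindle_events["so_phase_deg"].to_numpy())
        assert len(phases) >= 10
        resultant = np.abs(np.mean(np.exp(1j * phases)))
        assert np.sqrt(-2 * np.log(resultant)) < 1e-2  # circular SD -> 0

    def test_events_lie_inside_recording_and_sleep(self):
        cfg = SimConfig(duration=300.0, seed=4, n_rounds=1,
                        n_adjectives_per_category=3)
        rec, truth = generate_recording(cfg, 0)
        for df, col in [(truth.so_events, "trough_s"),
                        (truth.spindle_events, "center_s")]:
            t = df[col].to_numpy()
            assert (t >= 0).all() and (t <= rec.duration).all()
        stage = rec.stage_mask(("N2", "N3"))
        onset_idx = (rec.events["onset_s"].to_numpy() *
                     cfg.sampling_rate).astype(int)
        assert stage[onset_idx].all()

    def test_cue_schedule_isi_and_conditions(self, short_recording):
        rec, _ = short_recording
        ev = rec.events
        assert set(ev["condition"]) <= {"old-object", "old-scene", "control"}
        # ISI within 4 +/- 0.2 s inside a continuous cueing stretch
        d = np.diff(np.sort(ev["onset_s"].to_numpy()))
        within = d[d < 5.0]
        assert within.size > 0
        assert within.min() >= 3.8 - 1e-6 and within.max() <= 4.2 + 1e-6

    def test_too_short_duration_raises(self):
        with pytest.raises(ValueError, match="[Tt]oo short|eligible"):
            generate_recording(SimConfig(duration=90.0, seed=0), 0)

    @pytest.mark.parametrize("field,value", [
        ("so_rate", -1.0), ("coupling_phase", 200.0), ("spindle_freq", 20.0),
        ("sampling_rate", 25.0), ("category_pattern_snr", -0.5),
    ])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ValueError):
            SimConfig(**{field: value})

    def test_evoked_spindle_gain_reflected_in_truth(self):
        cfg = SimConfig(duration=1500.0, seed=5, evoked_spindle_gain_old=2.0,
                        evoked_spindle_prob=0.25)
        rec, truth = generate_recording(cfg, 0)
        sp = truth.spindle_events
        evoked = sp[sp["evoked"]]
        cue_cond = rec.events["condition"]
        n_old = (cue_cond != "control").sum()
        n_ctrl = (cue_cond == "control").sum()
        rate_old = (cue_cond.loc[evoked["cue_index"]] != "control").sum() / n_old
        rate_ctrl = (cue_cond.loc[evoked["cue_index"]] == "control").sum() / n_ctrl
        assert rate_ctrl > 0
        # binomial sampling error on ~150 old / ~75 control cues
        assert 1.3 < rate_old / rate_ctrl < 3.1


class TestBehaviorGeneration:
    def test_null_effect_gives_zero_mean_benefit(self):
        cfg = SimConfig(seed=6, behavior_effect=0.0, n_subjects=30,
                        n_items_per_category=200)
        table = generate_behavior(cfg, [_profile_truth(cfg, s)
                                        for s in range(30)])
        benefit = beh.tmr_benefit(table)
        assert abs(benefit.mean()) < 0.03

    def test_ceiling_retention(self):
        cfg = SimConfig(seed=7, behavior_effect=0.0, t2_retention=1.0,
                        t3_base_retention=1.0, n_subjects=3)
        table = generate_behavior(cfg, [_profile_truth(cfg, s)
                                        for s in range(3)])
        assert beh.retention(table, "T1", "T2") == 1.0
        assert beh.retention(table, "T2", "T3") == 1.0

    def test_benefit_tracks_distinctiveness(self):
        """Subjects with more distinct patterns gain more from cueing."""
        cfg = SimConfig(seed=8, behavior_effect=0.2, n_subjects=40,
                        n_items_per_category=200)
        truths = [_profile_truth(cfg, s) for s in range(40)]
        table = generate_behavior(cfg, truths)
        benefit = beh.tmr_benefit(table).reindex(range(40))
        rho, p = spearmanr([t.true_distinctiveness for t in truths],
                           benefit.values)
        assert rho > 0.3 and p < 0.01

    def test_inclusion_criterion_met(self):
        cfg = SimConfig(seed=9, n_subjects=5)
        table = generate_behavior(cfg, [_profile_truth(cfg, s)
                                        for s in range(5)])
        counts = (table[table["t1_correct"]]
                  .groupby(["subject", "category"]).size())
        assert (counts >= 14).all()

    def test_out_of_range_probability_clipped_with_warning(self):
        cfg = SimConfig(seed=10, behavior_effect=0.9, t3_base_retention=0.5,
                        n_subjects=1)
        with pytest.warns(UserWarning, match="clipped"):
            generate_behavior(cfg, [_profile_truth(cfg, 0)])


class TestFixtures:
    def test_roundtrip_within_quantization(self, tmp_path, short_recording):
        rec, truth = short_recording
        paths = write_fixture(rec, truth, tmp_path)
        rec2 = read_recording(paths["edf"], paths["events"], paths["hypnogram"],
                              expected_labels=tuple(rec.channel_labels))
        step = quantization_step(rec.signal).max()
        assert np.max(np.abs(rec2.signal - rec.signal)) <= step
        assert list(rec2.channel_labels) == list(rec.channel_labels)
        pd.testing.assert_frame_equal(
            rec2.events, rec.events, check_dtype=False)
        truth2 = GroundTruth.from_json(paths["truth"])
        assert truth2.true_benefit == truth.true_benefit

    def test_empty_event_list_gives_header_only_tsv(self, tmp_path):
        cfg = SimConfig(duration=300.0, seed=12, n_rounds=0,
                        category_pattern_snr=0.0)
        rec, truth = generate_recording(cfg, 0)
        paths = write_fixture(rec, truth, tmp_path)
        lines = paths["events"].read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split("\t")[0] == "onset_s"

    def test_edf_header_lists_configured_labels_in_order(self, tmp_path,
                                                         short_recording):
        import mne
        rec, truth = short_recording
        paths = write_fixture(rec, truth, tmp_path)
        raw = mne.io.read_raw_edf(str(paths["edf"]), verbose="error")
        assert raw.ch_names == list(rec.channel_labels)
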