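"""Beat-level feature extraction, envelopes and quality control."""

import numpy as np
import pytest

from cuffsim.features import (Recording, beat_features, detect_foot,
                              detect_r_peaks, lower_envelope, qc_reject)
from cuffsim.synth import inject_artifact


def impulse_train_ecg(duration=60.0, hr=1.0, fs=500.0, noise=0.0, seed=0):
    t = np.arange(0.0, duration, 1.0 / fs)
    ecg = np.zeros_like(t)
    for bt in np.arange(0.5, duration - 0.2, 1.0 / hr):
        ecg += np.exp(-0.5 * ((t - bt) / 0.004) ** 2)
    if noise:
        ecg += np.random.default_rng(seed).normal(0.0, noise, len(t))
    return ecg


class TestRPeaks:
    def test_one_hertz_train(self):
        times = detect_r_peaks(impulse_train_ecg(), 500.0)
        assert abs(len(times) - 60) <= 1
        assert np.allclose(np.diff(times), 1.0, atol=0.01)

    def test_noise_robustness_20db(self):
        # peak amplitude 1.0, noise sd 0.1 -> 20 dB
        clean = detect_r_peaks(impulse_train_ecg(), 500.0)
        noisy = detect_r_peaks(impulse_train_ecg(noise=0.1, seed=3), 500.0)
        assert len(noisy) == len(clean)

    def test_flat_signal_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = detect_r_peaks(np.zeros(5000), 500.0)
        assert out.size == 0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(np.zeros(100), 100.0)


class TestFootDetection:
    @staticmethod
    def pulse(onset, fs=125.0, duration=3.0, amp=1.0, shift=0.0):
        # half-sine upstroke: maximal slope right at the onset, so the
        # intersecting-tangent foot coincides with the true onset
        t = np.arange(0.0, duration, 1.0 / fs)
        y = np.zeros_like(t)
        rise = (t >= onset + shift) & (t < onset + shift + 0.3)
        y[rise] = amp * np.sin(np.pi * (t[rise] - onset - shift) / 0.6)
        y[t >= onset + shift + 0.3] = amp
        return y

    def test_known_onset_recovered_within_4ms(self):
        y = self.pulse(1.0)
        feet = detect_foot(y, 125.0, [(0.5, 2.0)])
        assert abs(feet[0] - 1.0) < 0.004

    def test_time_shift_equivariance(self):
        f0 = detect_foot(self.pulse(1.0), 125.0, [(0.5, 2.0)])[0]
        f1 = detect_foot(self.pulse(1.0, shift=0.4), 125.0, [(0.9, 2.4)])[0]
        assert f1 - f0 == pytest.approx(0.4, abs=1e-6)

    def test_amplitude_invariance(self):
        f1 = detect_foot(self.pulse(1.0, amp=1.0), 125.0, [(0.5, 2.0)])[0]
        f2 = detect_foot(self.pulse(1.0, amp=7.3), 125.0, [(0.5, 2.0)])[0]
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_no_upslope_gives_nan(self):
        feet = detect_foot(np.linspace(1, 0, 375), 125.0, [(0.5, 2.0)])
        assert np.isnan(feet[0])


class TestBeatFeatures:
    def test_baseline_dpat_near_zero(self, clean_recording):
        _, rec = clean_recording
        bs = beat_features(rec)
        pre = bs.beat_time < 4.5
        assert abs(np.nanmean(bs.dpat[pre])) < 0.002

    def test_round_trip_within_one_sample(self, preset, clean_recording, timing_table):
        """Extracted delta-PAT/PTT match the generating timing model to 8 ms."""
        _, rec = clean_recording
        bs = beat_features(rec)
        truth = timing_table.set_index(timing_table.beat_time.round().astype(int))
        idx = np.round(bs.beat_time).astype(int)
        on_ramp = (idx >= preset.cuff.t_start + 1) & (idx < 27)
        dpat_true = truth.dpat.reindex(idx[on_ramp]).to_numpy()
        dptt_true = 0.5 * truth.dptt_distal.reindex(idx[on_ramp]).to_numpy()
        ok = np.isfinite(dpat_true)
        assert np.nanmax(np.abs(bs.dpat[on_ramp][ok] - dpat_true[ok])) < 1 / 125.0
        assert np.nanmax(np.abs(bs.dptt_abp_ppg[on_ramp][ok] - dptt_true[ok])) < 1 / 125.0

    def test_blocked_beats_have_no_pat(self, clean_recording):
        _, rec = clean_recording
        bs = beat_features(rec)
        deep = (bs.beat_time > 36) & (bs.beat_time < 48)
        assert np.all(np.isnan(bs.pat[deep]))

    def test_patient_like_distal_ptt_drop(self, clean_recording):
        """Max drop in the ABP-PPG transit is ~-10 ms, as in the OR data."""
        _, rec = clean_recording
        bs = beat_features(rec)
        on_ramp = (bs.cuff_at_beat > 50) & (bs.cuff_at_beat < 100)
        drop = np.nanmin(bs.dptt_abp_ppg[on_ramp])
        assert -0.016 < drop < -0.005


class TestLowerEnvelope:
    def test_constant_signal(self):
        cuff = np.concatenate([np.zeros(125 * 2), np.linspace(0, 100, 125 * 20)])
        abp = np.full_like(cuff, 80.0)
        env = lower_envelope(abp, cuff, 125.0, 1.0)
        assert np.allclose(env.bp_env, 80.0)

    def test_envelope_below_signal_and_shape(self, preset, preset_sim):
        env = lower_envelope(preset_sim.p_art_distal, preset_sim.p_cuff,
                             1000.0, preset.wave.heart_rate)
        # envelope rises during build-up then decays toward equilibrium
        i_max = int(np.argmax(env.bp_env))
        assert env.bp_env[i_max] > env.bp_env[0] + 10.0
        assert env.bp_env[-1] < env.bp_env[i_max] - 10.0
        assert 0 < i_max < len(env.bp_env) - 1
        # non-increasing after the last inflow beat
        tail = env.bp_env[env.cuff_grid >= preset.cuff.p_max]
        assert np.all(np.diff(tail) <= 0.0)

    def test_on_grid_resampling(self, preset, preset_sim):
        env = lower_envelope(preset_sim.p_art_distal, preset_sim.p_cuff,
                             1000.0, preset.wave.heart_rate)
        g = env.on_grid(1.0)
        assert np.all(np.diff(g.cuff_grid) > 0)
        assert g.cuff_grid[0] == 0.0

    def test_too_few_beats_rejected(self):
        cuff = np.linspace(0, 100, 125 * 3)
        with pytest.raises(ValueError):
            lower_envelope(np.full_like(cuff, 80.0), cuff, 125.0, 1.0)


class TestQC:
    def test_clean_recording_kept(self, noisy_recording):
        _, rec = noisy_recording
        keep, reason = qc_reject(rec)
        assert keep and reason is None

    def test_pulse_step_rejected_at_threshold(self, noisy_recording):
        s, rec = noisy_recording
        t_step = s.cuff.t_start + 20.0
        bad = inject_artifact(rec, ("pulse_step", t_step, 25.0))
        keep, reason = qc_reject(bad)
        assert not keep and reason == "pulse_step"

    def test_small_pulse_step_kept(self, noisy_recording):
        s, rec = noisy_recording
        ok = inject_artifact(rec, ("pulse_step", s.cuff.t_start + 20.0, 10.0))
        keep, _ = qc_reject(ok)
        assert keep

    def test_dropout_rejected(self, noisy_recording):
        _, rec = noisy_recording
        bad = inject_artifact(rec, ("dropout", 8.0, 3.0))
        keep, reason = qc_reject(bad)
        assert not keep and reason == "dropout"

    def test_flush_rejected(self, noisy_recording):
        _, rec = noisy_recording
        bad = inject_artifact(rec, ("flush", 10.0, 2.0))
        keep, reason = qc_reject(bad)
        assert not keep and reason == "flush"

    def test_dropout_skips_beats_in_extraction(self, clean_recording):
        _, rec = clean_recording
        bad = inject_artifact(rec, ("dropout", 8.0, 3.0))
        bs_ok = beat_features(rec)
        bs_bad = beat_features(bad)
        window = (bs_ok.beat_time >= 7.5) & (bs_ok.beat_time <= 11.5)
        lost = (np.isfinite(bs_ok.ppg_foot_time[window]).sum()
                - np.isfinite(bs_bad.ppg_foot_time[window]).sum())
        assert lost >= 2

    def test_deterministic_decision(self, noisy_recording):
        _, rec = noisy_recording
        assert qc_reject(rec) == qc_reject(rec)
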