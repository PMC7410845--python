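"""FFR pipeline: filtering, epoching, pitch tracking, scoring, decoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tonelearn import ffr_analysis, synthgen
from tonelearn.types import EpochSet, PitchTrack, Recording


class TestBandpass:
    FS = 8000.0

    def test_passband_tone_preserved(self):
        t = np.arange(int(self.FS)) / self.FS
        x = np.sin(2 * np.pi * 500 * t)
        y = ffr_analysis.bandpass_zero_phase(x, self.FS)
        mid = slice(1000, -1000)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_attenuated_over_20db(self):
        t = np.arange(int(2 * self.FS)) / self.FS
        drift = np.sin(2 * np.pi * 10 * t)
        y = ffr_analysis.bandpass_zero_phase(drift, self.FS)
        mid = slice(2000, -2000)
        atten_db = 20 * np.log10(np.abs(y[mid]).max())
        assert atten_db < -20

    def test_impulse_response_is_symmetric(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        y = ffr_analysis.bandpass_zero_phase(x, self.FS)
        np.testing.assert_allclose(y[1:2000][::-1], y[2001:4000], atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ffr_analysis.bandpass_zero_phase(np.zeros(100), 1000.0, hi=600.0)


class TestSegmentation:
    FS = 8000.0

    def _recording(self, n=2.0):
        return Recording(np.zeros(int(n * self.FS)), self.FS)

    def test_clean_recording_keeps_all_epochs(self):
        rec = self._recording()
        onsets = 0.2 + np.arange(10) * 0.15
        eset = ffr_analysis.segment_ffr_epochs(rec, onsets, 0.1)
        assert eset.n_epochs == 10 and eset.n_rejected == 0

    def test_spike_epoch_rejected_at_threshold(self):
        rec = self._recording()
        onsets = 0.2 + np.arange(5) * 0.2
        spike_at = int((onsets[2] + 0.05) * self.FS)
        rec.data[spike_at] = 60.0  # beyond the +/-50 uV limit
        eset = ffr_analysis.segment_ffr_epochs(rec, onsets, 0.1)
        assert eset.n_epochs == 4 and eset.n_rejected == 1

    def test_constant_signal_zeroed_by_baseline_correction(self):
        rec = self._recording()
        rec.data[:] = 7.0
        eset = ffr_analysis.segment_ffr_epochs(rec, [0.5], 0.1)
        np.testing.assert_allclose(eset.epochs, 0.0, atol=1e-12)

    def test_epoch_past_end_dropped_with_warning(self):
        rec = self._recording(0.5)
        with pytest.warns(UserWarning):
            eset = ffr_analysis.segment_ffr_epochs(rec, [0.2, 0.48], 0.1)
        assert eset.n_epochs == 1

    def test_raising_reject_threshold_never_loses_epochs(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.normal(0, 30, int(2 * self.FS)), self.FS)
        onsets = 0.2 + np.arange(8) * 0.2
        kept = [
            ffr_analysis.segment_ffr_epochs(rec, onsets, 0.1, reject_uv=thr).n_epochs
            for thr in (20.0, 35.0, 50.0, 80.0, 1000.0)
        ]
        assert all(a <= b for a, b in zip(kept, kept[1:]))


class TestAveraging:
    def test_identical_epochs_average_to_one_epoch(self):
        ep = np.tile(np.sin(np.linspace(0, 6, 100)), (5, 1))
        eset = EpochSet(fs=1000.0, epochs=ep, window=(0, 0.1))
        wave, n = ffr_analysis.average_epochs(eset)
        np.testing.assert_allclose(wave, ep[0])
        assert n == 5

    def test_epoch_plus_negation_cancel(self):
        e = np.sin(np.linspace(0, 6, 100))
        eset = EpochSet(fs=1000.0, epochs=np.stack([e, -e]), window=(0, 0.1))
        wave, _ = ffr_analysis.average_epochs(eset)
        np.testing.assert_allclose(wave, 0.0, atol=1e-12)

    def test_noise_variance_shrinks_as_one_over_n(self):
        rng = np.random.default_rng(1)
        single_var, avg_var = [], []
        n = 64
        for _ in range(40):
            ep = rng.standard_normal((n, 200))
            single_var.append(ep.var())
            avg_var.append(ep.mean(axis=0).var())
        ratio = np.mean(single_var) / np.mean(avg_var)
        assert ratio == pytest.approx(n, rel=0.2)

    def test_empty_set_rejected(self):
        eset = EpochSet(fs=1000.0, epochs=np.empty((0, 10)), window=(0, 0.01))
        eset.epochs = np.empty((0, 10))
        with pytest.raises(ValueError):
            ffr_analysis.average_epochs(eset)


class TestPitchTracking:
    FS = 8000.0

    def test_stationary_tone_within_2hz(self):
        t = np.arange(int(0.3 * self.FS)) / self.FS
        track = ffr_analysis.track_pitch_autocorr(np.sin(2 * np.pi * 130 * t), self.FS)
        assert np.nanmax(np.abs(track.f0 - 130.0)) < 2.0

    def test_linear_sweep_within_5hz_midframes(self):
        t = np.arange(int(0.3 * self.FS)) / self.FS
        f_inst = 100 + 50 * t / 0.3
        sweep = np.sin(2 * np.pi * np.cumsum(f_inst) / self.FS)
        track = ffr_analysis.track_pitch_autocorr(sweep, self.FS)
        gt = np.interp(track.times, t, f_inst)
        assert np.nanmax(np.abs(track.f0 - gt)[2:-2]) < 5.0

    def test_frame_count_closed_form_300ms(self):
        t = np.arange(int(0.3 * self.FS)) / self.FS
        track = ffr_analysis.track_pitch_autocorr(np.sin(2 * np.pi * 130 * t), self.FS)
        assert track.f0.size == 27  # 1 + (300 - 40) // 10

    @given(n_ms=st.integers(min_value=40, max_value=800))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_frame_count_closed_form_property(self, n_ms):
        fs = 1000.0
        n = int(n_ms * fs / 1000)
        frame_n, hop_n = 40, 10
        assert ffr_analysis.n_frames(n, frame_n, hop_n) == 1 + (n - frame_n) // hop_n

    @pytest.mark.parametrize("scale", [0.01, 1.0, 250.0])
    def test_amplitude_invariance(self, scale):
        t = np.arange(int(0.25 * self.FS)) / self.FS
        base = np.sin(2 * np.pi * 170 * t)
        ref = ffr_analysis.track_pitch_autocorr(base, self.FS)
        scaled = ffr_analysis.track_pitch_autocorr(scale * base, self.FS)
        np.testing.assert_allclose(ref.f0, scaled.f0, equal_nan=True)

    def test_empty_f0_range_rejected(self):
        with pytest.raises(ValueError):
            ffr_analysis.track_pitch_autocorr(
                np.zeros(1000), self.FS, f0_range=(10.0, 12.0)
            )


class TestStimulusResponseR:
    def _track(self, values):
        return PitchTrack(np.linspace(0, 0.4, len(values)), np.asarray(values))

    def test_identical_contours_correlate_perfectly(self):
        c = self._track(np.linspace(110, 200, 30))
        r, n = ffr_analysis.stimulus_response_r(c, c)
        assert r == pytest.approx(1.0)
        assert n == 30

    def test_mirrored_contour_anticorrelates(self):
        f = np.linspace(110, 200, 30)
        r, _ = ffr_analysis.stimulus_response_r(self._track(f), self._track(310 - f))
        assert r == pytest.approx(-1.0)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        f = 150 + 30 * rng.random(25)
        g = 120 + 50 * rng.random(25)
        r1, _ = ffr_analysis.stimulus_response_r(self._track(f), self._track(g))
        r2, _ = ffr_analysis.stimulus_response_r(
            self._track(2.0 * f + 10.0), self._track(0.5 * g + 40.0)
        )
        assert r1 == pytest.approx(r2)

    def test_too_few_common_voiced_frames_reported_missing(self):
        a = PitchTrack(np.array([0.0, 0.1, 0.2]), np.array([100.0, np.nan, np.nan]))
        b = PitchTrack(np.array([0.0, 0.1, 0.2]), np.array([100.0, 120.0, np.nan]))
        r, n = ffr_analysis.stimulus_response_r(a, b)
        assert np.isnan(r) and n < 3

    def test_high_snr_end_to_end_exceeds_095(self, t2_stimulus):
        cfg = synthgen.FfrSimConfig(n_trials=30, snr_db=40, seed=0)
        _, rec, onsets = synthgen.synthesize_ffr_epochs(t2_stimulus, cfg)
        filtered = ffr_analysis.bandpass_zero_phase(rec)
        eset = ffr_analysis.segment_ffr_epochs(filtered, onsets, t2_stimulus.duration)
        wave, _ = ffr_analysis.average_epochs(eset)
        track = ffr_analysis.track_pitch_autocorr(wave, cfg.fs)
        r, _ = ffr_analysis.stimulus_response_r(t2_stimulus.f0, track)
        assert r > 0.95

    def test_r_nondecreasing_in_snr_in_expectation(self, t2_stimulus):
        means = []
        for snr in (-25.0, -5.0, 20.0):
            rs = []
            for seed in range(8):
                cfg = synthgen.FfrSimConfig(n_trials=20, snr_db=snr, seed=seed)
                _, rec, onsets = synthgen.synthesize_ffr_epochs(t2_stimulus, cfg)
                eset = ffr_analysis.segment_ffr_epochs(
                    ffr_analysis.bandpass_zero_phase(rec), onsets, t2_stimulus.duration
                )
                wave, _ = ffr_analysis.average_epochs(eset)
                track = ffr_analysis.track_pitch_autocorr(wave, cfg.fs)
                r, _ = ffr_analysis.stimulus_response_r(t2_stimulus.f0, track)
                rs.append(r)
            means.append(np.nanmean(rs))
        assert means[0] <= means[1] <= means[2]


class TestEncodingLmm:
    def _scores(self, seed=0, post_shift=None):
        rng = np.random.default_rng(seed)
        rows = []
        for g, group in enumerate(("Control", "tVNS-easy", "tVNS-hard")):
            for i in range(8):
                pid = f"{group}-{i}"
                base = rng.normal(0.6, 0.1)
                for session in ("pre", "post"):
                    r = base + rng.normal(0, 0.05)
                    if post_shift and session == "post" and group == post_shift[0]:
                        r += post_shift[1]
                    rows.append((pid, group, session, r))
        return pd.DataFrame(rows, columns=["participant", "group", "session", "r"])

    def test_injected_session_shift_recovered(self):
        fit = ffr_analysis.fit_encoding_lmm(self._scores(1, ("tVNS-easy", 0.2)))
        term = "group[tVNS-easy]:session[post]"
        assert fit.params[term] > 0.1
        assert fit.p[term] < 0.05

    def test_null_interaction_small(self):
        fit = ffr_analysis.fit_encoding_lmm(self._scores(2))
        assert abs(fit.params["group[tVNS-easy]:session[post]"]) < 0.1

    def test_single_session_rejected(self):
        scores = self._scores(0)
        with pytest.raises(ValueError):
            ffr_analysis.fit_encoding_lmm(scores[scores["session"] == "pre"])

    def test_low_averaging_n_flagging_rule(self):
        rng = np.random.default_rng(0)
        cohort = rng.normal(995, 37, 20).round().tolist()
        scores = pd.DataFrame({"n_averaged": cohort + [686]})
        flags = ffr_analysis.flag_low_averaging_n(scores)
        assert flags.sum() == 1 and bool(flags.iloc[-1])


class TestConfusion:
    def test_change_is_post_minus_pre(self):
        pre = ffr_analysis.ConfusionScore(20.0, 100, participant="P1")
        post = ffr_analysis.ConfusionScore(30.0, 100, participant="P1")
        assert ffr_analysis.confusion_change(pre, post) == pytest.approx(10.0)
        assert ffr_analysis.confusion_change(pre, pre) == 0.0

    def test_participant_mismatch_rejected(self):
        pre = ffr_analysis.ConfusionScore(20.0, 100, participant="P1")
        post = ffr_analysis.ConfusionScore(30.0, 100, participant="P2")
        with pytest.raises(ValueError):
            ffr_analysis.confusion_change(pre, post)

    def test_group_mean_delta_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pre = rng.uniform(10, 40, 9)
        post = rng.uniform(10, 40, 9)
        deltas = [
            ffr_analysis.confusion_change(
                ffr_analysis.ConfusionScore(a, 100, participant=f"P{i}"),
                ffr_analysis.ConfusionScore(b, 100, participant=f"P{i}"),
            )
            for i, (a, b) in enumerate(zip(pre, post))
        ]
        assert np.mean(deltas) == pytest.approx((post - pre).mean())

    def test_separable_tones_decode_below_10pct(self, catalog):
        pools = {}
        for tone, (f0a, f0b) in {"T1": (180, 180), "T2": (100, 140)}.items():
            t = np.linspace(0, 0.4, 41)
            from tonelearn.types import StimulusSpec

            stim = StimulusSpec(
                "syn", "t", tone, 0.4, PitchTrack(t, np.linspace(f0a, f0b, 41))
            )
            cfg = synthgen.FfrSimConfig(n_trials=120, snr_db=10, seed=ord(tone[1]))
            pools[tone], _, _ = synthgen.synthesize_ffr_epochs(stim, cfg)
        score = ffr_analysis.hmm_decode(
            pools, train_n=60, test_n=60, avg_n=30, n_subaverages=30, seed=4
        )
        assert score.percent_misclassified < 10.0

    def test_insufficient_trials_rejected(self, t2_stimulus):
        cfg = synthgen.FfrSimConfig(n_trials=10, seed=0)
        eset, _, _ = synthgen.synthesize_ffr_epochs(t2_stimulus, cfg)
        with pytest.raises(ValueError):
            ffr_analysis.hmm_decode(
                {"T1": eset, "T2": eset}, train_n=50, test_n=50, avg_n=10
            )
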