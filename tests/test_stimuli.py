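"""Stimulus chain: silence truncation, filtering, calibration, epoching,
click trains and regressor construction."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speechabr import stimuli
from speechabr.stimuli import (
    AudioStimulus,
    highpass_speech,
    make_click_train,
    make_regressor_clicks,
    make_regressor_speech,
    normalize_rms,
    render_click_audio,
    section_epochs,
    truncate_silences,
)

FS = 24414.0


def tone(freq, dur, fs=FS, amp=0.1):
    t = np.arange(int(round(dur * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestTruncateSilences:
    # constructed at fs=1000 Hz so tone/silence segments align with the
    # 10-ms silence-detection frames and sample counts are exact
    FS_T = 1000.0

    def test_long_pause_shortened_to_max(self):
        # speech / 1.2 s silence / speech -> 0.5 s silence, 0.7 s shorter
        fs = self.FS_T
        x = np.concatenate([tone(100, 1.0, fs), np.zeros(1200), tone(100, 1.0, fs)])
        out = truncate_silences(AudioStimulus(x, fs))
        assert out.n_samples == x.size - 700

    def test_no_long_pause_is_identity(self):
        fs = self.FS_T
        x = np.concatenate([tone(100, 0.5, fs), np.zeros(400), tone(100, 0.5, fs)])
        out = truncate_silences(AudioStimulus(x, fs))
        assert np.array_equal(out.samples, x)

    def test_mixed_runs_remove_exact_excess(self):
        # 2 s and 0.3 s pauses: only the first is shortened, by exactly 1.5 s
        fs = self.FS_T
        x = np.concatenate(
            [tone(100, 1.0, fs), np.zeros(2000), tone(100, 1.0, fs),
             np.zeros(300), tone(100, 1.0, fs)]
        )
        out = truncate_silences(AudioStimulus(x, fs))
        assert x.size - out.n_samples == 1500

    def test_content_order_preserved(self):
        fs = self.FS_T
        a, b = tone(50, 0.5, fs), tone(150, 0.5, fs)
        x = np.concatenate([a, np.zeros(1000), b])
        out = truncate_silences(AudioStimulus(x, fs))
        assert np.array_equal(out.samples[: a.size], a)
        assert np.array_equal(out.samples[-b.size :], b)

    def test_empty_audio_rejected(self):
        with pytest.raises(ValueError):
            truncate_silences(AudioStimulus(np.array([]), FS))


class TestHighpassSpeech:
    def test_dc_removed(self):
        audio = AudioStimulus(np.full(int(FS), 0.3), FS)
        out = highpass_speech(audio)
        # anti-causal filter: settling transient sits at the *end*
        assert np.max(np.abs(out.samples[: -200])) < 1e-6 * 0.3

    def test_cutoff_attenuation_is_3db(self):
        audio = AudioStimulus(tone(1000, 2.0), FS)
        out = highpass_speech(audio, cutoff=1000.0)
        mid = slice(int(0.5 * FS), int(1.5 * FS))
        gain_db = 20 * np.log10(
            np.std(out.samples[mid]) / np.std(audio.samples[mid])
        )
        assert gain_db == pytest.approx(-3.01, abs=0.1)

    def test_passband_gain_matches_analytic_response(self):
        audio = AudioStimulus(tone(8000, 1.0), FS)
        out = highpass_speech(audio, cutoff=1000.0)
        mid = slice(int(0.2 * FS), int(0.8 * FS))
        gain_db = 20 * np.log10(np.std(out.samples[mid]) / np.std(audio.samples[mid]))
        analytic_db = 20 * np.log10(8.0 / np.sqrt(1 + 8.0**2))  # first-order HP at 8x fc
        assert abs(gain_db) < 0.5
        assert gain_db == pytest.approx(analytic_db, abs=0.3)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass_speech(AudioStimulus(tone(100, 0.1), FS), cutoff=13000.0)


class TestNormalizeRms:
    def test_unit_sine_scaling(self):
        audio = AudioStimulus(np.sin(2 * np.pi * np.arange(4096) / 32), 1000.0)
        out = normalize_rms(audio)
        np.testing.assert_allclose(
            out.samples, audio.samples * 0.01 * np.sqrt(2), rtol=1e-6
        )

    def test_fixed_point(self):
        x = np.random.default_rng(0).standard_normal(1000)
        x *= 0.01 / np.sqrt(np.mean(x**2))
        out = normalize_rms(AudioStimulus(x, 1000.0))
        np.testing.assert_allclose(out.samples, x, rtol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_rms(AudioStimulus(np.zeros(100), 1000.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_target_rms_reached(self, seed):
        x = np.random.default_rng(seed).standard_normal(512) * 10 ** (seed % 5 - 2)
        out = normalize_rms(AudioStimulus(x, 1000.0))
        assert out.rms == pytest.approx(0.01, rel=1e-9)


class TestSectionEpochs:
    def test_paper_geometry_two_epochs_60s_novel(self):
        audio = AudioStimulus(np.random.default_rng(1).standard_normal(int(124 * FS)), FS)
        ep = section_epochs(audio)
        assert ep.n_epochs == 2
        # each epoch advances the source by 60 s of novel material
        n_step = int(60 * FS)
        assert np.array_equal(ep.raw_epochs[1].samples[: 100], audio.samples[n_step : n_step + 100])

    def test_overlap_region_shared_pre_fade(self):
        audio = AudioStimulus(np.random.default_rng(2).standard_normal(int(124 * FS)), FS)
        ep = section_epochs(audio)
        n_ov = int(4 * FS)
        np.testing.assert_array_equal(
            ep.raw_epochs[0].samples[-n_ov:], ep.raw_epochs[1].samples[:n_ov]
        )

    def test_zero_overlap_is_partition(self):
        audio = AudioStimulus(np.arange(int(8 * 1000)), 1000.0)
        ep = section_epochs(audio, epoch_dur=2.0, fade_dur=0.1, overlap_dur=0.0)
        rebuilt = np.concatenate([e.samples for e in ep.raw_epochs])
        np.testing.assert_array_equal(rebuilt, audio.samples)

    def test_fades_applied(self):
        audio = AudioStimulus(np.ones(int(10 * 1000)), 1000.0)
        ep = section_epochs(audio, epoch_dur=4.0, fade_dur=1.0, overlap_dur=0.0)
        e = ep.epochs[0].samples
        assert e[0] == 0.0 and e[-1] == pytest.approx(0.0, abs=1e-9)
        assert np.all(e[int(1.5 * 1000) : int(2.5 * 1000)] == 1.0)

    def test_fade_longer_than_epoch_rejected(self):
        audio = AudioStimulus(np.ones(1000), 100.0)
        with pytest.raises(ValueError):
            section_epochs(audio, epoch_dur=2.0, fade_dur=1.5, overlap_dur=0.0)


class TestClickTrains:
    def test_expected_total_click_count_per_session(self):
        train = make_click_train(seed=0)
        assert train.rate * train.duration * 20 == pytest.approx(26460.0)

    def test_periodic_click_placement(self):
        train = make_click_train(rate=44.1, duration=1.0, timing="periodic")
        assert train.n_clicks == 44
        np.testing.assert_allclose(train.click_times, np.arange(44) / 44.1)

    def test_poisson_count_statistics(self):
        # mean and variance of the count both match rate*duration (Fano ~ 1)
        counts = np.array(
            [make_click_train(duration=30.0, seed=s).n_clicks for s in range(10000)]
        )
        expected = 44.1 * 30.0
        se = np.sqrt(expected / counts.size)
        assert abs(counts.mean() - expected) < 3 * se
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.05)

    def test_poisson_gaps_exponential(self):
        train = make_click_train(duration=120.0, seed=3)
        gaps = np.diff(train.click_times)
        assert gaps.mean() == pytest.approx(1 / 44.1, rel=0.05)
        # memoryless: CV of exponential gaps is 1
        assert gaps.std() / gaps.mean() == pytest.approx(1.0, abs=0.1)

    def test_seeded_reproducibility(self):
        a = make_click_train(seed=42)
        b = make_click_train(seed=42)
        np.testing.assert_array_equal(a.click_times, b.click_times)


class TestRenderClickAudio:
    def test_pulse_duration_near_82_us(self):
        train = make_click_train(duration=1.0, seed=0)
        audio = render_click_audio(train)
        width_us = train.click_width_samples / audio.fs * 1e6
        assert width_us == pytest.approx(82.0, abs=0.5)

    def test_single_click_occupies_two_samples(self):
        train = stimuli.ClickTrain(np.array([0.0]), duration=0.01)
        audio = render_click_audio(train)
        assert set(np.flatnonzero(audio.samples)) == {0, 1}

    def test_nonzero_count_and_amplitude(self):
        train = make_click_train(rate=44.1, duration=1.0, timing="periodic")
        audio = render_click_audio(train)
        assert np.count_nonzero(audio.samples) == 2 * train.n_clicks
        # rarefaction clicks at the peak of the 75 dB SPL reference tone
        assert audio.samples.min() == pytest.approx(-np.sqrt(2) * 0.01)


class TestSpeechRegressor:
    def test_rectification_splits_signs(self):
        audio = AudioStimulus(np.array([1.0, -2.0, 3.0]), 100.0)
        reg = make_regressor_speech(audio, fs_eeg=100.0)  # same rate: no resampling
        np.testing.assert_array_equal(reg.pos[0], [1.0, 0.0, 3.0])
        np.testing.assert_array_equal(reg.neg[0], [0.0, 2.0, 0.0])

    def test_positive_signal_has_empty_negative_branch(self):
        audio = AudioStimulus(np.abs(np.random.default_rng(0).standard_normal(500)), 100.0)
        reg = make_regressor_speech(audio, fs_eeg=100.0)
        assert np.all(reg.neg == 0)

    def test_sinusoid_branches_balanced(self):
        audio = AudioStimulus(np.sin(2 * np.pi * 300 * np.arange(int(FS)) / FS), FS)
        reg = make_regressor_speech(audio, fs_eeg=10000.0)
        assert reg.pos.mean() == pytest.approx(reg.neg.mean(), rel=0.01)

    def test_rectification_is_lossless_split(self, speech_audio):
        # pos - neg reconstructs the band-limited signed audio
        reg = make_regressor_speech(speech_audio, fs_eeg=10000.0)
        signed = stimuli.downsample_signed_audio(speech_audio, fs_eeg=10000.0)
        r = np.corrcoef(reg.pos[0] - reg.neg[0], signed[0])[0, 1]
        assert r > 0.99

    def test_branches_are_non_negative(self, speech_audio):
        reg = make_regressor_speech(speech_audio, fs_eeg=10000.0)
        assert reg.pos.min() >= 0 and reg.neg.min() >= 0


class TestClickRegressor:
    def test_unit_impulse_placement(self):
        train = stimuli.ClickTrain(np.array([0.1]), duration=0.2)
        reg = make_regressor_clicks(train, fs_eeg=10000.0)
        assert reg.kind == "impulse_train"
        assert np.flatnonzero(reg.pos[0]).tolist() == [1000]
        assert reg.pos[0, 1000] == 1.0

    def test_round_half_even_tie_break(self):
        # 0.10005 s * 10 kHz = 1000.5 -> banker's rounding to 1000
        train = stimuli.ClickTrain(np.array([0.10005]), duration=0.2)
        reg = make_regressor_clicks(train, fs_eeg=10000.0)
        assert np.flatnonzero(reg.pos[0]).tolist() == [1000]

    def test_collisions_saturate_to_unit_height(self, caplog):
        train = stimuli.ClickTrain(np.array([0.1, 0.10004]), duration=0.2)
        with caplog.at_level(logging.WARNING):
            reg = make_regressor_clicks(train, fs_eeg=10000.0)
        assert reg.pos[0].sum() == 1.0
        assert any("collided" in r.message for r in caplog.records)

    def test_impulse_count_matches_distinct_clicks(self):
        train = make_click_train(duration=10.0, seed=9)
        reg = make_regressor_clicks(train, fs_eeg=10000.0)
        n_distinct = np.unique(np.round(train.click_times * 10000.0).astype(int)).size
        assert reg.pos.sum() == n_distinct
        assert np.array_equal(reg.pos, reg.neg)
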