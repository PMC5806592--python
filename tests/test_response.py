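"""Deconvolution core: identities, click-triggered-average equivalence,
kernel recovery, scaling laws, normalization and the traditional ABR."""

import numpy as np
import pytest
from scipy import signal

from speechabr import metrics
from speechabr.eeg import EegEpochs
from speechabr.response import (
    ResponseWaveform,
    apply_gn,
    average_abr_traditional,
    click_triggered_average,
    combine_conditions,
    compute_gn,
    cumulative_deconvolve,
    deconvolve,
    postfilter_response,
)
from speechabr.simulate import make_abr_kernel
from speechabr.stimuli import ClickTrain, Regressor, make_click_train, make_regressor_clicks

FS = 10000.0


def impulse_regressor(indices, n, n_epochs=1):
    rows = np.zeros((n_epochs, n))
    for e, idx in enumerate(indices):
        rows[e, idx] = 1.0
    return Regressor(rows, rows.copy(), FS, "impulse_train")


class TestDeconvolutionIdentities:
    def test_single_impulse_recovers_placed_kernel(self):
        k = make_abr_kernel(FS)[:400]
        n = 20000
        eeg = np.zeros((2, n))
        for e, idx in enumerate([5000, 7000]):
            eeg[e, idx : idx + k.size] = k
        reg = impulse_regressor([[5000], [7000]], n, n_epochs=2)
        resp = deconvolve(EegEpochs(eeg, FS), reg, lags_ms=(-150.0, 350.0))
        rec = resp.amplitude[resp.n_pre : resp.n_pre + k.size]
        assert np.max(np.abs(rec - k)) < 1e-6 * np.max(np.abs(k))

    def test_matches_click_triggered_average_exactly(self):
        rng = np.random.default_rng(0)
        trains = [make_click_train(duration=10.0, seed=s) for s in (1, 2)]
        reg = make_regressor_clicks(trains, FS)
        n = int(10.1 * FS)
        k = make_abr_kernel(FS)[:300]
        eeg = np.stack([
            signal.fftconvolve(np.pad(reg.pos[e], (0, n - reg.n_samples)), k)[:n]
            + 5.0 * rng.standard_normal(n)
            for e in range(2)
        ])
        epochs = EegEpochs(eeg, FS)
        resp = deconvolve(epochs, reg)
        cta = click_triggered_average(epochs, trains)
        assert np.max(np.abs(resp.amplitude - cta.amplitude)) < 1e-9

    def test_white_noise_regressor_recovers_long_kernel(self):
        # broadband regressor, 500-tap kernel, strong per-sample noise
        rng = np.random.default_rng(3)
        k = make_abr_kernel(FS)[:500]
        n_ep, n = 40, int(60 * FS)
        x = np.abs(rng.standard_normal((n_ep, n)))  # rectified white drive
        reg = Regressor(x, x.copy(), FS, "rectified_speech")
        eeg = np.empty((n_ep, n))
        for e in range(n_ep):
            clean = signal.fftconvolve(x[e], k)[:n]
            noise = rng.standard_normal(n)
            eeg[e] = clean + noise * (10.0 * clean.std() / noise.std())  # -20 dB/sample
        resp = deconvolve(EegEpochs(eeg, FS), reg)
        rec = resp.window_values((0.0, 20.0))
        r = np.corrcoef(rec, k[: rec.size])[0, 1]
        assert r > 0.95

    def test_degenerate_regressor_rejected(self):
        reg = Regressor(np.zeros((1, 1000)), np.zeros((1, 1000)), FS, "rectified_speech")
        with pytest.raises(ValueError):
            deconvolve(EegEpochs(np.zeros((1, 1100)), FS), reg)


class TestScalingCovariance:
    def test_response_scales_with_eeg_and_inversely_with_regressor(self):
        rng = np.random.default_rng(5)
        x = np.abs(rng.standard_normal((2, 5000)))
        reg = Regressor(x, np.abs(rng.standard_normal((2, 5000))), FS, "rectified_speech")
        eeg = rng.standard_normal((2, 5200))
        base = deconvolve(EegEpochs(eeg, FS), reg, lags_ms=(-20.0, 50.0)).amplitude
        scaled_y = deconvolve(EegEpochs(3.0 * eeg, FS), reg, lags_ms=(-20.0, 50.0)).amplitude
        np.testing.assert_allclose(scaled_y, 3.0 * base, rtol=1e-10)
        reg2 = Regressor(2.0 * reg.pos, 2.0 * reg.neg, FS, "rectified_speech")
        scaled_x = deconvolve(EegEpochs(eeg, FS), reg2, lags_ms=(-20.0, 50.0)).amplitude
        np.testing.assert_allclose(scaled_x, base / 2.0, rtol=1e-10)

    def test_noise_floor_shrinks_with_epoch_count(self):
        # regressor-uncorrelated noise: pre-stimulus RMS drops ~ 1/sqrt(epochs)
        rng = np.random.default_rng(6)
        n_ep, n = 16, int(4 * FS)
        x = np.abs(rng.standard_normal((n_ep, n)))
        reg = Regressor(x, x.copy(), FS, "rectified_speech")
        eeg = rng.standard_normal((n_ep, n))
        epochs = EegEpochs(eeg, FS)
        floors = []
        for n_use in (4, 16):
            resp = deconvolve(
                epochs.select(np.arange(n_use)), reg.select(np.arange(n_use))
            )
            floors.append(np.std(resp.window_values((-125.0, -10.0))))
        assert floors[0] / floors[1] == pytest.approx(2.0, rel=0.35)


class TestPostfilter:
    def test_smooth_kernel_barely_affected_by_2khz_lowpass(self):
        t = np.arange(2001) / FS * 1000.0 - 50.0
        smooth = np.exp(-0.5 * (t / 1.0) ** 2)  # ~160 Hz bandwidth
        resp = ResponseWaveform(smooth, FS, 500)
        out = postfilter_response(resp, 2000.0, direction="zerophase")
        change = np.sqrt(np.mean((out.amplitude - smooth) ** 2) / np.mean(smooth**2))
        assert change < 0.01

    def test_20hz_lowpass_erases_wave_v(self):
        k = make_abr_kernel(FS)[:2000]
        resp = ResponseWaveform(k, FS, 0)
        out = postfilter_response(resp, 20.0)
        inside = np.max(np.abs(out.window_values((5.0, 7.0))))
        flank = np.max(np.abs(out.window_values((40.0, 80.0))))
        assert inside < flank  # no resolvable 5-7 ms peak above later slow waves

    def test_none_is_identity(self):
        resp = ResponseWaveform(np.random.default_rng(0).standard_normal(500), FS, 100)
        out = postfilter_response(resp, None)
        assert np.array_equal(out.amplitude, resp.amplitude)

    def test_provenance_records_filter(self):
        resp = ResponseWaveform(np.zeros(100), FS, 10)
        out = postfilter_response(resp, 200.0)
        assert out.provenance["filters"][0]["cutoff_hz"] == 200.0


class TestCombineConditions:
    def test_identical_inputs_unchanged(self):
        a = ResponseWaveform(np.sin(np.arange(100)), FS, 10)
        out = combine_conditions([a, a.replace()])
        np.testing.assert_allclose(out.amplitude, a.amplitude)

    def test_opposite_inputs_cancel(self):
        a = ResponseWaveform(np.sin(np.arange(100)), FS, 10)
        b = a.replace(amplitude=-a.amplitude)
        out = combine_conditions([a, b])
        np.testing.assert_allclose(out.amplitude, 0.0, atol=1e-15)

    def test_mismatched_grids_rejected(self):
        a = ResponseWaveform(np.zeros(100), FS, 10)
        b = ResponseWaveform(np.zeros(101), FS, 10)
        with pytest.raises(ValueError):
            combine_conditions([a, b])


class TestNormalization:
    def _resp(self, amp):
        return ResponseWaveform(amp, FS, 1500)

    def test_identical_responses_give_unit_gain(self):
        rng = np.random.default_rng(0)
        r = self._resp(rng.standard_normal(5001))
        out = compute_gn([r], [r.replace()])
        assert out.g_n == pytest.approx(1.0)

    def test_known_amplitude_ratio_recovered(self):
        rng = np.random.default_rng(1)
        clicks = [self._resp(rng.standard_normal(5001)) for _ in range(3)]
        speech = [c.replace(amplitude=c.amplitude / 28.2) for c in clicks]
        out = compute_gn(clicks, speech)
        assert out.g_n == pytest.approx(28.2, rel=1e-9)

    def test_cohort_ratio_recovered_within_5pct(self):
        rng = np.random.default_rng(2)
        true_ratio = 25.0
        clicks, speech = [], []
        for _ in range(10):
            c = self._resp(rng.standard_normal(5001) * rng.uniform(0.5, 2.0))
            g_i = true_ratio * np.exp(rng.normal(0, 0.03))
            clicks.append(c)
            speech.append(c.replace(amplitude=c.amplitude / g_i))
        out = compute_gn(clicks, speech)
        assert out.g_n == pytest.approx(true_ratio, rel=0.05)

    def test_apply_gn_marks_normalized(self):
        r = self._resp(np.ones(5001))
        out = apply_gn(r, 28.2)
        assert out.normalized
        assert out.amplitude[0] == pytest.approx(28.2)

    def test_zero_speech_sd_rejected(self):
        r = self._resp(np.random.default_rng(0).standard_normal(5001))
        with pytest.raises(ValueError):
            compute_gn([r], [self._resp(np.zeros(5001))])


class TestTraditionalAbr:
    def _periodic_session(self, spike_sweeps=(), n_epochs=2, dur=10.0):
        k = make_abr_kernel(FS)[:190]
        trains = [
            make_click_train(rate=44.1, duration=dur, timing="periodic")
            for _ in range(n_epochs)
        ]
        n = int((dur + 0.1) * FS)
        eeg = np.zeros((n_epochs, n))
        for e, tr in enumerate(trains):
            idx = np.round(tr.click_times * FS).astype(int)
            for j, i in enumerate(idx):
                eeg[e, i : i + k.size] += k[: n - i]
                if (e, j) in spike_sweeps:
                    eeg[e, i + 50] += 200.0
        return EegEpochs(eeg, FS), trains

    def test_window_end_set_by_click_rate(self):
        epochs, trains = self._periodic_session()
        resp = average_abr_traditional(epochs, trains)
        assert resp.provenance["window_ms"][1] == pytest.approx(-3.0 + 1000.0 / 44.1)
        assert resp.lag_range_ms[0] == pytest.approx(-3.0)

    def test_clean_sweeps_average_to_template(self):
        epochs, trains = self._periodic_session()
        resp = average_abr_traditional(epochs, trains)
        assert resp.provenance["n_rejected"] == 0
        # every sweep identical after settling -> average matches a late sweep
        filt = average_abr_traditional(
            epochs.select([0]), [trains[0]]
        )
        np.testing.assert_allclose(resp.amplitude, filt.amplitude, rtol=0.05, atol=1e-4)

    def test_spiked_sweeps_rejected_exactly(self):
        spikes = {(0, 50), (0, 150), (1, 99), (1, 300)}
        epochs, trains = self._periodic_session(spike_sweeps=spikes)
        resp = average_abr_traditional(epochs, trains)
        assert resp.provenance["n_rejected"] == len(spikes)

    def test_all_rejected_is_error(self):
        epochs, trains = self._periodic_session(dur=2.0)
        with pytest.raises(ValueError):
            average_abr_traditional(epochs, trains, reject_pp=1e-12)


class TestCumulativeDeconvolve:
    def test_final_prefix_matches_full_deconvolve(self):
        rng = np.random.default_rng(7)
        x = np.abs(rng.standard_normal((4, 4000)))
        reg = Regressor(x, np.abs(rng.standard_normal((4, 4000))), FS, "rectified_speech")
        epochs = EegEpochs(rng.standard_normal((4, 4100)), FS)
        full = deconvolve(epochs, reg, lags_ms=(-20.0, 40.0))
        cum = cumulative_deconvolve(epochs, reg, lags_ms=(-20.0, 40.0), prefixes=[2, 4])
        np.testing.assert_allclose(cum[-1].amplitude, full.amplitude, rtol=1e-10)
        assert cum[0].provenance["n_epochs"] == 2
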