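"""Preprocessing pipeline: filtering, epoching, rejection, CAR, z-scoring."""

import numpy as np
import pytest

from tcpl.containers import EpochedTrial, RawRecording
from tcpl.preprocessing import (PreprocessConfig, bandpass_filter,
                                common_average_reference, epoch_and_baseline,
                                reject_artifacts, resample_car_zscore,
                                run_pipeline)


def _recording(signal, fs, events=None, sid="s0"):
    ch = [f"ch{i}" for i in range(signal.shape[0])]
    return RawRecording(signal, fs, ch, events or [], sid)


def _fft_amplitude(x, fs, freq):
    n = len(x)
    spec = np.abs(np.fft.rfft(x * np.hanning(n))) / n * 4
    freqs = np.fft.rfftfreq(n, 1 / fs)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestBandpass:
    def test_dc_removed(self):
        rec = _recording(np.full((2, 1024), 5.0), 128.0)
        out = bandpass_filter(rec, (8, 30))
        core = out.signal[:, 128:-128]
        assert np.abs(core).max() < 1e-6 * 5.0

    def test_passband_tone_preserved(self):
        fs, f0 = 128.0, 20.0
        t = np.arange(int(8 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)[None, :]
        out = bandpass_filter(_recording(x, fs), (8, 30))
        mid = slice(int(0.1 * x.shape[1]), int(0.9 * x.shape[1]))
        a_in = _fft_amplitude(x[0, mid], fs, f0)
        a_out = _fft_amplitude(out.signal[0, mid], fs, f0)
        assert abs(a_out / a_in - 1) < 0.05

    def test_stopband_tone_rejected(self):
        fs, f0 = 256.0, 50.0
        t = np.arange(int(8 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)[None, :]
        out = bandpass_filter(_recording(x, fs), (8, 30))
        assert (_fft_amplitude(out.signal[0], fs, f0)
                <= 0.1 * _fft_amplitude(x[0], fs, f0))

    def test_band_above_nyquist_rejected(self):
        rec = _recording(np.zeros((1, 256)), 64.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, (8, 40))

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 512))
        y = rng.normal(size=(2, 512))
        fa = bandpass_filter(_recording(2 * x + 3 * y, 128.0), (8, 30)).signal
        fb = (2 * bandpass_filter(_recording(x, 128.0), (8, 30)).signal
              + 3 * bandpass_filter(_recording(y, 128.0), (8, 30)).signal)
        assert np.allclose(fa, fb, rtol=1e-8, atol=1e-10)


class TestEpoching:
    def test_constant_channels_zero_after_baseline(self):
        sig = np.repeat([[1.0], [-2.0]], 6 * 128, axis=1)
        rec = _recording(sig, 128.0, events=[(128, 0)])
        trials = epoch_and_baseline(rec, PreprocessConfig())
        assert len(trials) == 1
        assert np.all(trials[0].data == 0.0)

    def test_trial_count_and_shape(self):
        fs = 128.0
        rec = _recording(np.zeros((3, int(20 * fs))), fs,
                         events=[(256, 0), (1024, 1), (2000, 2)])
        trials = epoch_and_baseline(rec, PreprocessConfig())
        assert len(trials) == 3
        assert all(t.data.shape == (3, int(4 * fs)) for t in trials)
        assert [t.label for t in trials] == [0, 1, 2]

    def test_step_at_cue_gives_constant_difference(self):
        fs = 128.0
        a, b = 1.5, 4.0
        cue = int(2 * fs)
        sig = np.full((1, int(8 * fs)), a)
        sig[:, cue:] = b
        rec = _recording(sig, fs, events=[(cue, 1)])
        (trial,) = epoch_and_baseline(rec, PreprocessConfig())
        assert np.allclose(trial.data, b - a)

    def test_out_of_range_event_skipped_not_fatal(self):
        fs = 128.0
        rec = _recording(np.zeros((1, int(6 * fs))), fs,
                         events=[(0, 0), (int(1.5 * fs), 1)])
        trials = epoch_and_baseline(rec, PreprocessConfig())
        assert len(trials) == 1 and trials[0].label == 1


class TestArtifactRejection:
    def _trial(self, peak):
        d = np.zeros((2, 64))
        d[0, 10] = peak
        return EpochedTrial(d, 0, "s0", 128.0)

    def test_spike_trial_removed(self):
        trials = [self._trial(10.0)] * 9 + [self._trial(500.0)]
        assert len(reject_artifacts(trials, 100.0)) == 9

    def test_infinite_threshold_is_identity(self):
        trials = [self._trial(10.0), self._trial(500.0)]
        assert reject_artifacts(trials, np.inf) == trials

    def test_median_threshold_keeps_exactly_half(self):
        rng = np.random.default_rng(3)
        peaks = rng.uniform(10, 200, size=20)
        trials = [self._trial(p) for p in peaks]
        thresh = float(np.median(peaks))
        kept = reject_artifacts(trials, thresh)
        expected = sum(1 for p in peaks if p <= thresh)
        assert len(kept) == expected


class TestResampleCarZscore:
    def test_car_zeroes_identical_channels(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=512)
        trials = [EpochedTrial(np.tile(row, (4, 1)), 0, "s0", 128.0)]
        out = resample_car_zscore(trials, PreprocessConfig())
        # all-equal channels vanish under CAR; z-score floor keeps them 0
        assert np.allclose(out[0].data, 0.0)

    def test_car_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 512))
        once = common_average_reference(x)
        assert np.abs(once.mean(axis=0)).max() < 1e-12
        twice = common_average_reference(once)
        assert np.allclose(twice, once, rtol=0, atol=1e-12)

    def test_antisymmetric_channels_unchanged_by_car(self):
        x = np.vstack([np.ones(512), -np.ones(512)])
        assert np.allclose(common_average_reference(x), x)

    def test_pooled_zscore_statistics(self):
        rng = np.random.default_rng(2)
        trials = [EpochedTrial(rng.normal(3.0, 2.0, size=(4, 512)), 0, "s0", 128.0)
                  for _ in range(6)]
        cfg = PreprocessConfig(car=False)
        out = resample_car_zscore(trials, cfg)
        stacked = np.stack([t.data for t in out])
        assert np.abs(stacked.mean(axis=(0, 2))).max() < 1e-6
        assert np.abs(stacked.std(axis=(0, 2)) - 1).max() < 1e-6

    def test_downsampling_to_target_rate(self):
        rng = np.random.default_rng(4)
        trials = [EpochedTrial(rng.normal(size=(2, 2048)), 0, "s0", 512.0)]
        out = resample_car_zscore(trials, PreprocessConfig())
        assert out[0].fs == 128.0
        assert out[0].data.shape == (2, 512)


class TestPipeline:
    def _cued_recording(self, fs=512.0, n_events=6, seed=0, sid="s0"):
        rng = np.random.default_rng(seed)
        n = int(fs * (6 * n_events + 4))
        t = np.arange(n) / fs
        drift = 20 * np.sin(2 * np.pi * 2.0 * t)
        alpha = np.sin(2 * np.pi * 10.0 * t)
        sig = np.vstack([drift + alpha + rng.normal(0, 1, n) for _ in range(4)])
        events = [(int(fs * (2 + 6 * i)), i % 2) for i in range(n_events)]
        return _recording(sig, fs, events=events, sid=sid)

    def test_shapes_and_rate(self):
        trials = run_pipeline(self._cued_recording(), PreprocessConfig())
        assert trials, "pipeline should keep trials on clean input"
        assert all(t.data.shape == (4, 512) and t.fs == 128.0 for t in trials)
        assert all(np.isfinite(t.data).all() for t in trials)

    def test_out_of_band_drift_removed(self):
        rec = self._cued_recording()
        trials = run_pipeline(rec, PreprocessConfig())
        x = trials[0].data[0]
        freqs = np.fft.rfftfreq(len(x), 1 / 128.0)
        spec = np.abs(np.fft.rfft(x))
        drift_power = spec[(freqs > 1) & (freqs < 4)].mean()
        alpha_power = spec[(freqs > 9) & (freqs < 11)].mean()
        assert alpha_power > 10 * drift_power

    def test_empty_events_yield_empty_output(self):
        rec = _recording(np.zeros((2, 5120)), 512.0, events=[])
        assert run_pipeline(rec, PreprocessConfig()) == []

    def test_determinism(self):
        rec = self._cued_recording()
        a = run_pipeline(rec, PreprocessConfig())
        b = run_pipeline(rec, PreprocessConfig())
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))

    def test_bad_channel_list_removed(self):
        rec = self._cued_recording()
        cfg = PreprocessConfig(bad_channels=("ch0", "ch3"))
        trials = run_pipeline(rec, cfg)
        assert trials[0].data.shape[0] == 2


def test_config_invariants():
    with pytest.raises(ValueError):
        PreprocessConfig(band=(30, 8))
    with pytest.raises(ValueError):
        PreprocessConfig(band=(8, 70))  # >= Nyquist of 128 Hz target
    with pytest.raises(ValueError):
        PreprocessConfig(epoch_s=0)
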