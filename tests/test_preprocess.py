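"""Preprocessing: resampling, wavelet denoising, segmentation, scaling."""

import numpy as np
import pytest
from scipy.signal import periodogram

from anobeat.containers import BEAT_LEN, ECGRecord, PRE_R
from anobeat.preprocess import (
    SegmentLog,
    denoise,
    normalize_beat,
    normalize_matrix,
    preprocess_record,
    resample_record,
    segment_beats,
)
from anobeat.synthetic import SimConfig, beat_template, make_record


class TestResample:
    def test_560_to_360_length(self):
        rec = make_record(10, SimConfig(fs=560, heart_rate_bpm=60, seed=1))
        n_in = rec.samples.size
        out = resample_record(rec, 360)
        assert out.fs == 360
        assert out.samples.size == round(n_in * 360 / 560)

    def test_identity_when_rates_match(self):
        rec = make_record(3, SimConfig(seed=1))
        out = resample_record(rec, rec.fs)
        np.testing.assert_allclose(out.samples, rec.samples)
        np.testing.assert_array_equal(out.r_peaks, rec.r_peaks)

    def test_sine_matches_analytic_values(self):
        """A pure 5 Hz tone resampled 560 -> 360 Hz equals the closed-form
        sine on the new grid (away from filter edge effects)."""
        fs_in, fs_out, f0 = 560.0, 360.0, 5.0
        t_in = np.arange(5600) / fs_in
        rec = ECGRecord(np.sin(2 * np.pi * f0 * t_in), fs_in)
        out = resample_record(rec, fs_out)
        t_out = np.arange(out.samples.size) / fs_out
        expected = np.sin(2 * np.pi * f0 * t_out)
        interior = slice(50, -50)
        assert np.max(np.abs(out.samples[interior] - expected[interior])) < 1e-3

    def test_peaks_resnap_to_local_maximum(self):
        rec = make_record(8, SimConfig(fs=560, heart_rate_bpm=60,
                                       noise_sd=0.0, baseline_amp=0.0,
                                       seed=2))
        out = resample_record(rec, 360)
        for p in out.r_peaks:
            lo, hi = max(p - 3, 0), min(p + 4, out.samples.size)
            assert np.abs(out.samples[p]) == np.max(np.abs(out.samples[lo:hi]))

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            resample_record(ECGRecord(np.empty(0), 360.0), 360)


class TestDenoise:
    def test_zero_signal_stays_zero(self):
        rec = ECGRecord(np.zeros(4096), 360.0)
        out = denoise(rec)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_baseline_wander_removed(self):
        """Power below 0.5 Hz drops by >= 90% after denoising."""
        cfg = SimConfig(noise_sd=0.0, baseline_amp=0.2, baseline_freq=0.3,
                        seed=3)
        rec = make_record(20, cfg)

        def low_power(x):
            f, p = periodogram(x, fs=rec.fs)
            return p[f < 0.5].sum()

        out = denoise(rec)
        assert low_power(out.samples) < 0.1 * low_power(rec.samples)

    def test_white_noise_reduced(self):
        cfg_clean = SimConfig(noise_sd=0.0, baseline_amp=0.0,
                              amplitude_jitter=0.0, width_jitter=0.0, seed=4,
                              class_mix={"N": 1.0, "A": 0, "L": 0, "R": 0,
                                         "V": 0})
        clean = make_record(20, cfg_clean)
        rng = np.random.default_rng(0)
        noisy = ECGRecord(clean.samples + 0.05 * rng.standard_normal(
            clean.samples.size), clean.fs, clean.r_peaks, clean.beat_labels)
        out = denoise(noisy)
        rmse_before = np.sqrt(np.mean((noisy.samples - clean.samples) ** 2))
        rmse_after = np.sqrt(np.mean((out.samples - clean.samples) ** 2))
        assert rmse_after < rmse_before

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            denoise(ECGRecord(np.ones(4), 360.0))


class TestSegment:
    def test_window_is_250_samples_around_r(self):
        samples = np.arange(1000, dtype=float)
        rec = ECGRecord(samples, 360.0, [500], ["N"])
        m = segment_beats(rec)
        assert m.beats.shape == (1, BEAT_LEN)
        np.testing.assert_array_equal(m.beats[0], samples[400:650])

    def test_boundary_peaks_skipped_and_logged(self):
        rec = ECGRecord(np.zeros(600), 360.0, [50, 300, 550], list("NNN"))
        log = SegmentLog()
        m = segment_beats(rec, log=log)
        assert m.n_beats == 1  # only the middle peak has full context
        assert log.kept == 1 and log.skipped == 2
        assert log.total == 3

    def test_no_valid_peaks_warns_not_raises(self, caplog):
        rec = ECGRecord(np.zeros(120), 360.0, [10], ["N"])
        m = segment_beats(rec)
        assert m.n_beats == 0

    def test_labels_carried_over(self):
        rec = ECGRecord(np.zeros(2000), 360.0, [400, 800, 1200],
                        list("NVL"))
        m = segment_beats(rec)
        np.testing.assert_array_equal(m.labels, ["N", "V", "L"])


class TestNormalize:
    def test_closed_form(self):
        beat = np.linspace(0, 4, BEAT_LEN)
        out = normalize_beat(beat)
        np.testing.assert_allclose(out, np.linspace(-1, 1, BEAT_LEN))

    def test_degenerate_beat_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_beat(np.full(BEAT_LEN, 3.7)),
                                      np.zeros(BEAT_LEN))

    def test_range_endpoints(self, rng):
        beat = rng.standard_normal(BEAT_LEN)
        out = normalize_beat(beat)
        assert out.min() == -1.0
        assert out.max() == 1.0

    def test_idempotence(self, rng):
        beat = rng.standard_normal(BEAT_LEN)
        once = normalize_beat(beat)
        np.testing.assert_allclose(normalize_beat(once), once, atol=1e-12)

    def test_non_finite_rejected(self):
        beat = np.zeros(BEAT_LEN)
        beat[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            normalize_beat(beat)


class TestPipeline:
    def test_composition_recovers_templates(self):
        """resample -> denoise -> segment -> normalize on a noiseless
        560 Hz record yields beats correlating > 0.95 with the placed
        template."""
        cfg = SimConfig(fs=560, heart_rate_bpm=60, noise_sd=0.0,
                        baseline_amp=0.1, amplitude_jitter=0.0,
                        width_jitter=0.0, seed=6,
                        class_mix={"N": 1.0, "A": 0, "L": 0, "R": 0, "V": 0})
        rec = make_record(12, cfg)
        log = SegmentLog()
        m = preprocess_record(rec, target_fs=360, log=log)
        assert log.kept + log.skipped == rec.r_peaks.size
        assert m.n_beats >= 10
        t = (np.arange(BEAT_LEN) - PRE_R) / 360.0
        template = beat_template("N").evaluate(t)
        for beat in m.beats:
            corr = np.corrcoef(beat, template)[0, 1]
            assert corr > 0.95

    def test_rows_normalized(self):
        rec = make_record(6, SimConfig(seed=8))
        m = preprocess_record(rec)
        for row in m.beats:
            assert np.isclose(row.min(), -1) and np.isclose(row.max(), 1)
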