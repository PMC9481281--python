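"""Synthetic ECG generator: morphology, determinism, record structure."""

import numpy as np
import pytest

from anobeat.containers import ABNORMAL_CLASSES, BEAT_LEN, PRE_R
from anobeat.synthetic import SimConfig, beat_template, make_beat, make_dataset, make_record


def qrs_width(beat: np.ndarray, frac: float = 0.2) -> int:
    """Contiguous run of samples around the R anchor above frac * R height."""
    thr = frac * beat[PRE_R]
    left = PRE_R
    while left > 0 and beat[left - 1] > thr:
        left -= 1
    right = PRE_R
    while right < beat.size - 1 and beat[right + 1] > thr:
        right += 1
    return right - left + 1


class TestMakeBeat:
    @pytest.mark.parametrize("label", ["N", "A", "L", "R", "V"])
    def test_beat_shape_and_r_anchor(self, label):
        beat = make_beat(label, SimConfig(seed=1))
        assert beat.shape == (BEAT_LEN,)
        assert np.argmax(np.abs(beat)) == PRE_R

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown beat class"):
            make_beat("X", SimConfig(seed=1))

    def test_seed_determinism(self):
        cfg = SimConfig(seed=7)
        np.testing.assert_array_equal(make_beat("N", cfg), make_beat("N", cfg))

    def test_ventricular_qrs_wider_than_normal(self):
        cfg = SimConfig(seed=1, noise_sd=0.0)
        assert qrs_width(make_beat("V", cfg)) > qrs_width(make_beat("N", cfg))

    def test_ventricular_has_no_p_wave(self, clean_config):
        n = make_beat("N", clean_config)
        v = make_beat("V", clean_config)
        # P-wave window well before the QRS
        p_win = slice(30, 55)
        assert np.max(np.abs(v[p_win])) < 0.3 * np.max(np.abs(n[p_win]))

    def test_atrial_p_wave_advanced_and_smaller(self, clean_config):
        n = make_beat("N", clean_config)
        a = make_beat("A", clean_config)
        p_region = slice(0, 80)
        assert np.argmax(a[p_region]) < np.argmax(n[p_region])
        assert np.max(a[p_region]) < 0.75 * np.max(n[p_region])


class TestTemplates:
    @pytest.mark.parametrize("label", ["N", "A", "L", "R", "V"])
    def test_r_component_dominates(self, label):
        tpl = beat_template(label)
        amps = [abs(a) for a, _, _ in tpl.wave_params]
        centers = [c for _, c, _ in tpl.wave_params]
        assert amps[int(np.argmin(np.abs(centers)))] == max(amps)
        assert all(w > 0 for _, _, w in tpl.wave_params)

    def test_class_separability(self):
        """V beats sit farther from the N centroid than N beats from
        each other (signal-level separability on 50 noiseless beats)."""
        cfg = SimConfig(seed=3, noise_sd=0.0)
        rng_seeds = range(50)
        n_beats = np.array([make_beat("N", SimConfig(seed=s, noise_sd=0.0))
                            for s in rng_seeds])
        v_beats = np.array([make_beat("V", SimConfig(seed=s, noise_sd=0.0))
                            for s in rng_seeds])
        within = np.mean([np.linalg.norm(b - n_beats.mean(0)) for b in n_beats])
        across = np.mean([np.linalg.norm(b - n_beats.mean(0)) for b in v_beats])
        assert across > within


class TestMakeRecord:
    def test_regular_rhythm_spacing(self):
        cfg = SimConfig(fs=360, heart_rate_bpm=60, noise_sd=0.0,
                        baseline_amp=0.0, seed=2)
        rec = make_record(10, cfg)
        assert rec.r_peaks.size == 10
        np.testing.assert_array_equal(np.diff(rec.r_peaks), 360)
        assert rec.beat_labels.size == 10

    def test_high_rate_record(self):
        rec = make_record(5, SimConfig(fs=560, seed=2))
        assert rec.fs == 560
        assert rec.r_peaks.size == 5

    def test_seed_determinism(self):
        cfg = SimConfig(seed=9)
        a, b = make_record(6, cfg), make_record(6, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.r_peaks, b.r_peaks)
        np.testing.assert_array_equal(a.beat_labels, b.beat_labels)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_record(0, SimConfig(seed=1))
        with pytest.raises(ValueError):
            SimConfig(heart_rate_bpm=0)

    def test_record_window_recovers_placed_beat(self, clean_config):
        """Extracting [r-100, r+150) of a noiseless record reproduces the
        beat-template waveform."""
        cfg = SimConfig(fs=360, heart_rate_bpm=60, noise_sd=0.0,
                        baseline_amp=0.0, amplitude_jitter=0.0,
                        width_jitter=0.0, seed=4,
                        class_mix={"N": 1.0, "A": 0, "L": 0, "R": 0, "V": 0})
        rec = make_record(4, cfg)
        tpl = beat_template("N")
        t = (np.arange(BEAT_LEN) - PRE_R) / 360.0
        expected = tpl.evaluate(t)
        for r in rec.r_peaks:
            window = rec.samples[r - PRE_R : r + 150]
            assert np.max(np.abs(window - expected)) < 1e-6


class TestMakeDataset:
    def test_one_class_training_split(self):
        train, test = make_dataset(100, 50, 50, SimConfig(seed=3))
        assert train.beats.shape == (100, BEAT_LEN)
        assert set(train.labels) == {"N"}
        assert test.n_beats == 100
        assert np.sum(test.labels == "N") == 50
        assert set(test.labels[test.labels != "N"]) <= set(ABNORMAL_CLASSES)

    def test_abnormal_mix_frequency(self):
        """With a uniform abnormal mix, all four classes appear across
        repeated draws."""
        mix = {"N": 0.0, "A": 0.25, "L": 0.25, "R": 0.25, "V": 0.25}
        seen = set()
        for seed in range(12):
            _, test = make_dataset(0, 0, 4, SimConfig(seed=seed, class_mix=mix))
            seen |= set(test.labels)
        assert seen == set(ABNORMAL_CLASSES)

    def test_all_normal_mix_rejected_for_abnormal_request(self):
        mix = {"N": 1.0, "A": 0.0, "L": 0.0, "R": 0.0, "V": 0.0}
        with pytest.raises(ValueError, match="all-normal"):
            make_dataset(0, 0, 4, SimConfig(seed=3, class_mix=mix))

    def test_determinism(self):
        cfg = SimConfig(seed=12)
        t1, s1 = make_dataset(20, 5, 5, cfg)
        t2, s2 = make_dataset(20, 5, 5, cfg)
        np.testing.assert_array_equal(t1.beats, t2.beats)
        np.testing.assert_array_equal(s1.beats, s2.beats)
        np.testing.assert_array_equal(s1.labels, s2.labels)


def test_class_mix_must_sum_to_one():
    with pytest.raises(ValueError, match="sum to 1"):
        SimConfig(class_mix={"N": 0.5, "V": 0.4})
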