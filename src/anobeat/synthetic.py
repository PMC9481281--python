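"""Synthetic single-lead ECG generator.

Beats are modelled as sums of Gaussian bumps for the P, Q, R, S and T waves
on a 250-sample grid at 360 Hz, with the R peak anchored at sample 100.
Abnormal classes are deliberate caricatures of their clinical morphology,
good enough to be separable from normal sinus beats but not clinically
validated:

``N``
    normal sinus beat, P-R interval ~0.16 s, QRS ~0.08 s.
``V``
    ventricular premature beat: no P wave, QRS roughly twice as wide,
    discordant (inverted) T wave.
``L``
    left bundle branch block: broad QRS with a notched, two-lobed R wave.
``R``
    right bundle branch block: deep S followed by a secondary R' deflection.
``A``
    atrial premature beat: P wave advanced by 40 ms with half amplitude.

Full records place beats at a configurable heart rate and add white noise
plus a single-tone sinusoidal baseline wander.  One integer seed drives all
randomness through a single :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (
    ABNORMAL_CLASSES,
    BEAT_CLASSES,
    BEAT_FS,
    BEAT_LEN,
    POST_R,
    PRE_R,
    BeatMatrix,
    ECGRecord,
)

__all__ = [
    "BeatTemplate",
    "SimConfig",
    "beat_template",
    "make_beat",
    "make_record",
    "make_dataset",
]


@dataclass(frozen=True)
class BeatTemplate:
    """Gaussian-mixture description of one beat class.

    ``wave_params`` is a list of ``(amplitude, center, width)`` tuples with
    centers in seconds relative to the R peak and widths as Gaussian sigmas
    in seconds.  The R component sits at center 0 and has the largest
    absolute amplitude.
    """

    class_label: str
    wave_params: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if self.class_label not in BEAT_CLASSES:
            raise ValueError(f"unknown beat class {self.class_label!r}")
        amps = [abs(a) for a, _, _ in self.wave_params]
        centers = [c for _, c, _ in self.wave_params]
        r_idx = int(np.argmin(np.abs(centers)))
        if abs(centers[r_idx]) > 1e-12:
            raise ValueError("template must contain an R component at center 0")
        if amps[r_idx] < max(amps):
            raise ValueError("R component must have the largest |amplitude|")
        if any(w <= 0 for _, _, w in self.wave_params):
            raise ValueError("wave widths must be positive")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Continuous-time waveform at times ``t`` (s, R peak at 0)."""
        out = np.zeros_like(t, dtype=np.float64)
        for amp, center, width in self.wave_params:
            out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        return out


# (amplitude a.u., center s, sigma s) per wave; R always at center 0.
_TEMPLATES: dict[str, tuple[tuple[float, float, float], ...]] = {
    # P, Q, R, S, T
    "N": (
        (0.15, -0.16, 0.025),
        (-0.12, -0.035, 0.010),
        (1.00, 0.0, 0.018),
        (-0.25, 0.035, 0.012),
        (0.35, 0.25, 0.060),
    ),
    # no P, double-width QRS, inverted T
    "V": (
        (-0.14, -0.060, 0.018),
        (1.00, 0.0, 0.036),
        (-0.40, 0.065, 0.026),
        (-0.40, 0.28, 0.070),
    ),
    # notched broad QRS: second R lobe merged into the main one
    "L": (
        (0.10, -0.16, 0.025),
        (1.00, 0.0, 0.028),
        (0.65, 0.045, 0.028),
        (-0.20, 0.10, 0.015),
        (0.25, 0.28, 0.060),
    ),
    # deep S then secondary R' deflection
    "R": (
        (0.15, -0.16, 0.025),
        (-0.10, -0.035, 0.010),
        (1.00, 0.0, 0.018),
        (-0.50, 0.040, 0.015),
        (0.50, 0.075, 0.020),
        (0.25, 0.26, 0.055),
    ),
    # P advanced by 40 ms with halved amplitude
    "A": (
        (0.075, -0.20, 0.022),
        (-0.12, -0.035, 0.010),
        (1.00, 0.0, 0.018),
        (-0.25, 0.035, 0.012),
        (0.35, 0.25, 0.060),
    ),
}


def beat_template(class_label: str) -> BeatTemplate:
    """Return the canonical :class:`BeatTemplate` for a beat class."""
    if class_label not in _TEMPLATES:
        raise ValueError(
            f"unknown beat class {class_label!r}; expected one of {BEAT_CLASSES}"
        )
    return BeatTemplate(class_label, _TEMPLATES[class_label])


_DEFAULT_MIX = {"N": 0.8, "A": 0.05, "L": 0.05, "R": 0.05, "V": 0.05}


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; ``seed`` fully determines every output."""

    fs: float = BEAT_FS
    heart_rate_bpm: float = 70.0
    noise_sd: float = 0.03
    baseline_amp: float = 0.1
    baseline_freq: float = 0.3
    amplitude_jitter: float = 0.05  # per-wave multiplicative sd
    width_jitter: float = 0.03
    seed: int = 0
    class_mix: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        unknown = set(self.class_mix) - set(BEAT_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes in class_mix: {sorted(unknown)}")
        total = sum(self.class_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"class_mix proportions must sum to 1, got {total}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _jittered_template(template: BeatTemplate, config: SimConfig,
                       rng: np.random.Generator) -> BeatTemplate:
    """Perturb wave amplitudes/widths to emulate beat-to-beat variability."""
    waves = []
    for amp, center, width in template.wave_params:
        a = amp * (1.0 + config.amplitude_jitter * rng.standard_normal())
        w = width * max(1.0 + config.width_jitter * rng.standard_normal(), 0.5)
        waves.append((a, center, w))
    # R stays dominant: jitter is small, but guard against the rare draw
    amps = [abs(a) for a, _, _ in waves]
    r_idx = int(np.argmin([abs(c) for _, c, _ in waves]))
    if amps[r_idx] < max(amps):
        waves[r_idx] = (np.sign(waves[r_idx][0]) * (max(amps) + 1e-3),
                        0.0, waves[r_idx][2])
    return replace(template, wave_params=tuple(waves))


def _beat_from_rng(class_label: str, config: SimConfig,
                   rng: np.random.Generator) -> np.ndarray:
    template = _jittered_template(beat_template(class_label), config, rng)
    t = (np.arange(BEAT_LEN) - PRE_R) / BEAT_FS
    beat = template.evaluate(t)
    if config.noise_sd > 0:
        beat = beat + config.noise_sd * rng.standard_normal(BEAT_LEN)
    # re-anchor: the R sample must dominate the QRS window even under noise
    qrs = slice(PRE_R - 10, PRE_R + 11)
    shift = int(np.argmax(np.abs(beat[qrs]))) - 10
    if shift:
        beat = np.roll(beat, -shift)
    return beat


def make_beat(class_label: str, config: SimConfig | None = None) -> np.ndarray:
    """Generate one 250-sample beat of ``class_label`` at 360 Hz.

    The R peak falls at index 100.  Deterministic in ``config.seed``.
    """
    config = config or SimConfig()
    return _beat_from_rng(class_label, config, config.rng())


def make_record(n_beats: int, config: SimConfig | None = None) -> ECGRecord:
    """Generate an annotated record of ``n_beats`` heartbeats.

    Beats are placed at the configured heart rate; classes are drawn from
    ``class_mix``.  White Gaussian noise (sd ``noise_sd``) and a sinusoidal
    baseline ``baseline_amp * sin(2*pi*baseline_freq*t)`` are added.
    """
    config = config or SimConfig()
    if n_beats < 1:
        raise ValueError("n_beats must be at least 1")
    rng = config.rng()
    fs = config.fs
    rr = 60.0 / config.heart_rate_bpm
    offset = 0.5  # leave room for the pre-R window of the first beat
    peak_times = offset + rr * np.arange(n_beats)
    duration = peak_times[-1] + 0.6
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    labels = rng.choice(classes, size=n_beats, p=probs)

    signal = np.zeros(n)
    for peak_t, label in zip(peak_times, labels):
        template = _jittered_template(beat_template(label), config, rng)
        lo = max(int((peak_t - 0.45) * fs), 0)
        hi = min(int((peak_t + 0.55) * fs), n)
        signal[lo:hi] += template.evaluate(t[lo:hi] - peak_t)
    if config.baseline_amp:
        signal += config.baseline_amp * np.sin(
            2 * np.pi * config.baseline_freq * t
        )
    if config.noise_sd > 0:
        signal += config.noise_sd * rng.standard_normal(n)

    r_peaks = np.round(peak_times * fs).astype(np.int64)
    return ECGRecord(signal, fs, r_peaks, labels)


def make_dataset(
    n_train_normal: int,
    n_test_normal: int,
    n_test_abnormal: int,
    config: SimConfig | None = None,
) -> tuple[BeatMatrix, BeatMatrix]:
    """Generate the one-class train/test split of pre-segmented beats.

    The training matrix holds only normal (``N``) beats.  Test abnormal
    classes are drawn from ``class_mix`` restricted to {A, L, R, V}.
    Beats are raw simulator output; normalize before network training.
    """
    config = config or SimConfig()
    if min(n_train_normal, n_test_normal, n_test_abnormal) < 0:
        raise ValueError("counts must be nonnegative")
    rng = config.rng()

    abn = np.array([config.class_mix.get(c, 0.0) for c in ABNORMAL_CLASSES])
    if n_test_abnormal > 0:
        if abn.sum() <= 0:
            raise ValueError(
                "cannot draw abnormal test beats from an all-normal class_mix"
            )
        abn = abn / abn.sum()

    def _block(labels: np.ndarray, tag: str) -> BeatMatrix:
        beats = np.empty((labels.size, BEAT_LEN))
        for i, lab in enumerate(labels):
            beats[i] = _beat_from_rng(lab, config, rng)
        ids = np.array([f"sim/{tag}/{i}" for i in range(labels.size)], dtype=object)
        return BeatMatrix(beats, labels, ids)

    train = _block(np.full(n_train_normal, "N"), "train")
    test_n = _block(np.full(n_test_normal, "N"), "test-n")
    test_a = _block(
        rng.choice(list(ABNORMAL_CLASSES), size=n_test_abnormal, p=abn)
        if n_test_abnormal
        else np.empty(0, dtype="U1"),
        "test-a",
    )
    return train, BeatMatrix.concat([test_n, test_a])
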