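"""Shared data containers: annotated ECG records and beat matrices.

A beat is always a vector of ``BEAT_LEN`` = 250 samples taken at 360 Hz,
anchored 100 samples before and 150 samples after the R peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BEAT_LEN = 250
PRE_R = 100
POST_R = 150
BEAT_FS = 360.0

#: MIT-BIH style single-character beat classes handled by the pipeline.
BEAT_CLASSES = ("N", "A", "L", "R", "V")
ABNORMAL_CLASSES = ("A", "L", "R", "V")


@dataclass
class ECGRecord:
    """A single-lead ECG trace with R-peak annotations.

    Attributes
    ----------
    samples : ndarray, shape (n,)
        Signal amplitude in arbitrary (mV-scale) units.
    fs : float
        Sampling rate in Hz.
    r_peaks : ndarray of int
        Strictly increasing sample indices of annotated R peaks.
    beat_labels : ndarray of str
        One beat class per R peak (see :data:`BEAT_CLASSES`).
    """

    samples: np.ndarray
    fs: float
    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    beat_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype="U1"))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        self.beat_labels = np.asarray(self.beat_labels, dtype="U1")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if self.r_peaks.size:
            if np.any(np.diff(self.r_peaks) <= 0):
                raise ValueError("r_peaks must be strictly increasing")
            if self.r_peaks[0] < 0 or self.r_peaks[-1] >= self.samples.size:
                raise ValueError("r_peaks must lie within the record")
        if self.r_peaks.size != self.beat_labels.size:
            raise ValueError(
                f"{self.r_peaks.size} r_peaks but {self.beat_labels.size} labels"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class BeatMatrix:
    """A stack of fixed-length heartbeats with class labels.

    ``beats`` has one 250-sample beat per row; ``labels`` carries the beat
    class and ``source_ids`` an optional provenance string per row.
    """

    beats: np.ndarray
    labels: np.ndarray
    source_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=np.float64)
        if self.beats.ndim == 1:
            self.beats = self.beats.reshape(0, BEAT_LEN) if self.beats.size == 0 else self.beats.reshape(1, -1)
        if self.beats.shape[0] and self.beats.shape[1] != BEAT_LEN:
            raise ValueError(
                f"beats must have {BEAT_LEN} samples per row, got {self.beats.shape[1]}"
            )
        self.labels = np.asarray(self.labels, dtype="U1")
        if self.labels.size != self.beats.shape[0]:
            raise ValueError("one label per beat row is required")
        if self.source_ids is not None:
            self.source_ids = np.asarray(self.source_ids, dtype=object)
            if self.source_ids.size != self.beats.shape[0]:
                raise ValueError("one source_id per beat row is required")

    @property
    def n_beats(self) -> int:
        return self.beats.shape[0]

    def __len__(self) -> int:
        return self.n_beats

    def subset(self, mask: np.ndarray) -> "BeatMatrix":
        src = None if self.source_ids is None else self.source_ids[mask]
        return BeatMatrix(self.beats[mask], self.labels[mask], src)

    @staticmethod
    def empty() -> "BeatMatrix":
        return BeatMatrix(np.empty((0, BEAT_LEN)), np.empty(0, dtype="U1"))

    @staticmethod
    def concat(parts: list["BeatMatrix"]) -> "BeatMatrix":
        parts = [p for p in parts if p.n_beats]
        if not parts:
            return BeatMatrix.empty()
        src = None
        if all(p.source_ids is not None for p in parts):
            src = np.concatenate([p.source_ids for p in parts])
        return BeatMatrix(
            np.vstack([p.beats for p in parts]),
            np.concatenate([p.labels for p in parts]),
            src,
        )
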