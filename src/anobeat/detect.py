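"""Outlier scoring and thresholding.

Each beat gets a reconstruction score ``R(x)`` (autoencoder MSE), a
discrimination score ``D(x)`` (probability of being real) and the combined
anomaly score ``a(x) = (1 - lambda) * R(x) + lambda / D(x)``.  The default
``lambda = 0`` uses reconstruction error alone.  The decision threshold is
one standard deviation above the mean anomaly score of the (normal-only)
training set, and beats scoring strictly above it are called abnormal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BeatMatrix
from .model import AAE

__all__ = [
    "ScoreSet",
    "D_EPS",
    "r_score",
    "anomaly_score",
    "score_beats",
    "fit_threshold",
    "classify",
]

D_EPS = 1e-7


@dataclass
class ScoreSet:
    """Per-beat scores plus the fitted decision threshold."""

    r_scores: np.ndarray
    d_scores: np.ndarray
    a_scores: np.ndarray
    lam: float
    threshold: float | None = None

    def __len__(self) -> int:
        return self.a_scores.size


def _require_trained(model: AAE) -> None:
    if not getattr(model, "is_trained", False):
        raise ValueError(
            "model has not been trained; fit it (or load trained parameters) "
            "before scoring"
        )


def r_score(beat: np.ndarray, model: AAE) -> float:
    """Reconstruction error of one beat under the trained autoencoder."""
    _require_trained(model)
    beat = np.asarray(beat, dtype=np.float64)
    return float(np.mean((beat.ravel() - np.asarray(
        model.reconstruct(beat)).ravel()) ** 2))


def anomaly_score(r: np.ndarray | float, d: np.ndarray | float,
                  lam: float = 0.0) -> np.ndarray | float:
    """Combined anomaly score ``(1 - lam) * r + lam / max(d, eps)``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    r = np.asarray(r, dtype=np.float64)
    d = np.maximum(np.asarray(d, dtype=np.float64), D_EPS)
    out = (1.0 - lam) * r + lam / d
    return float(out) if out.ndim == 0 else out


def score_beats(model: AAE, beats: BeatMatrix | np.ndarray,
                lam: float = 0.0, batch_size: int = 256) -> ScoreSet:
    """Score every beat; inference mode (dropout disabled), deterministic."""
    _require_trained(model)
    x = beats.beats if isinstance(beats, BeatMatrix) else np.asarray(beats)
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        x = x[None]
    r = np.empty(x.shape[0])
    d = np.empty(x.shape[0])
    for lo in range(0, x.shape[0], batch_size):
        xb = x[lo : lo + batch_size, :, None].astype(model.dtype)
        rec = model.decoder.forward(model.encoder.forward(xb))
        diff = xb.astype(np.float64) - rec.astype(np.float64)
        r[lo : lo + xb.shape[0]] = np.mean(diff**2, axis=(1, 2))
        d[lo : lo + xb.shape[0]] = model.discriminator.forward(xb)[:, 0]
    return ScoreSet(r, d, np.asarray(anomaly_score(r, d, lam)), lam)


def fit_threshold(training_scores: np.ndarray | list[float]) -> float:
    """One standard deviation (n-1 denominator) above the mean score."""
    scores = np.asarray(training_scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need at least 2 training scores to fit a threshold")
    return float(scores.mean() + scores.std(ddof=1))


def classify(scores: np.ndarray | ScoreSet,
             threshold: float | None = None) -> np.ndarray:
    """Label each beat ``abnormal`` iff its anomaly score exceeds T.

    The comparison is strict: a score exactly at the threshold is normal.
    """
    if isinstance(scores, ScoreSet):
        if threshold is None:
            threshold = scores.threshold
        scores = scores.a_scores
    if threshold is None:
        raise ValueError("no threshold: fit one on training scores first")
    scores = np.asarray(scores, dtype=np.float64)
    return np.where(scores > threshold, "abnormal", "normal")
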