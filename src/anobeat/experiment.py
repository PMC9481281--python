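"""End-to-end one-class experiment: simulate -> preprocess -> train ->
threshold -> score -> evaluate.

`run_experiment` reproduces the study protocol at configurable scale:
train the adversarial autoencoder on normal beats only, fit the decision
threshold at mean + 1 SD of the training anomaly scores, then score a
mixed normal/abnormal test set and report ACC/Pre/Rec/F1/AUC with
abnormal as the positive class.  All artifacts (resolved configuration,
loss history, scores, report) are written as plain text next to the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import detect, training
from .evaluate import (
    EvalReport,
    binarize_labels,
    confusion,
    metrics,
    evaluate as evaluate_all,
)
from .containers import BeatMatrix
from .model import AAE, ModelSpec, save_params
from .preprocess import normalize_matrix
from .synthetic import SimConfig, make_dataset
from .training import TrainConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ExperimentResult", "run_experiment"]


@dataclass
class RunConfig:
    """Flat, serializable description of one experiment run."""

    # data
    n_train_normal: int = 2000
    n_test_normal: int = 500
    n_test_abnormal: int = 500
    noise_sd: float = 0.03
    amplitude_jitter: float = 0.05
    width_jitter: float = 0.03
    # model
    latent_dim: int = 8
    kernel_size: int = 9
    dropout_rate: float = 0.05
    # training
    epochs: int = 100
    batch_size: int = 64
    lr_ae: float = 1e-3
    lr_d: float = 2e-4
    gamma: float = 0.05
    patience: int = 10
    # detection
    lam: float = 0.0
    # plumbing
    seed: int = 0
    outdir: str | None = None
    save_model: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(noise_sd=self.noise_sd,
                         amplitude_jitter=self.amplitude_jitter,
                         width_jitter=self.width_jitter, seed=self.seed)

    def model_spec(self) -> ModelSpec:
        return ModelSpec(latent_dim=self.latent_dim,
                         kernel_size=self.kernel_size,
                         dropout_rate=self.dropout_rate)

    def train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                           lr_ae=self.lr_ae, lr_d=self.lr_d,
                           gamma=self.gamma, patience=self.patience,
                           seed=self.seed)


@dataclass
class ExperimentResult:
    report: EvalReport
    threshold: float
    train_scores: detect.ScoreSet
    test_scores: detect.ScoreSet
    history: training.TrainHistory
    model: AAE
    test_labels: np.ndarray = field(default_factory=lambda: np.empty(0))


def _stage(name: str):
    logger.info("stage: %s", name)
    return name


def run_experiment(
    config: RunConfig,
    train_matrix: BeatMatrix | None = None,
    test_matrix: BeatMatrix | None = None,
) -> ExperimentResult:
    """Run the full pipeline; pass matrices to skip simulation.

    Raises ``RuntimeError`` naming the failed stage on any error.
    """
    stage = "setup"
    try:
        if train_matrix is None or test_matrix is None:
            stage = _stage("simulate")
            train_matrix, test_matrix = make_dataset(
                config.n_train_normal, config.n_test_normal,
                config.n_test_abnormal, config.sim_config())

        stage = _stage("normalize")
        train_n = normalize_matrix(train_matrix)
        test_n = normalize_matrix(test_matrix)

        stage = _stage("train")
        model, history = training.train(train_n, config.model_spec(),
                                        config.train_config())

        stage = _stage("threshold")
        train_scores = detect.score_beats(model, train_n, lam=config.lam)
        threshold = detect.fit_threshold(train_scores.a_scores)
        train_scores.threshold = threshold

        stage = _stage("score")
        test_scores = detect.score_beats(model, test_n, lam=config.lam)
        test_scores.threshold = threshold
        pred = detect.classify(test_scores)

        stage = _stage("evaluate")
        truth = binarize_labels(test_n.labels)
        try:
            report = evaluate_all(truth, pred, test_scores.a_scores)
        except ValueError as exc:
            # single-class test sets still get counts and accuracy
            logger.warning("AUC unavailable: %s", exc)
            counts = confusion(truth, pred)
            acc, pre, rec, f1 = metrics(counts)
            report = EvalReport(counts, acc, pre, rec, f1, None)

        result = ExperimentResult(report, threshold, train_scores,
                                  test_scores, history, model, truth)
        if config.outdir is not None:
            stage = _stage("write-artifacts")
            _write_artifacts(config, result, test_n)
        return result
    except Exception as exc:
        logger.error("experiment failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"experiment failed at stage {stage!r}") from exc


def _score_histogram(scores: np.ndarray, threshold: float,
                     bins: int = 50) -> dict:
    counts, edges = np.histogram(scores, bins=bins)
    return {"bin_edges": edges.tolist(), "counts": counts.tolist(),
            "threshold": threshold}


def _write_artifacts(config: RunConfig, result: ExperimentResult,
                     test_n: BeatMatrix) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    with open(out / "history.csv", "w") as fh:
        fh.write("epoch,recon_loss,d_loss,g_loss\n")
        for i, (r, d, g) in enumerate(zip(result.history.recon_loss,
                                          result.history.d_loss,
                                          result.history.g_loss)):
            fh.write(f"{i},{r:.8g},{d:.8g},{g:.8g}\n")

    with open(out / "test_scores.csv", "w") as fh:
        fh.write("r_score,d_score,a_score,true_label\n")
        for r, d, a, t in zip(result.test_scores.r_scores,
                              result.test_scores.d_scores,
                              result.test_scores.a_scores,
                              result.test_labels):
            fh.write(f"{r:.8g},{d:.8g},{a:.8g},{t}\n")

    rep = result.report
    payload = {
        "threshold": result.threshold,
        "counts": dataclasses.asdict(rep.counts),
        "acc": rep.acc, "pre": rep.pre, "rec": rep.rec,
        "f1": rep.f1, "auc": rep.auc,
        "train_score_histogram": _score_histogram(
            result.train_scores.a_scores, result.threshold),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2)

    # a few reconstruction examples per outcome class (Fig. 7-style data)
    recon = result.model.reconstruct(test_n.beats[:8, :, None])[:, :, 0]
    with open(out / "reconstructions.csv", "w") as fh:
        fh.write("beat_idx,sample,input,reconstruction\n")
        for i in range(recon.shape[0]):
            for s in range(recon.shape[1]):
                fh.write(f"{i},{s},{test_n.beats[i, s]:.6g},"
                         f"{recon[i, s]:.6g}\n")

    if config.save_model:
        save_params(result.model, out / "model.npz")
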