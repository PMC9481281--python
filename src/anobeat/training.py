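"""One-class adversarial training on normal beats.

Each batch alternates two updates: the discriminator descends a binary
cross-entropy that labels original beats real and reconstructions fake,
then the autoencoder descends ``MSE(x, x') + gamma * g_loss`` where
``g_loss`` is the non-saturating generator objective ``-log D(x')``.
``gamma = 0`` reduces the procedure to a plain autoencoder: the
autoencoder's random streams (init, shuffling, dropout) are separate from
the discriminator's, so its trajectory is then independent of the
adversary.

Epoch reconstruction losses in the history are *end-of-epoch* evaluations
of the full training set with dropout disabled, so they can be reproduced
exactly from the saved parameters; discriminator/adversarial entries are
online batch means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BeatMatrix
from .model import AAE, ModelSpec
from .nn import Adam

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "reconstruction_loss",
    "adversarial_losses",
    "train",
    "evaluate_reconstruction_loss",
    "PROB_EPS",
]

PROB_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    lr_ae: float = 1e-3
    lr_d: float = 2e-4
    adam_betas: tuple[float, float] = (0.5, 0.999)
    gamma: float = 0.05          # adversarial weight in the AE objective
    seed: int = 0
    patience: int = 10           # early stop on reconstruction-loss plateau
    min_delta: float = 1e-5
    restore_best: bool = True    # keep the best-reconstruction epoch's weights

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.lr_ae <= 0 or self.lr_d <= 0:
            raise ValueError("learning rates must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


@dataclass
class TrainHistory:
    recon_loss: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    g_loss: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.recon_loss)


def reconstruction_loss(x: np.ndarray, x_prime: np.ndarray) -> float:
    """Mean squared error between a beat (or batch) and its reconstruction."""
    x = np.asarray(x, dtype=np.float64)
    x_prime = np.asarray(x_prime, dtype=np.float64)
    if x.shape != x_prime.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    return float(np.mean((x - x_prime) ** 2))


def adversarial_losses(d_real: np.ndarray | float,
                       d_recon: np.ndarray | float) -> tuple[float, float]:
    """Discriminator and (non-saturating) generator losses.

    ``d_loss = -[mean log D(real) + mean log(1 - D(recon))]`` and
    ``g_loss = -mean log D(recon)``; probabilities are clamped to
    ``[eps, 1 - eps]`` before taking logs.
    """
    d_real = np.atleast_1d(np.asarray(d_real, dtype=np.float64))
    d_recon = np.atleast_1d(np.asarray(d_recon, dtype=np.float64))
    for name, v in (("d_real", d_real), ("d_recon", d_recon)):
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{name} must lie in [0, 1] before clamping")
    pr = np.clip(d_real, PROB_EPS, 1.0 - PROB_EPS)
    pf = np.clip(d_recon, PROB_EPS, 1.0 - PROB_EPS)
    d_loss = float(-(np.mean(np.log(pr)) + np.mean(np.log(1.0 - pf))))
    g_loss = float(-np.mean(np.log(pf)))
    return d_loss, g_loss


def evaluate_reconstruction_loss(model: AAE, beats: np.ndarray,
                                 batch_size: int = 256) -> float:
    """Mean per-beat MSE over ``beats`` with dropout disabled."""
    x = np.asarray(beats, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None]
    losses = []
    for lo in range(0, x.shape[0], batch_size):
        xb = x[lo : lo + batch_size].astype(np.float64)
        rec = np.asarray(model.reconstruct(xb), dtype=np.float64)
        losses.append(np.mean((xb - rec) ** 2) * xb.shape[0])
    return float(np.sum(losses) / x.shape[0])


def train(
    train_beats: BeatMatrix | np.ndarray,
    model_spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
) -> tuple[AAE, TrainHistory]:
    """Fit the adversarial autoencoder on normal beats only.

    ``train_beats`` may be a labelled :class:`BeatMatrix` (all labels must
    be ``N``) or a bare ``(n, 250)`` array of normalized beats.  Returns
    the trained model and the per-epoch loss history.
    """
    config = config or TrainConfig()
    if isinstance(train_beats, BeatMatrix):
        if train_beats.labels.size and np.any(train_beats.labels != "N"):
            bad = sorted(set(train_beats.labels) - {"N"})
            raise ValueError(
                f"one-class training requires normal beats only; "
                f"found classes {bad}"
            )
        x = train_beats.beats
    else:
        x = np.asarray(train_beats, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("training data must be a nonempty (n, 250) matrix")
    n = x.shape[0]

    ss = np.random.SeedSequence([int(config.seed), 0x7A1])
    seeds = ss.spawn(4)
    model = AAE(model_spec, seed=int(config.seed))
    x = x[:, :, None].astype(model.dtype)
    rng_shuffle = np.random.default_rng(seeds[0])
    rng_ae = np.random.default_rng(seeds[1])
    rng_d = np.random.default_rng(seeds[2])

    opt_ae = Adam(model.ae_parameters(), lr=config.lr_ae,
                  betas=config.adam_betas)
    opt_d = Adam(model.discriminator.parameters(), lr=config.lr_d,
                 betas=config.adam_betas)

    history = TrainHistory()
    best = np.inf
    best_params: list[np.ndarray] | None = None
    stale = 0
    adversarial = config.gamma > 0

    for _epoch in range(config.epochs):
        order = rng_shuffle.permutation(n)
        d_losses, g_losses, weights = [], [], []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb = x[idx]
            b = xb.shape[0]

            # autoencoder forward (training mode caches for backward)
            z = model.encoder.forward(xb, train=True, rng=rng_ae)
            x_rec = model.decoder.forward(z, train=True, rng=rng_ae)

            if adversarial:
                # --- discriminator step on [real; fake] ----------------
                both = np.concatenate([xb, x_rec], axis=0)
                p = model.discriminator.forward(both, train=True, rng=rng_d)
                d_loss, _ = adversarial_losses(p[:b, 0], p[b:, 0])
                pc = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
                dp = np.zeros_like(p)
                dp[:b] = -1.0 / (b * pc[:b])
                dp[b:] = 1.0 / (b * (1.0 - pc[b:]))
                model.discriminator.backward(dp)
                opt_d.step()
                model.discriminator.zero_grad()

                # --- generator (AE) step -------------------------------
                p_fake = model.discriminator.forward(x_rec, train=True,
                                                     rng=rng_d)
                _, g_loss = adversarial_losses(np.full(b, 0.5), p_fake[:, 0])
                pc = np.clip(p_fake, PROB_EPS, 1.0 - PROB_EPS)
                dx_adv = model.discriminator.backward(
                    -config.gamma / (b * pc))
                model.discriminator.zero_grad()  # grads belong to AE path
                d_losses.append(d_loss)
                g_losses.append(g_loss)
            else:
                dx_adv = 0.0
            weights.append(b)

            dx_rec = 2.0 * (x_rec - xb) / x_rec.size + dx_adv
            model.encoder.backward(model.decoder.backward(dx_rec))
            opt_ae.step()
            for p_ in model.ae_parameters():
                p_.zero_grad()

        epoch_recon = evaluate_reconstruction_loss(model, x[:, :, 0])
        history.recon_loss.append(epoch_recon)
        w = np.asarray(weights, dtype=np.float64)
        if adversarial:
            history.d_loss.append(float(np.average(d_losses, weights=w)))
            history.g_loss.append(float(np.average(g_losses, weights=w)))
        else:
            history.d_loss.append(float("nan"))
            history.g_loss.append(float("nan"))

        if epoch_recon < best - config.min_delta:
            best = epoch_recon
            stale = 0
            if config.restore_best:
                best_params = [p.value.copy() for p in model.parameters()]
        else:
            stale += 1
            if stale >= config.patience:
                break

    # adversarial updates make late epochs oscillate; hand back the
    # best-reconstruction checkpoint rather than whatever came last
    if config.restore_best and best_params is not None:
        for p, v in zip(model.parameters(), best_params):
            p.value[...] = v
    model.is_trained = True
    return model, history
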