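"""The adversarial autoencoder: encoder, decoder and discriminator.

All three subnetworks are TCN stacks on 250-sample beats:

* encoder — ``TCN(1->32) -> pool5 -> TCN(32->16) -> pool5 -> TCN(16->8)
  -> pool5 -> flatten(16) -> dense(8) -> ReLU``; latent dimension 8.
* decoder — ``dense(16) -> ReLU -> reshape(2, 8) -> [up5 -> TCN] x 3
  (8->8, 8->16, 16->32) -> causal conv(32->1, k=9) -> tanh``.
* discriminator — encoder trunk plus ``dense(8) -> ReLU -> dense(1)
  -> sigmoid``.

Upsampling repeats the time axis only; channel changes are carried by the
TCN blocks.  The decoder output activation is tanh so reconstructions live
on the [-1, 1] scale of normalized beats (configurable back to ReLU).
Dilations grow 1, 2, 4 across the three blocks of each stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BEAT_LEN
from . import nn
from .nn import (
    Dense,
    Flatten,
    Param,
    ReLU,
    Reshape,
    Sequential,
    Sigmoid,
    Tanh,
    Upsample1d,
    MaxPool1d,
)
from .tcn import CausalConv1d, TCNBlock, TCNBlockSpec

__all__ = ["ModelSpec", "AAE", "save_params", "load_params"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters; defaults mirror the reference design."""

    beat_length: int = BEAT_LEN
    latent_dim: int = 8
    channels: tuple[int, int, int] = (32, 16, 8)
    kernel_size: int = 9
    dilations: tuple[int, int, int] = (1, 2, 4)
    pool_factor: int = 5
    dropout_rate: float = 0.05
    decoder_output_activation: str = "tanh"  # or "relu"

    def __post_init__(self) -> None:
        t = self.beat_length
        for _ in self.channels:
            if t % self.pool_factor:
                raise ValueError(
                    "beat_length must divide by pool_factor at every stage"
                )
            t //= self.pool_factor
        if self.decoder_output_activation not in ("tanh", "relu"):
            raise ValueError("decoder_output_activation must be tanh or relu")

    @property
    def bottleneck_len(self) -> int:
        return self.beat_length // self.pool_factor ** len(self.channels)

    @property
    def flat_dim(self) -> int:
        return self.bottleneck_len * self.channels[-1]


def _encoder_trunk(spec: ModelSpec, rng: np.random.Generator,
                   name: str) -> list:
    layers: list = []
    cin = 1
    for i, (cout, d) in enumerate(zip(spec.channels, spec.dilations)):
        layers.append(TCNBlock(
            TCNBlockSpec(cin, cout, spec.kernel_size, d, spec.dropout_rate),
            rng, name=f"{name}.block{i}"))
        layers.append(MaxPool1d(spec.pool_factor))
        cin = cout
    layers.append(Flatten())
    return layers


def _build_encoder(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    layers = _encoder_trunk(spec, rng, "enc")
    layers += [Dense(spec.flat_dim, spec.latent_dim, rng, "enc.dense"), ReLU()]
    return Sequential(layers)


def _build_decoder(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    rev_channels = spec.channels[::-1]          # (8, 16, 32)
    rev_dilations = spec.dilations[: len(rev_channels)]
    layers: list = [
        Dense(spec.latent_dim, spec.flat_dim, rng, "dec.dense"),
        ReLU(),
        Reshape((spec.bottleneck_len, rev_channels[0])),
    ]
    cin = rev_channels[0]
    for i, (cout, d) in enumerate(zip(rev_channels, rev_dilations)):
        layers.append(Upsample1d(spec.pool_factor))
        layers.append(TCNBlock(
            TCNBlockSpec(cin, cout, spec.kernel_size, d, spec.dropout_rate),
            rng, name=f"dec.block{i}"))
        cin = cout
    layers.append(CausalConv1d(cin, 1, spec.kernel_size, 1, rng,
                               name="dec.out"))
    layers.append(Tanh() if spec.decoder_output_activation == "tanh"
                  else ReLU())
    return Sequential(layers)


def _build_discriminator(spec: ModelSpec, rng: np.random.Generator) -> Sequential:
    layers = _encoder_trunk(spec, rng, "disc")
    layers += [
        Dense(spec.flat_dim, spec.latent_dim, rng, "disc.dense1"),
        ReLU(),
        Dense(spec.latent_dim, 1, rng, "disc.dense2"),
        Sigmoid(),
    ]
    return Sequential(layers)


class AAE:
    """Adversarial autoencoder with one-class anomaly-scoring heads.

    Construction is deterministic in ``seed``; dropout is active only when
    a training-mode forward is requested explicitly.
    """

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0):
        self.spec = spec or ModelSpec()
        self.seed = seed
        self.dtype = nn.DEFAULT_DTYPE
        init_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 0xA0E]))
        self.encoder = _build_encoder(self.spec, init_rng)
        self.decoder = _build_decoder(self.spec, init_rng)
        self.discriminator = _build_discriminator(self.spec, init_rng)
        self.is_trained = False

    # ---- parameter plumbing -------------------------------------------

    def parameters(self) -> list[Param]:
        return (self.encoder.parameters() + self.decoder.parameters()
                + self.discriminator.parameters())

    def ae_parameters(self) -> list[Param]:
        return self.encoder.parameters() + self.decoder.parameters()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # ---- shape handling -----------------------------------------------

    def _as_batch(self, x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=self.dtype)
        single = x.ndim == 1 or (x.ndim == 2 and x.shape == (self.spec.beat_length, 1))
        if x.ndim == 1:
            x = x[None, :, None]
        elif x.ndim == 2:
            if x.shape == (self.spec.beat_length, 1):
                x = x[None]
            else:
                x = x[:, :, None]
        if x.shape[1] != self.spec.beat_length or x.shape[2] != 1:
            raise ValueError(
                f"expected beats of length {self.spec.beat_length}, "
                f"got shape {x.shape}"
            )
        return x, single

    # ---- forward maps --------------------------------------------------

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Map beat(s) to the 8-dimensional latent code."""
        xb, single = self._as_batch(x)
        z = self.encoder.forward(xb)
        return z[0] if single else z

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Map latent code(s) back to a 250-sample beat."""
        z = np.asarray(z, dtype=self.dtype)
        single = z.ndim == 1
        if single:
            z = z[None]
        if z.shape[1] != self.spec.latent_dim:
            raise ValueError(
                f"expected latent dimension {self.spec.latent_dim}, "
                f"got {z.shape[1]}"
            )
        x = self.decoder.forward(z)
        return x[0] if single else x

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        xb, single = self._as_batch(x)
        out = self.decoder.forward(self.encoder.forward(xb))
        return out[0] if single else out

    def discriminate(self, x: np.ndarray) -> np.ndarray | float:
        """Probability that beat(s) are real rather than reconstructed."""
        xb, single = self._as_batch(x)
        p = self.discriminator.forward(xb)[:, 0]
        return float(p[0]) if single else p

    def shape_trace(self, subnetwork: str) -> list[tuple[str, tuple[int, ...]]]:
        """Per-layer output shapes (excluding batch axis) of one subnetwork."""
        trace: list = []
        if subnetwork == "encoder":
            x = np.zeros((1, self.spec.beat_length, 1))
            self.encoder.forward(x, trace=trace)
        elif subnetwork == "decoder":
            z = np.zeros((1, self.spec.latent_dim))
            self.decoder.forward(z, trace=trace)
        elif subnetwork == "discriminator":
            x = np.zeros((1, self.spec.beat_length, 1))
            self.discriminator.forward(x, trace=trace)
        else:
            raise ValueError(f"unknown subnetwork {subnetwork!r}")
        return trace


def save_params(model: AAE, path) -> None:
    """Serialize all weights (and the spec) to an ``.npz`` container."""
    arrays = {p.name: p.value for p in model.parameters()}
    if len(arrays) != len(model.parameters()):
        raise RuntimeError("duplicate parameter names")
    meta = dict(
        seed=model.seed,
        dtype=str(np.dtype(model.dtype)),
        is_trained=int(model.is_trained),
        beat_length=model.spec.beat_length,
        latent_dim=model.spec.latent_dim,
        channels=np.array(model.spec.channels),
        kernel_size=model.spec.kernel_size,
        dilations=np.array(model.spec.dilations),
        pool_factor=model.spec.pool_factor,
        dropout_rate=model.spec.dropout_rate,
    )
    np.savez(path, __activation__=model.spec.decoder_output_activation,
             **{f"__{k}__": v for k, v in meta.items()}, **arrays)


def load_params(path) -> AAE:
    """Rebuild an :class:`AAE` from :func:`save_params` output, bit-exactly."""
    with np.load(path, allow_pickle=False) as data:
        spec = ModelSpec(
            beat_length=int(data["__beat_length__"]),
            latent_dim=int(data["__latent_dim__"]),
            channels=tuple(int(c) for c in data["__channels__"]),
            kernel_size=int(data["__kernel_size__"]),
            dilations=tuple(int(d) for d in data["__dilations__"]),
            pool_factor=int(data["__pool_factor__"]),
            dropout_rate=float(data["__dropout_rate__"]),
            decoder_output_activation=str(data["__activation__"]),
        )
        with nn.default_dtype(str(data["__dtype__"])):
            model = AAE(spec, seed=int(data["__seed__"]))
        for p in model.parameters():
            if p.name not in data:
                raise ValueError(f"missing parameter {p.name!r} in {path}")
            stored = data[p.name]
            if stored.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name!r}")
            p.value[...] = stored
        model.is_trained = bool(int(data["__is_trained__"]))
    return model
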