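"""Dilated causal 1-D convolution and the two-layer TCN residual block.

The causal convolution computes ``y[t] = sum_j w[j] . x[t - j*d]`` with
left zero-padding of ``(k-1)*d`` so the output has the input's length and
depends only on current and past samples.  A residual block stacks two such
convolutions (same dilation) with weight normalization, ReLU and dropout,
adds a skip path (identity, or a kernel-1 convolution when the channel
count changes) and applies a final ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dropout, Layer, Param, ReLU, glorot_uniform
from .nn import default_dtype as nn_default_dtype

__all__ = [
    "TCNBlockSpec",
    "CausalConv1d",
    "causal_dilated_conv",
    "TCNBlock",
    "receptive_field",
]

_NORM_EPS = 1e-12


@dataclass(frozen=True)
class TCNBlockSpec:
    """Hyperparameters of one residual block (both convs share ``dilation``)."""

    in_channels: int
    out_channels: int
    kernel_size: int = 9
    dilation: int = 1
    dropout_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.dilation < 1:
            raise ValueError("dilation must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


class CausalConv1d(Layer):
    """Left-padded dilated convolution, optionally weight-normalized.

    The kernel has shape ``(kernel_size, in_channels, out_channels)``; tap
    ``j`` multiplies ``x[t - j*d]``.  With weight normalization the kernel
    is stored as a direction ``v`` plus a per-output-channel scale ``g``
    and the effective kernel is ``g * v / ||v||`` (norm taken over the
    ``k * cin`` fan-in of each output channel).  The forward/backward
    passes run one GEMM per tap over shifted views of the padded input,
    avoiding an im2col copy.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, rng: np.random.Generator | None = None,
                 weight_norm: bool = True, name: str = "conv"):
        if kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        self.cin, self.cout = in_channels, out_channels
        self.k, self.d = kernel_size, dilation
        self.weight_norm = weight_norm
        rng = rng or np.random.default_rng(0)
        fan_in = kernel_size * in_channels
        v0 = glorot_uniform(rng, (kernel_size, in_channels, out_channels),
                            fan_in, out_channels)
        if weight_norm:
            self.v = Param(f"{name}.v", v0)
            # g = ||v|| so the initial effective kernel equals v
            self.g = Param(f"{name}.g", self._fan_norm(v0))
            self.b = Param(f"{name}.b", np.zeros(out_channels))
        else:
            self.w = Param(f"{name}.w", v0)
            self.b = Param(f"{name}.b", np.zeros(out_channels))

    @staticmethod
    def _fan_norm(v: np.ndarray) -> np.ndarray:
        return np.sqrt(np.maximum(np.sum(v**2, axis=(0, 1)), _NORM_EPS**2))

    def parameters(self) -> list[Param]:
        if self.weight_norm:
            return [self.v, self.g, self.b]
        return [self.w, self.b]

    def _kernel(self) -> np.ndarray:
        if not self.weight_norm:
            return self.w.value
        return self.v.value * (self.g.value / self._fan_norm(self.v.value))

    def set_kernel(self, weights: np.ndarray) -> None:
        """Set the effective kernel from ``(k, cin, cout)`` weights
        (tap ``j`` multiplies ``x[t - j*d]``)."""
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (self.k, self.cin, self.cout):
            raise ValueError(
                f"expected kernel shape {(self.k, self.cin, self.cout)}, "
                f"got {weights.shape}"
            )
        if self.weight_norm:
            self.v.value[...] = weights
            self.g.value[...] = self._fan_norm(weights)
        else:
            self.w.value[...] = weights

    def forward(self, x, train=False, rng=None):
        b, t, c = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        pad = (self.k - 1) * self.d
        xp = np.pad(x, ((0, 0), (pad, 0), (0, 0)))
        w = self._kernel()
        y = np.empty((b, t, self.cout), dtype=xp.dtype)
        y[...] = self.b.value
        for j in range(self.k):
            lo = pad - j * self.d
            y += xp[:, lo : lo + t, :] @ w[j]
        self._xp = xp
        self._t = t
        return y

    def backward(self, dy):
        b, t, _ = dy.shape
        pad = (self.k - 1) * self.d
        w = self._kernel()
        dy2 = dy.reshape(b * t, self.cout)
        dw = np.empty_like(w)
        dxp = np.zeros_like(self._xp)
        for j in range(self.k):
            lo = pad - j * self.d
            xs = self._xp[:, lo : lo + t, :]
            dw[j] = xs.reshape(b * t, self.cin).T @ dy2
            dxp[:, lo : lo + t, :] += dy @ w[j].T
        self.b.grad += dy2.sum(axis=0)
        if self.weight_norm:
            norm = self._fan_norm(self.v.value)
            vhat = self.v.value / norm
            proj = np.sum(dw * vhat, axis=(0, 1))
            self.g.grad += proj
            self.v.grad += (self.g.value / norm) * (dw - vhat * proj)
        else:
            self.w.grad += dw
        return dxp[:, pad:, :]


def causal_dilated_conv(x: np.ndarray, weights: np.ndarray,
                        dilation: int = 1,
                        bias: np.ndarray | None = None) -> np.ndarray:
    """Functional causal dilated convolution.

    Parameters
    ----------
    x : array, shape (T, C_in) or (B, T, C_in)
        Input sequence(s); a plain 1-D array is treated as one channel.
    weights : array, shape (k, C_in, C_out) or (k,)
        Kernel; tap ``j`` multiplies ``x[t - j*dilation]``.
    dilation : int
        Tap spacing ``d >= 1``.
    """
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    squeeze_batch = x.ndim < 3
    squeeze_chan = False
    if x.ndim == 1:
        x = x[:, None]
        squeeze_chan = True
    if x.ndim == 2:
        x = x[None]
    if weights.ndim == 1:
        weights = weights[:, None, None]
    if weights.ndim != 3:
        raise ValueError("weights must have shape (k, C_in, C_out)")
    if weights.shape[0] < 1:
        raise ValueError("kernel size must be >= 1")
    with nn_default_dtype(np.float64):
        layer = CausalConv1d(weights.shape[1], weights.shape[2],
                             weights.shape[0], dilation, weight_norm=False)
    layer.set_kernel(weights)
    layer.b.value[...] = 0.0 if bias is None else bias
    y = layer.forward(x)
    if squeeze_chan:
        y = y[..., 0]
    return y[0] if squeeze_batch else y


class TCNBlock(Layer):
    """Residual block: ``ReLU(skip(x) + F(x))`` with
    ``F = [causal conv -> weight norm -> ReLU -> dropout] x 2``."""

    def __init__(self, spec: TCNBlockSpec, rng: np.random.Generator,
                 name: str = "tcn"):
        self.spec = spec
        self.conv1 = CausalConv1d(spec.in_channels, spec.out_channels,
                                  spec.kernel_size, spec.dilation, rng,
                                  name=f"{name}.conv1")
        self.conv2 = CausalConv1d(spec.out_channels, spec.out_channels,
                                  spec.kernel_size, spec.dilation, rng,
                                  name=f"{name}.conv2")
        self.relu1, self.relu2 = ReLU(), ReLU()
        self.drop1 = Dropout(spec.dropout_rate)
        self.drop2 = Dropout(spec.dropout_rate)
        if spec.in_channels != spec.out_channels:
            self.proj: CausalConv1d | None = CausalConv1d(
                spec.in_channels, spec.out_channels, 1, 1, rng,
                weight_norm=False, name=f"{name}.proj")
        else:
            self.proj = None
        self._out_relu = ReLU()

    def parameters(self) -> list[Param]:
        params = (self.conv1.parameters() + self.conv2.parameters())
        if self.proj is not None:
            params += self.proj.parameters()
        return params

    def forward(self, x, train=False, rng=None):
        h = self.drop1.forward(
            self.relu1.forward(self.conv1.forward(x, train, rng)), train, rng)
        f = self.drop2.forward(
            self.relu2.forward(self.conv2.forward(h, train, rng)), train, rng)
        skip = x if self.proj is None else self.proj.forward(x, train, rng)
        return self._out_relu.forward(skip + f)

    def backward(self, dy):
        ds = self._out_relu.backward(dy)
        df = self.conv2.backward(self.relu2.backward(self.drop2.backward(ds)))
        dx = self.conv1.backward(self.relu1.backward(self.drop1.backward(df)))
        if self.proj is None:
            return dx + ds
        return dx + self.proj.backward(ds)


def receptive_field(kernel_size: int, dilations: tuple[int, ...] | list[int]) -> int:
    """Past-input span of a stack of two-conv residual blocks.

    Each block contributes ``2 * (k - 1) * d`` samples of history on top of
    the current sample: ``1 + sum_blocks 2*(k-1)*d``.
    """
    if kernel_size < 1:
        raise ValueError("kernel_size must be >= 1")
    if any(d < 1 for d in dilations):
        raise ValueError("dilations must be >= 1")
    return 1 + sum(2 * (kernel_size - 1) * d for d in dilations)
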