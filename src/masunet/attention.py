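"""Dual attention gate: spatial and channel attention on skip connections.

The gate modulates an encoder skip feature x with a decoder gating
feature g of equal resolution and width:

* spatial coefficient (per pixel):
      alpha = sigmoid(W2(ReLU(Wx·x + Wg·g)))
* channel coefficient (per channel):
      beta = sigmoid(W1(W0(ReLU(AvgPool(x) + AvgPool(g)))))
  where AvgPool is global average pooling and the ReLU is applied to the
  pooled sum, with no nonlinearity between the two 1x1 maps — the
  ``se_order`` flag switches to the conventional squeeze-excitation
  order W1(ReLU(W0(·))) instead.
* gate output: alpha ⊙ beta ⊙ x, with alpha broadcast over channels and
  beta broadcast over pixels.

All linear maps are 1x1 convolutions with biases.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .blocks import Conv2d, Module

__all__ = ["AttentionGate", "spatial_attention", "channel_attention",
           "attention_gate_forward"]


class AttentionGate(Module):
    """Combined spatial + channel attention gate.

    Parameters
    ----------
    channels : int
        Width of both the skip feature x and the gating feature g
        (F_l = F_g by network wiring).
    inter_channels : int, optional
        Width of the spatial branch's intermediate map (F_int);
        defaults to channels // 2 (minimum 1).
    reduction : int
        Channel-branch bottleneck divisor (default 16); the hidden width
        is max(1, channels // reduction) so narrow test networks remain
        constructible.
    se_order : bool
        Use the conventional W1(ReLU(W0(·))) channel-branch order instead
        of the default W1(W0(ReLU(·))).
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 inter_channels: int | None = None, reduction: int = 16,
                 se_order: bool = False):
        self.channels = channels
        self.inter_channels = inter_channels or max(channels // 2, 1)
        self.reduction = reduction
        self.se_order = se_order
        hidden = max(channels // reduction, 1)
        # spatial branch
        self.w_x = Conv2d(channels, self.inter_channels, 1, rng)
        self.w_g = Conv2d(channels, self.inter_channels, 1, rng)
        self.w_2 = Conv2d(self.inter_channels, 1, 1, rng)
        # channel branch
        self.w_0 = Conv2d(channels, hidden, 1, rng)
        self.w_1 = Conv2d(hidden, channels, 1, rng)

    # ------------------------------------------------------------------
    def _check(self, x: Tensor, g: Tensor) -> None:
        if x.shape[2:] != g.shape[2:]:
            raise ValueError(
                f"attention gate needs same-resolution inputs, got skip "
                f"{x.shape[2:]} vs gate {g.shape[2:]}"
            )
        if x.shape[1] != self.channels or g.shape[1] != self.channels:
            raise ValueError(
                f"attention gate built for {self.channels} channels, got "
                f"skip {x.shape[1]} / gate {g.shape[1]}"
            )

    def spatial(self, x: Tensor, g: Tensor) -> Tensor:
        """Per-pixel coefficient alpha, shape (N, 1, H, W), values in (0, 1)."""
        self._check(x, g)
        q = (self.w_x(x) + self.w_g(g)).relu()
        return self.w_2(q).sigmoid()

    def channel(self, x: Tensor, g: Tensor) -> Tensor:
        """Per-channel coefficient beta, shape (N, C, 1, 1), values in (0, 1)."""
        self._check(x, g)
        pooled = x.mean(axis=(2, 3), keepdims=True) + g.mean(axis=(2, 3), keepdims=True)
        if self.se_order:
            q = self.w_1(self.w_0(pooled).relu())
        else:
            q = self.w_1(self.w_0(pooled.relu()))
        return q.sigmoid()

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        """Gated skip feature alpha ⊙ beta ⊙ x, same shape as x."""
        alpha = self.spatial(x, g)
        beta = self.channel(x, g)
        return x * alpha * beta

    # ------------------------------------------------------------------
    def saturate_open(self, bias: float = 40.0) -> None:
        """Force both coefficients to 1 (gate fully open).

        Zeroes the output maps' weights and sets their biases so both
        sigmoids saturate; with float32 sigmoid(40) rounds to exactly 1,
        making the gated network match the gate-free one bitwise.
        """
        self.w_2.weight.data[...] = 0.0
        self.w_2.bias.data[...] = bias
        self.w_1.weight.data[...] = 0.0
        self.w_1.bias.data[...] = bias


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x)), False


def spatial_attention(x, g, gate: AttentionGate):
    """Functional form of the spatial coefficient (ndarray in → ndarray out)."""
    xt, wx = _wrap(x)
    gt, _ = _wrap(g)
    out = gate.spatial(xt, gt)
    return out if wx else out.numpy()


def channel_attention(x, g, gate: AttentionGate):
    """Functional form of the channel coefficient."""
    xt, wx = _wrap(x)
    gt, _ = _wrap(g)
    out = gate.channel(xt, gt)
    return out if wx else out.numpy()


def attention_gate_forward(x, g, gate: AttentionGate):
    """Functional form of the full gate output alpha ⊙ beta ⊙ x."""
    xt, wx = _wrap(x)
    gt, _ = _wrap(g)
    out = gate.forward(xt, gt)
    return out if wx else out.numpy()
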