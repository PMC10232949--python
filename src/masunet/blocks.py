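"""Reusable network blocks: GN conv blocks, pooling, upsampling, ASPP.

The building blocks of the zonal-segmentation network:

* ``GroupNorm`` — group normalization, y = (x − E[x_g]) / sqrt(Var[x_g] + ε) · γ + β,
  with statistics taken per sample over channel groups, so behaviour is
  independent of batch size (the reason it replaces batch norm here).
* ``ConvBlock`` — two rounds of (3x3 conv, same padding → GN → ReLU),
  optionally followed by dropout (p = 0.5) in the bottleneck block.
* ``max_pool_downsample`` / ``nearest_upsample`` — the 2x down / integer-up
  resampling primitives of the encoder and decoder.
* ``UpConvBlock`` — nearest upsample x2 then a channel-halving 3x3 conv
  with GN and ReLU.
* ``ASPP`` — atrous spatial pyramid pooling: parallel 3x3 dilated
  convolutions at rates (1, 6, 12, 18), each with padding equal to its
  rate so spatial size is preserved, concatenated and reduced by a 1x1
  convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, conv2d, maxpool2x2, upsample_nearest

__all__ = [
    "Module",
    "Conv2d",
    "GroupNorm",
    "ConvBlock",
    "UpConvBlock",
    "ASPPConfig",
    "ASPP",
    "group_normalize",
    "max_pool_downsample",
    "nearest_upsample",
    "resolve_gn_groups",
]


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x)), False


def resolve_gn_groups(channels: int, groups: int,
                      min_group_width: int = 8) -> int:
    """Group count actually used for a layer of ``channels`` width.

    Uses the requested ``groups`` (default 8) but never lets a group get
    narrower than ``min_group_width`` channels: at reduced widths the
    count shrinks toward 1 (layer norm over channels). With one channel
    per group GN degenerates to instance norm, which discards the
    relative scale between channels and measurably impairs narrow
    networks; a minimum group width avoids that while leaving the
    default widths (64 and up) at the requested count.
    """
    resolved = min(groups, max(channels // min_group_width, 1))
    while channels % resolved:
        resolved -= 1
    return resolved


class Module:
    """Minimal module container: parameter collection and train/eval mode."""

    def _children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
        for child in self._children():
            params.extend(child.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 2-D convolution with Kaiming-uniform weights and zero bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int = 0, dilation: int = 1):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.dilation = dilation
        # Kaiming-uniform as parameterized by the mainstream deep-learning
        # frameworks' conv default (negative-slope a = sqrt(5)), giving
        # bound = 1/sqrt(fan_in); biases start at zero — they are redundant
        # under the following normalization, and a zero output-head bias
        # makes the initial prediction unbiased (p = 0.5) for every class
        fan_in = in_channels * kernel_size * kernel_size
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound,
                        size=(out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      padding=self.padding, dilation=self.dilation)


class GroupNorm(Module):
    """Group normalization with learnable per-channel scale and shift."""

    def __init__(self, channels: int, num_groups: int = 8, eps: float = 1e-5):
        num_groups = resolve_gn_groups(channels, num_groups)
        if channels % num_groups:
            raise ValueError(
                f"group normalization requires channels ({channels}) divisible "
                f"by num_groups ({num_groups})"
            )
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.channels = channels
        self.num_groups = num_groups
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(
                f"group norm built for {self.channels} channels, got {c}")
        g = self.num_groups
        xr = x.reshape(n, g, (c // g) * h * w)
        mu = xr.mean(axis=2, keepdims=True)
        centered = xr - mu
        var = (centered * centered).mean(axis=2, keepdims=True)
        xn = centered / (var + self.eps).sqrt()
        xn = xn.reshape(n, c, h, w)
        gamma = self.gamma.reshape(1, c, 1, 1)
        beta = self.beta.reshape(1, c, 1, 1)
        return xn * gamma + beta


def group_normalize(x, num_groups: int, gamma=None, beta=None,
                    eps: float = 1e-5):
    """Functional group normalization of a (N, C, H, W) array.

    ``gamma``/``beta`` default to 1/0 (pure normalization). Returns the
    same container kind as the input (ndarray in → ndarray out).
    """
    t, was_tensor = _as_tensor(x)
    n, c, h, w = t.shape
    if c % num_groups:
        raise ValueError(
            f"group normalization requires channels ({c}) divisible by "
            f"num_groups ({num_groups})"
        )
    gn = GroupNorm(c, num_groups=num_groups, eps=eps)
    # keep the explicit group count even below the default fallback width
    gn.num_groups = num_groups
    if gamma is not None:
        gn.gamma = Tensor(np.asarray(gamma, dtype=t.dtype), requires_grad=True)
    if beta is not None:
        gn.beta = Tensor(np.asarray(beta, dtype=t.dtype), requires_grad=True)
    out = gn.forward(t)
    return out if was_tensor else out.numpy()


def max_pool_downsample(x):
    """2x2 max pooling, stride 2; channels unchanged, H and W halved."""
    t, was_tensor = _as_tensor(x)
    out = maxpool2x2(t)
    return out if was_tensor else out.numpy()


def nearest_upsample(x, scale: int):
    """Nearest-neighbour upsampling by an integer ``scale``."""
    t, was_tensor = _as_tensor(x)
    out = upsample_nearest(t, scale)
    return out if was_tensor else out.numpy()


class ConvBlock(Module):
    """Two (3x3 conv → GN → ReLU) rounds, optional trailing dropout.

    The bottleneck variant sets ``with_dropout`` (p = 0.5), applied after
    the second activation and only in training mode.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, gn_groups: int = 8,
                 with_dropout: bool = False, dropout_p: float = 0.5):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.with_dropout = with_dropout
        self.dropout_p = dropout_p
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng, padding=1)
        self.gn1 = GroupNorm(out_channels, gn_groups)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng, padding=1)
        self.gn2 = GroupNorm(out_channels, gn_groups)

    def forward(self, x: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"conv block expects {self.in_channels} input channels, "
                f"got {x.shape[1]}"
            )
        h = self.gn1(self.conv1(x)).relu()
        h = self.gn2(self.conv2(h)).relu()
        if self.with_dropout and training:
            if rng is None:
                raise ValueError("training-mode dropout needs an RNG")
            keep = 1.0 - self.dropout_p
            mask = (rng.random(h.shape) < keep).astype(h.dtype) / keep
            h = h * Tensor(mask)
        return h


class UpConvBlock(Module):
    """Nearest upsample x2 followed by a channel-halving 3x3 conv + GN + ReLU."""

    def __init__(self, in_channels: int, rng: np.random.Generator,
                 gn_groups: int = 8):
        if in_channels % 2:
            raise ValueError(
                f"up-conv block halves channels; input width {in_channels} is odd")
        self.in_channels = in_channels
        self.out_channels = in_channels // 2
        self.conv = Conv2d(in_channels, self.out_channels, 3, rng, padding=1)
        self.gn = GroupNorm(self.out_channels, gn_groups)

    def forward(self, x: Tensor) -> Tensor:
        up = upsample_nearest(x, 2)
        return self.gn(self.conv(up)).relu()


@dataclass(frozen=True)
class ASPPConfig:
    """Atrous-pyramid configuration; rates default to (1, 6, 12, 18)."""

    in_channels: int
    out_channels: int
    dilation_rates: tuple[int, ...] = (1, 6, 12, 18)
    rate1_kernel: int = 3  # the rate-1 branch's kernel size

    def __post_init__(self):
        if self.in_channels % len(self.dilation_rates):
            raise ValueError(
                f"ASPP needs in_channels ({self.in_channels}) divisible by the "
                f"number of branches ({len(self.dilation_rates)})"
            )


class ASPP(Module):
    """Parallel dilated convolutions concatenated then reduced by 1x1 conv.

    Each branch is a 3x3 convolution with dilation rate r and padding r
    (so every branch preserves spatial size), followed by GN and ReLU,
    emitting in_channels / n_branches channels; the concatenation restores
    in_channels before the final 1x1 reduction to out_channels.
    """

    def __init__(self, cfg: ASPPConfig, rng: np.random.Generator,
                 gn_groups: int = 8):
        self.cfg = cfg
        branch_ch = cfg.in_channels // len(cfg.dilation_rates)
        self.branch_channels = branch_ch
        self.branches = []
        self.branch_norms = []
        for rate in cfg.dilation_rates:
            k = cfg.rate1_kernel if rate == 1 else 3
            pad = rate if k == 3 else 0
            self.branches.append(
                Conv2d(cfg.in_channels, branch_ch, k, rng,
                       padding=pad, dilation=rate))
            self.branch_norms.append(GroupNorm(branch_ch, gn_groups))
        self.reduce = Conv2d(branch_ch * len(cfg.dilation_rates),
                             cfg.out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"ASPP expects {self.cfg.in_channels} channels, got {x.shape[1]}")
        outs = [gn(conv(x)).relu()
                for conv, gn in zip(self.branches, self.branch_norms)]
        return self.reduce(concat(outs, axis=1))
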