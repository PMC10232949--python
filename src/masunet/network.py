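"""MAS-UNet assembly: encoder, ASPP bottleneck, attention-gated decoder.

Encoder: five conv blocks separated by four 2x2 max-pools, widths
doubling per stage (base, 2b, 4b, 8b, 16b); the fifth block carries
dropout (p = 0.5) and feeds the ASPP bottleneck. Decoder: at each of
four scales an up-conv block halves channels and doubles resolution,
an attention gate modulates the same-scale encoder skip, the gated skip
is concatenated with the decoder feature, and a conv block (scales 1-3)
or the final 1x1 output convolution (scale 4) reduces the width. The
output is a raw per-class logit map — one channel per zone (PZ, TZ) —
with sigmoids applied only at the loss and at inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .attention import AttentionGate
from .autodiff import Tensor, concat
from .blocks import ASPP, ASPPConfig, Conv2d, ConvBlock, Module, UpConvBlock

__all__ = ["MASUNetConfig", "MASUNet", "build_masunet", "predict_masks",
           "save_checkpoint", "load_checkpoint"]

DOWNSAMPLE_FACTOR = 16  # 2**4 pooling stages


@dataclass(frozen=True)
class MASUNetConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the stage-1 encoder width; widths double per
    stage up to 16x base at the bottleneck. ``num_classes`` is one
    sigmoid channel per zone (PZ, TZ). Inputs must have H and W
    divisible by 16 (four pooling stages).
    """

    in_channels: int = 1
    num_classes: int = 2
    base_channels: int = 64
    gn_groups: int = 8
    aspp_rates: tuple[int, ...] = (1, 6, 12, 18)
    dropout_p: float = 0.5
    attention_reduction: int = 16
    se_order: bool = False
    output_kernel: int = 1

    @property
    def stage_widths(self) -> tuple[int, ...]:
        b = self.base_channels
        return (b, 2 * b, 4 * b, 8 * b, 16 * b)


class MASUNet(Module):
    """The full segmentation network (see module docstring for wiring)."""

    def __init__(self, config: MASUNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.stage_widths
        g = config.gn_groups
        # encoder
        self.enc = [
            ConvBlock(config.in_channels, w[0], rng, g),
            ConvBlock(w[0], w[1], rng, g),
            ConvBlock(w[1], w[2], rng, g),
            ConvBlock(w[2], w[3], rng, g),
            ConvBlock(w[3], w[4], rng, g, with_dropout=True,
                      dropout_p=config.dropout_p),
        ]
        self.aspp = ASPP(
            ASPPConfig(w[4], w[4], dilation_rates=config.aspp_rates), rng, g)
        # decoder: coarsest to finest
        self.upconvs = [UpConvBlock(w[4], rng, g), UpConvBlock(w[3], rng, g),
                        UpConvBlock(w[2], rng, g), UpConvBlock(w[1], rng, g)]
        self.gates = [
            AttentionGate(w[3], rng, reduction=config.attention_reduction,
                          se_order=config.se_order),
            AttentionGate(w[2], rng, reduction=config.attention_reduction,
                          se_order=config.se_order),
            AttentionGate(w[1], rng, reduction=config.attention_reduction,
                          se_order=config.se_order),
            AttentionGate(w[0], rng, reduction=config.attention_reduction,
                          se_order=config.se_order),
        ]
        self.dec = [ConvBlock(2 * w[3], w[3], rng, g),
                    ConvBlock(2 * w[2], w[2], rng, g),
                    ConvBlock(2 * w[1], w[1], rng, g)]
        pad = (config.output_kernel - 1) // 2
        self.out_conv = Conv2d(2 * w[0], config.num_classes,
                               config.output_kernel, rng, padding=pad)

    # ------------------------------------------------------------------
    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def forward(self, x, training: bool = False,
                rng: np.random.Generator | None = None,
                bypass_gates: bool = False) -> Tensor:
        """Per-class logits of shape (N, num_classes, H, W).

        ``bypass_gates`` replaces every attention gate by an identity
        skip (the plain-UNet reduction used as an oracle in tests).
        """
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(
                f"network built for {self.config.in_channels} input "
                f"channels, got {c}"
            )
        if h % DOWNSAMPLE_FACTOR or w % DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by "
                f"{DOWNSAMPLE_FACTOR} (four 2x pooling stages)"
            )
        from .autodiff import maxpool2x2

        skips = []
        feat = x
        for block in self.enc[:4]:
            feat = block(feat, training=training, rng=rng)
            skips.append(feat)
            feat = maxpool2x2(feat)
        feat = self.enc[4](feat, training=training, rng=rng)
        feat = self.aspp(feat)

        for i in range(4):
            g = self.upconvs[i](feat)
            skip = skips[3 - i]
            gated = skip if bypass_gates else self.gates[i](skip, g)
            merged = concat([gated, g], axis=1)
            if i < 3:
                feat = self.dec[i](merged, training=training, rng=rng)
            else:
                feat = self.out_conv(merged)
        return feat

    def open_all_gates(self) -> None:
        """Saturate every attention gate fully open (coefficients = 1)."""
        for gate in self.gates:
            gate.saturate_open()


def build_masunet(config: MASUNetConfig | None = None, seed: int = 0) -> MASUNet:
    """Build a network with deterministic Kaiming-uniform initialization."""
    return MASUNet(config or MASUNetConfig(), seed=seed)


def predict_masks(net: MASUNet, x, threshold: float = 0.5):
    """Per-class binary masks and a single resolved label map.

    Returns ``(masks, labels)``: ``masks`` is (num_classes, H, W) boolean
    with mask_c = sigmoid(logit_c) > threshold (classes may overlap);
    ``labels`` assigns each pixel its highest-probability above-threshold
    class code (1 = PZ, 2 = TZ, 0 = background).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    logits = net.forward(x, training=False).numpy()
    if logits.ndim == 4:
        if logits.shape[0] != 1:
            raise ValueError("predict_masks handles one slice at a time")
        logits = logits[0]
    probs = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    masks = probs > threshold
    # overlap resolution: among above-threshold classes, keep the most probable
    eligible = np.where(masks, probs, -np.inf)
    best = eligible.argmax(axis=0)
    labels = np.where(masks.any(axis=0), best + 1, 0).astype(np.int16)
    return masks, labels


# ----------------------------------------------------------------------
# checkpointing: one .npz parameter archive + a JSON config sidecar
# ----------------------------------------------------------------------

def _flat_params(net: MASUNet) -> dict[str, np.ndarray]:
    return {f"p{i}": p.data for i, p in enumerate(net.parameters())}


def save_checkpoint(net: MASUNet, path: str | Path, seed: int = 0,
                    extra: dict | None = None) -> None:
    """Write ``path``.npz (weights) and ``path``.json (config + seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **_flat_params(net))
    meta = {"config": asdict(net.config), "seed": seed}
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> tuple[MASUNet, dict]:
    """Rebuild the network from a checkpoint; validates the config sidecar."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(meta["config"])
    cfg_dict["aspp_rates"] = tuple(cfg_dict["aspp_rates"])
    config = MASUNetConfig(**cfg_dict)
    net = MASUNet(config, seed=meta.get("seed", 0))
    with np.load(path.with_suffix(".npz")) as archive:
        params = net.parameters()
        if len(archive.files) != len(params):
            raise ValueError(
                f"checkpoint holds {len(archive.files)} arrays but the "
                f"config implies {len(params)} parameters"
            )
        for i, p in enumerate(params):
            stored = archive[f"p{i}"]
            if stored.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint parameter {i} has shape {stored.shape}, "
                    f"expected {p.data.shape}"
                )
            p.data = stored.astype(p.data.dtype)
    return net, meta
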