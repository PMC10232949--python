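"""Losses and evaluation metrics for zonal segmentation.

Training loss is the equally weighted sum of per-channel binary
cross-entropy on sigmoid(logits) and a smoothed soft dice loss
(1 − mean_c (2·Σpt + s)/(Σp + Σt + s)). Evaluation uses the standard
overlap metrics on binary masks:

    dice = 2|P ∩ T| / (|P| + |T|)
    PPV  = |P ∩ T| / |P|          (precision)
    sensitivity = |P ∩ T| / |T|   (recall)

The pixel-softmax field and weighted cross-entropy of the classic U-Net
energy are provided as reference operations; the training loss here is
the per-channel BCE-dice compound, so the weight map defaults to 1 and
is unused by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = [
    "softmax_field", "weighted_cross_entropy",
    "soft_dice_loss", "bce_dice_loss",
    "dice_coefficient", "ppv", "sensitivity",
    "MetricsReport", "evaluate_volume",
]

_LOG_FLOOR = 1e-12


# ----------------------------------------------------------------------
# pixel softmax + weighted cross-entropy (reference energy)
# ----------------------------------------------------------------------

def softmax_field(activations: np.ndarray) -> np.ndarray:
    """Numerically stable per-pixel softmax over the leading class axis.

    ``activations``: (K, ...) finite reals. Returns probabilities of the
    same shape summing to 1 over the class axis at every pixel.
    """
    a = np.asarray(activations, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("softmax_field requires finite activations")
    shifted = a - a.max(axis=0, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=0, keepdims=True)


def weighted_cross_entropy(probabilities: np.ndarray, labels: np.ndarray,
                           weights: np.ndarray | None = None) -> float:
    """E = −Σ_x w(x)·log p_{l(x)}(x) over the pixel lattice.

    ``probabilities``: (K, ...) softmax field; ``labels``: integer truth
    in {1..K} per pixel; ``weights``: nonnegative per-pixel map
    (default 1 everywhere). Probabilities at the true label are floored
    at 1e-12 so the energy is never infinite.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    l = np.asarray(labels)
    k = p.shape[0]
    if l.shape != p.shape[1:]:
        raise ValueError(
            f"label shape {l.shape} does not match pixel lattice {p.shape[1:]}")
    if l.min() < 1 or l.max() > k:
        raise ValueError(f"labels must lie in 1..{k}, got range "
                         f"[{l.min()}, {l.max()}]")
    if weights is None:
        w = np.ones_like(l, dtype=np.float64)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if np.any(w < 0):
            raise ValueError("weight map must be nonnegative")
    p_true = np.take_along_axis(p, (l - 1)[None], axis=0)[0]
    return float(-(w * np.log(np.maximum(p_true, _LOG_FLOOR))).sum())


# ----------------------------------------------------------------------
# training losses (accept ndarray for evaluation or Tensor for training)
# ----------------------------------------------------------------------

def soft_dice_loss(probabilities, targets, smooth: float = 1.0):
    """1 − mean over classes of the smoothed soft dice coefficient.

    Class axis is axis 0 for 3-D input (C, H, W) or axis 1 for batched
    (N, C, H, W); sums pool over everything but the class axis. Returns
    a float for ndarray input or a scalar Tensor on the graph for
    Tensor input.
    """
    if isinstance(probabilities, Tensor):
        t = targets if isinstance(targets, Tensor) else Tensor(np.asarray(targets))
        if probabilities.shape != t.shape:
            raise ValueError(
                f"shape mismatch: {probabilities.shape} vs {t.shape}")
        axes = (0, 2, 3) if probabilities.ndim == 4 else tuple(
            i for i in range(probabilities.ndim) if i != 0)
        inter = (probabilities * t).sum(axis=axes)
        denom = probabilities.sum(axis=axes) + t.sum(axis=axes)
        dice = (2.0 * inter + smooth) / (denom + smooth)
        return 1.0 - dice.mean()

    p = np.asarray(probabilities, dtype=np.float64)
    tg = np.asarray(targets, dtype=np.float64)
    if p.shape != tg.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {tg.shape}")
    axes = (0, 2, 3) if p.ndim == 4 else tuple(range(1, p.ndim))
    class_axis = 1 if p.ndim == 4 else 0
    inter = (p * tg).sum(axis=axes)
    denom = p.sum(axis=axes) + tg.sum(axis=axes)
    dice = (2.0 * inter + smooth) / (denom + smooth)
    return float(1.0 - dice.mean())


def bce_dice_loss(logits, targets, smooth: float = 1.0,
                  bce_weight: float = 1.0, dice_weight: float = 1.0):
    """Mean binary cross-entropy on sigmoid(logits) plus soft dice loss.

    The BCE term uses the numerically stable log-sum-exp form
    max(z,0) − z·t + log(1 + exp(−|z|)) averaged over all entries.
    """
    if isinstance(logits, Tensor):
        t = targets if isinstance(targets, Tensor) else Tensor(
            np.asarray(targets, dtype=logits.dtype))
        if logits.shape != t.shape:
            raise ValueError(f"shape mismatch: {logits.shape} vs {t.shape}")
        absz = logits.relu() + (-logits).relu()
        bce = (logits.relu() - logits * t + ((-absz).exp() + 1.0).log()).mean()
        dice = soft_dice_loss(logits.sigmoid(), t, smooth=smooth)
        return bce * bce_weight + dice * dice_weight

    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if z.shape != t.shape:
        raise ValueError(f"shape mismatch: {z.shape} vs {t.shape}")
    bce = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    dice = soft_dice_loss(1.0 / (1.0 + np.exp(-z)), t, smooth=smooth)
    return bce_weight * bce + dice_weight * dice


# ----------------------------------------------------------------------
# binary overlap metrics
# ----------------------------------------------------------------------

def _as_binary(mask, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} mask must be binary, found values {vals}")
        m = m.astype(bool)
    return m


def _counts(pred, true) -> tuple[int, int, int]:
    p = _as_binary(pred, "pred")
    t = _as_binary(true, "true")
    if p.shape != t.shape:
        raise ValueError(f"mask shape mismatch: {p.shape} vs {t.shape}")
    return int(np.logical_and(p, t).sum()), int(p.sum()), int(t.sum())


def dice_coefficient(pred, true) -> float:
    """2|P ∩ T| / (|P| + |T|); defined as 1.0 when both masks are empty."""
    inter, np_, nt = _counts(pred, true)
    if np_ + nt == 0:
        return 1.0
    return 2.0 * inter / (np_ + nt)


def ppv(pred, true) -> float:
    """|P ∩ T| / |P|; empty prediction scores 1.0 iff the truth is empty too."""
    inter, np_, nt = _counts(pred, true)
    if np_ == 0:
        return 1.0 if nt == 0 else 0.0
    return inter / np_


def sensitivity(pred, true) -> float:
    """|P ∩ T| / |T|; empty truth scores 1.0 iff the prediction is empty too."""
    inter, np_, nt = _counts(pred, true)
    if nt == 0:
        return 1.0 if np_ == 0 else 0.0
    return inter / nt


# ----------------------------------------------------------------------
# per-volume aggregation
# ----------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-class overlap metrics for one volume, pooled over its slices."""

    volume_id: str
    class_names: tuple[str, ...]
    dice: dict[str, float] = field(default_factory=dict)
    ppv: dict[str, float] = field(default_factory=dict)
    sensitivity: dict[str, float] = field(default_factory=dict)
    counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def as_rows(self) -> list[dict]:
        return [
            {"volume_id": self.volume_id, "class": c,
             "dice": self.dice[c], "ppv": self.ppv[c],
             "sensitivity": self.sensitivity[c]}
            for c in self.class_names
        ]


def evaluate_volume(pred_masks, true_masks,
                    class_names: tuple[str, ...] = ("PZ", "TZ"),
                    volume_id: str = "volume") -> MetricsReport:
    """Pool pixel counts over all slices of one volume, then score once.

    ``pred_masks``/``true_masks``: (num_classes, slices, H, W) binary
    arrays (a single slice (num_classes, H, W) is promoted to one-slice
    volumes).
    """
    p = np.asarray(pred_masks)
    t = np.asarray(true_masks)
    if p.ndim == 3:
        p = p[:, None]
    if t.ndim == 3:
        t = t[:, None]
    if p.shape != t.shape:
        raise ValueError(
            f"prediction/truth volume shapes differ: {p.shape} vs {t.shape}")
    if p.shape[0] != len(class_names):
        raise ValueError(
            f"{p.shape[0]} mask channels but {len(class_names)} class names")
    report = MetricsReport(volume_id=volume_id, class_names=tuple(class_names))
    for c, name in enumerate(class_names):
        inter, np_, nt = _counts(p[c], t[c])
        report.counts[name] = (inter, np_, nt)
        report.dice[name] = 1.0 if np_ + nt == 0 else 2.0 * inter / (np_ + nt)
        report.ppv[name] = (1.0 if nt == 0 else 0.0) if np_ == 0 else inter / np_
        report.sensitivity[name] = (1.0 if np_ == 0 else 0.0) if nt == 0 else inter / nt
    return report
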