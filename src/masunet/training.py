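"""Training loop, early stopping, checkpointing, evaluation, prediction.

The default recipe: BCE-dice loss, Adam (lr 3e-4, β1 0.9, β2 0.999,
weight decay 1e-4 applied as L2 on gradients), batch size 4, up to 1000
epochs with early stopping at 20 epochs without improvement of the
validation mean dice (mean of PZ and TZ). The best-scoring weights are
retained and restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .data import (CLASS_NAMES, DatasetSplit, SliceSample, VolumeRecord,
                   preprocess_volume, _resize_label)
from .losses import bce_dice_loss, evaluate_volume, MetricsReport
from .network import MASUNet, predict_masks

__all__ = ["TrainConfig", "TrainState", "Adam", "SGD", "train_model",
           "early_stopping_check", "evaluate_model", "predict_volume",
           "EvaluationResult"]


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults are the published recipe)."""

    loss: str = "bce_dice"
    max_epochs: int = 1000
    patience: int = 20
    batch_size: int = 4
    optimizer: str = "adam"          # "adam" (momentum row read as beta1) or "sgd"
    learning_rate: float = 0.0003
    momentum: float = 0.9
    weight_decay: float = 0.0001
    seed: int = 0
    monitor: str = "dice"            # "dice" or "loss"
    threshold: float = 0.5
    improvement_tol: float = 1e-6


@dataclass
class TrainState:
    """Mutable loop state and per-epoch history."""

    epoch: int = 0
    best_score: float = -np.inf
    best_epoch: int = 0
    epochs_since_improvement: int = 0
    history: list[dict] = field(default_factory=list)
    stop_reason: str = ""

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.eps, self.weight_decay = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGD:
    """SGD with classical momentum (alternative reading of the recipe)."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.buf = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.buf[i] = self.momentum * self.buf[i] + g
            p.data -= self.lr * self.buf[i]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def make_optimizer(net: MASUNet, cfg: TrainConfig):
    if cfg.optimizer == "adam":
        return Adam(net.parameters(), lr=cfg.learning_rate,
                    beta1=cfg.momentum, weight_decay=cfg.weight_decay)
    if cfg.optimizer == "sgd":
        return SGD(net.parameters(), lr=cfg.learning_rate,
                   momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    raise ValueError(f"unknown optimizer {cfg.optimizer!r}")


# ----------------------------------------------------------------------
# loop pieces
# ----------------------------------------------------------------------

def _batch_arrays(samples: list[SliceSample], idx) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([samples[i].image for i in idx]).astype(np.float32)
    tgts = np.stack([samples[i].target for i in idx]).astype(np.float32)
    return imgs, tgts


def train_step(net: MASUNet, optimizer, images: np.ndarray,
               targets: np.ndarray, rng: np.random.Generator) -> float:
    """One optimizer step on a mini-batch; returns the scalar loss."""
    optimizer.zero_grad()
    logits = net.forward(Tensor(images), training=True, rng=rng)
    loss = bce_dice_loss(logits, Tensor(targets))
    loss.backward()
    optimizer.step()
    return loss.item()


def _validate(net: MASUNet, samples: list[SliceSample],
              threshold: float) -> tuple[float, dict[str, float]]:
    """Validation loss and per-class dice pooled over all slices."""
    total_loss = 0.0
    inter = np.zeros(2)
    psum = np.zeros(2)
    tsum = np.zeros(2)
    for s in samples:
        logits = net.forward(Tensor(s.image[None]), training=False)
        total_loss += bce_dice_loss(logits.numpy()[0], s.target.astype(np.float64))
        probs = 1.0 / (1.0 + np.exp(-logits.numpy()[0].astype(np.float64)))
        pred = probs > threshold
        for c in range(2):
            inter[c] += np.logical_and(pred[c], s.target[c] > 0).sum()
            psum[c] += pred[c].sum()
            tsum[c] += s.target[c].sum()
    dice = {}
    for c, name in enumerate(CLASS_NAMES):
        denom = psum[c] + tsum[c]
        dice[name] = 1.0 if denom == 0 else 2.0 * inter[c] / denom
    return total_loss / max(len(samples), 1), dice


def early_stopping_check(state: TrainState, patience: int) -> bool:
    """True when training should stop (no improvement for ``patience`` epochs)."""
    if not state.history:
        raise ValueError("early stopping needs a nonempty history")
    return state.epochs_since_improvement >= patience


def _snapshot(net: MASUNet) -> list[np.ndarray]:
    return [p.data.copy() for p in net.parameters()]


def _restore(net: MASUNet, snap: list[np.ndarray]) -> None:
    for p, d in zip(net.parameters(), snap):
        p.data = d.copy()


def train_model(net: MASUNet, split: DatasetSplit, cfg: TrainConfig,
                max_steps: int | None = None,
                verbose: bool = False) -> tuple[MASUNet, TrainState]:
    """Train ``net`` on the split's slice samples with the given recipe.

    ``max_steps`` caps the total number of optimizer steps (useful for
    short runs); the best-validation weights are restored before return.
    """
    if not split.train_samples:
        raise ValueError("training set is empty")
    if not split.val_samples:
        raise ValueError("validation set is empty")
    rng = np.random.default_rng(cfg.seed)
    optimizer = make_optimizer(net, cfg)
    state = TrainState()
    best = _snapshot(net)
    steps = 0

    for epoch in range(1, cfg.max_epochs + 1):
        state.epoch = epoch
        order = rng.permutation(len(split.train_samples))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            images, targets = _batch_arrays(split.train_samples, idx)
            loss = train_step(net, optimizer, images, targets, rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, step {steps}; "
                    f"batch volumes "
                    f"{[split.train_samples[i].volume_id for i in idx]}")
            losses.append(loss)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break

        val_loss, val_dice = _validate(net, split.val_samples, cfg.threshold)
        mean_dice = float(np.mean(list(val_dice.values())))
        score = mean_dice if cfg.monitor == "dice" else -val_loss
        state.history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(losses)) if losses else np.nan,
            "val_loss": val_loss,
            "val_dice_PZ": val_dice["PZ"],
            "val_dice_TZ": val_dice["TZ"],
            "val_mean_dice": mean_dice,
        })
        if verbose:
            print(f"epoch {epoch:4d}  train {state.history[-1]['train_loss']:.4f}"
                  f"  val {val_loss:.4f}  dice PZ {val_dice['PZ']:.4f}"
                  f"  TZ {val_dice['TZ']:.4f}")

        if score > state.best_score + cfg.improvement_tol:
            state.best_score = score
            state.best_epoch = epoch
            state.epochs_since_improvement = 0
            best = _snapshot(net)
        else:
            state.epochs_since_improvement += 1

        if max_steps is not None and steps >= max_steps:
            state.stop_reason = f"reached max_steps={max_steps}"
            break
        if early_stopping_check(state, cfg.patience):
            state.stop_reason = (
                f"no improvement for {cfg.patience} epochs "
                f"(best at epoch {state.best_epoch})")
            break
    else:
        state.stop_reason = f"reached max_epochs={cfg.max_epochs}"

    _restore(net, best)
    return net, state


# ----------------------------------------------------------------------
# evaluation / prediction harness
# ----------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Per-volume reports plus dataset means."""

    reports: list[MetricsReport]
    table: pd.DataFrame
    means: dict[str, dict[str, float]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def evaluate_model(net: MASUNet, volumes: list[VolumeRecord],
                   target_size: tuple[int, int] = (256, 256),
                   threshold: float = 0.5,
                   aggregation: str = "volume") -> EvaluationResult:
    """Predict every slice, pool per volume, report per-class metrics.

    ``aggregation``: "volume" (pool counts per volume then average over
    volumes, the default), "slice" (average slice-level metrics), or
    "global" (pool counts over the whole dataset).
    """
    if aggregation not in ("volume", "slice", "global"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    reports = []
    rows = []
    global_pred, global_true = [], []
    for vol in volumes:
        if not vol.labeled:
            raise ValueError(f"volume {vol.volume_id} has no labels")
        samples = preprocess_volume(vol, target_size)
        preds = []
        trues = []
        for s in samples:
            masks, _ = predict_masks(net, s.image[None], threshold)
            preds.append(masks)
            trues.append(s.target > 0)
        pred_vol = np.stack(preds, axis=1)   # (C, S, H, W)
        true_vol = np.stack(trues, axis=1)
        if aggregation == "slice":
            per_slice = [evaluate_volume(p, t, CLASS_NAMES, vol.volume_id)
                         for p, t in zip(preds, trues)]
            rep = MetricsReport(volume_id=vol.volume_id,
                                class_names=CLASS_NAMES)
            for name in CLASS_NAMES:
                rep.dice[name] = float(np.mean([r.dice[name] for r in per_slice]))
                rep.ppv[name] = float(np.mean([r.ppv[name] for r in per_slice]))
                rep.sensitivity[name] = float(
                    np.mean([r.sensitivity[name] for r in per_slice]))
        else:
            rep = evaluate_volume(pred_vol, true_vol, CLASS_NAMES,
                                  vol.volume_id)
        reports.append(rep)
        rows.extend(rep.as_rows())
        global_pred.append(pred_vol.reshape(2, -1))
        global_true.append(true_vol.reshape(2, -1))

    table = pd.DataFrame(rows)
    if aggregation == "global":
        pooled = evaluate_volume(
            np.concatenate(global_pred, axis=1)[:, :, None],
            np.concatenate(global_true, axis=1)[:, :, None],
            CLASS_NAMES, "pooled")
        means = {name: {"dice": pooled.dice[name], "ppv": pooled.ppv[name],
                        "sensitivity": pooled.sensitivity[name]}
                 for name in CLASS_NAMES}
    else:
        means = {
            name: {
                "dice": float(table[table["class"] == name]["dice"].mean()),
                "ppv": float(table[table["class"] == name]["ppv"].mean()),
                "sensitivity": float(
                    table[table["class"] == name]["sensitivity"].mean()),
            }
            for name in CLASS_NAMES
        }
    return EvaluationResult(reports=reports, table=table, means=means)


def predict_volume(net: MASUNet, volume: VolumeRecord,
                   target_size: tuple[int, int] = (256, 256),
                   threshold: float = 0.5,
                   overlay_dir=None) -> np.ndarray:
    """Segment a volume; returns a (slice, row, col) label volume.

    Slices are resized to ``target_size`` for the network and the
    predicted labels are nearest-resized back to the input grid, so the
    output aligns with the input volume. ``overlay_dir`` optionally
    receives one PNG per slice (green PZ, red TZ).
    """
    from .data import save_overlay
    from pathlib import Path

    samples = preprocess_volume(volume, target_size)
    n_slices = volume.image.shape[1]
    h0, w0 = volume.image.shape[2], volume.image.shape[3]
    out = np.zeros((n_slices, h0, w0), dtype=np.int16)
    for s, sample in enumerate(samples):
        _, labels = predict_masks(net, sample.image[None], threshold)
        out[s] = _resize_label(labels, (h0, w0))
    if overlay_dir is not None:
        overlay_dir = Path(overlay_dir)
        overlay_dir.mkdir(parents=True, exist_ok=True)
        for s in range(n_slices):
            save_overlay(volume.image[0, s], out[s],
                         overlay_dir / f"{volume.volume_id}_slice{s:03d}.png")
    return out
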