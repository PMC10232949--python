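"""Model/Results front end for zonal segmentation.

``ZonalSegmentationModel`` bundles the data pipeline, the network and
the training recipe behind a fit interface: build the model from a list
of volumes (or a dataset directory), call :meth:`fit`, and receive a
``SegmentationResults`` carrying the trained network, the per-epoch
history, the validation metrics and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .data import (AugmentationConfig, DatasetSplit, VolumeRecord,
                   load_phantom_dataset, prepare_split)
from .network import MASUNet, MASUNetConfig, build_masunet, save_checkpoint
from .training import (EvaluationResult, TrainConfig, TrainState,
                       evaluate_model, train_model)

__all__ = ["ZonalSegmentationModel", "SegmentationResults"]


class ZonalSegmentationModel:
    """Prostate TZ/PZ segmentation model fitted to a volume dataset.

    Parameters
    ----------
    volumes : list of VolumeRecord
        Labeled (and possibly unlabeled) subject volumes.
    net_config, train_config : optional
        Architecture and recipe; defaults are the published settings
        (base width 64, BCE-dice + Adam at 3e-4).
    target_size : (H, W)
        Uniform slice size, divisible by 16.
    augmentation : AugmentationConfig or None
        Offline training-set augmentation; default triples the set.
    split_fraction, split_seed
        Volume-level train/validation partition.
    """

    def __init__(self, volumes: list[VolumeRecord],
                 net_config: MASUNetConfig | None = None,
                 train_config: TrainConfig | None = None,
                 target_size: tuple[int, int] = (256, 256),
                 augmentation: AugmentationConfig | None = AugmentationConfig(),
                 split_fraction: float = 0.8,
                 split_seed: int = 0,
                 build_seed: int = 0):
        self.volumes = volumes
        self.net_config = net_config or MASUNetConfig()
        self.train_config = train_config or TrainConfig()
        self.target_size = target_size
        self.augmentation = augmentation
        self.split_fraction = split_fraction
        self.split_seed = split_seed
        self.build_seed = build_seed
        self.split: DatasetSplit | None = None

    @classmethod
    def from_directory(cls, data_dir: str | Path, **kwargs
                       ) -> "ZonalSegmentationModel":
        """Build from an MSD-style directory with a ``dataset.json``."""
        return cls(load_phantom_dataset(data_dir), **kwargs)

    # ------------------------------------------------------------------
    def fit(self, max_steps: int | None = None,
            verbose: bool = False) -> "SegmentationResults":
        """Prepare the split, train the network, evaluate on validation."""
        self.split = prepare_split(
            self.volumes, fraction=self.split_fraction,
            split_seed=self.split_seed, target_size=self.target_size,
            augmentation=self.augmentation)
        net = build_masunet(self.net_config, seed=self.build_seed)
        net, state = train_model(net, self.split, self.train_config,
                                 max_steps=max_steps, verbose=verbose)
        evaluation = evaluate_model(net, self.split.val_volumes,
                                    target_size=self.target_size,
                                    threshold=self.train_config.threshold)
        return SegmentationResults(model=self, network=net, state=state,
                                   evaluation=evaluation)


@dataclass
class SegmentationResults:
    """Fit artifacts: trained network, history, validation metrics."""

    model: ZonalSegmentationModel
    network: MASUNet
    state: TrainState
    evaluation: EvaluationResult

    @property
    def history(self) -> pd.DataFrame:
        return self.state.history_frame()

    @property
    def val_dice(self) -> dict[str, float]:
        return {name: self.evaluation.means[name]["dice"]
                for name in self.evaluation.means}

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.network, path, seed=self.model.build_seed,
                        extra={"best_epoch": self.state.best_epoch,
                               "best_score": self.state.best_score})

    def summary(self) -> str:
        """Human-readable fit report."""
        cfg = self.model.net_config
        tc = self.model.train_config
        lines = [
            "Zonal Segmentation Model Results",
            "=" * 64,
            f"{'Network:':<28}attention-gated U-Net + ASPP (GN)",
            f"{'Base width / classes:':<28}{cfg.base_channels} / {cfg.num_classes}",
            f"{'Parameters:':<28}{self.network.num_parameters():,}",
            f"{'Loss / optimizer:':<28}{tc.loss} / {tc.optimizer} "
            f"(lr {tc.learning_rate:g})",
            f"{'Epochs run (best):':<28}{self.state.epoch} "
            f"({self.state.best_epoch})",
            f"{'Stop reason:':<28}{self.state.stop_reason or 'n/a'}",
            "-" * 64,
            f"{'class':<8}{'dice':>10}{'PPV':>10}{'sensitivity':>14}",
        ]
        for name, m in self.evaluation.means.items():
            lines.append(f"{name:<8}{m['dice']:>10.4f}{m['ppv']:>10.4f}"
                         f"{m['sensitivity']:>14.4f}")
        lines.append("=" * 64)
        return "\n".join(lines)
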