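"""Volume I/O, preprocessing, offline augmentation, splitting, phantoms.

Volumes follow the MSD Task05 prostate layout: NIfTI images with an
optional trailing modality axis (channel 0 T2-weighted, channel 1 ADC)
and integer label volumes coding 0 = background, 1 = peripheral zone
(PZ), 2 = transition zone (TZ). In memory a volume is canonicalized to
(modality, slice, row, col) with the label as (slice, row, col).

The synthetic phantom generator replaces the real dataset in tests and
examples: each volume is a noisy background holding a bright elliptical
TZ core nested inside a PZ annulus of intermediate intensity, with
geometry jittered per slice to mimic through-plane variation, written in
the same NIfTI + ``dataset.json`` layout.

Training data is prepared as in the source protocol: per-volume z-score
normalization, resize to a uniform slice size divisible by 16, per-slice
extraction, offline augmentation of the training set to three times its
size (original + 2 augmented copies: flips, rotation, Gaussian noise,
brightness/contrast), and an 80/20 split by volume so no patient leaks
between sets. Validation keeps only original images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy import ndimage as ndi
from skimage.transform import resize as _sk_resize

__all__ = [
    "VolumeRecord", "SliceSample", "AugmentationConfig", "PhantomConfig",
    "DatasetSplit", "load_msd_volume", "preprocess_volume",
    "augment_offline", "split_dataset", "prepare_split",
    "generate_phantom_dataset", "load_phantom_dataset", "save_overlay",
]

LABEL_CODES = {0: "background", 1: "PZ", 2: "TZ"}
CLASS_NAMES = ("PZ", "TZ")


# ----------------------------------------------------------------------
# records
# ----------------------------------------------------------------------

@dataclass
class VolumeRecord:
    """One subject: image volume, optional label volume, voxel spacing."""

    volume_id: str
    image: np.ndarray                       # (modality, slice, row, col)
    label: np.ndarray | None = None         # (slice, row, col) int
    spacing: tuple[float, float, float] = (0.6, 0.6, 4.0)

    @property
    def labeled(self) -> bool:
        return self.label is not None

    def __post_init__(self):
        if self.image.ndim != 4:
            raise ValueError(
                f"image volume must be (modality, slice, row, col), "
                f"got {self.image.ndim} axes")
        if self.label is not None:
            if self.label.shape != self.image.shape[1:]:
                raise ValueError(
                    f"label shape {self.label.shape} does not match image "
                    f"spatial shape {self.image.shape[1:]}")
            bad = sorted(set(np.unique(self.label)) - set(LABEL_CODES))
            if bad:
                raise ValueError(
                    f"unknown label codes {bad}; expected subset of "
                    f"{sorted(LABEL_CODES)}")


@dataclass
class SliceSample:
    """One 2-D training unit: normalized image and per-class masks."""

    image: np.ndarray        # (channels, H, W) float32
    target: np.ndarray       # (2, H, W) uint8, disjoint PZ/TZ masks
    volume_id: str
    slice_index: int
    augmentation: str = "original"


@dataclass(frozen=True)
class AugmentationConfig:
    """Offline augmentation recipe: 1 original + ``copies_per_image`` variants.

    Each variant applies a random subset of the enabled transforms;
    geometric transforms hit image and masks identically (nearest
    interpolation for masks), intensity transforms hit the image only.
    """

    copies_per_image: int = 2
    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_degrees: float = 15.0
    noise_sigma_range: tuple[float, float] = (0.01, 0.05)
    brightness_range: tuple[float, float] = (0.8, 1.2)
    contrast_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0


@dataclass(frozen=True)
class PhantomConfig:
    """Synthetic prostate phantom recipe (stand-in for the MSD volumes).

    Intensities are means of the Gaussian-noised regions; radii are
    fractions of the slice size. The TZ core is strictly nested inside
    the PZ outer ellipse by construction.
    """

    num_volumes: int = 10
    slices_per_volume: int = 15
    slice_size: int = 64
    num_modalities: int = 1
    pz_radius_range: tuple[float, float] = (0.24, 0.34)
    tz_fraction_range: tuple[float, float] = (0.45, 0.62)  # of PZ radius
    background_mean: float = 0.2
    pz_mean: float = 0.5
    tz_mean: float = 0.8
    noise_sigma: float = 0.05
    labeled_fraction: float = 1.0
    seed: int = 0


@dataclass
class DatasetSplit:
    """Volume-level 80/20 partition plus materialized slice samples."""

    train_volumes: list[VolumeRecord]
    val_volumes: list[VolumeRecord]
    train_samples: list[SliceSample] = field(default_factory=list)
    val_samples: list[SliceSample] = field(default_factory=list)

    @property
    def train_ids(self) -> set[str]:
        return {v.volume_id for v in self.train_volumes}

    @property
    def val_ids(self) -> set[str]:
        return {v.volume_id for v in self.val_volumes}


# ----------------------------------------------------------------------
# NIfTI I/O
# ----------------------------------------------------------------------

def load_msd_volume(image_path: str | Path,
                    label_path: str | Path | None = None,
                    code_map: dict[int, int] | None = None) -> VolumeRecord:
    """Load an MSD-style NIfTI image (and optional label) volume.

    The on-disk image is (row, col, slice) or (row, col, slice, modality);
    axes are canonicalized to (modality, slice, row, col). ``code_map``
    optionally remaps on-disk label integers to the {0, 1 PZ, 2 TZ}
    convention before validation.
    """
    image_path = Path(image_path)
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(
            f"{image_path.name}: expected 3-D or 4-D image, got {data.ndim}-D")
    # (R, C, S, M) -> (M, S, R, C)
    image = np.ascontiguousarray(data.transpose(3, 2, 0, 1))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])

    label = None
    if label_path is not None:
        lab = np.asarray(nib.load(str(label_path)).dataobj)
        lab = np.rint(lab).astype(np.int16)
        if lab.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got {lab.ndim}-D")
        lab = np.ascontiguousarray(lab.transpose(2, 0, 1))
        if code_map:
            remapped = np.zeros_like(lab)
            for src, dst in code_map.items():
                remapped[lab == src] = dst
            lab = remapped
        label = lab

    vid = image_path.name.replace(".nii.gz", "").replace(".nii", "")
    return VolumeRecord(volume_id=vid, image=image, label=label,
                        spacing=spacing)


def _nifti_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_volume(record: VolumeRecord, image_path: Path,
                label_path: Path | None = None) -> None:
    """Write a VolumeRecord back to MSD-style NIfTI files."""
    aff = _nifti_affine(record.spacing)
    # (M, S, R, C) -> (R, C, S, M); squeeze single modality to 3-D
    img = record.image.transpose(2, 3, 1, 0)
    if img.shape[-1] == 1:
        img = img[..., 0]
    nib.save(nib.Nifti1Image(img.astype(np.float32), aff), str(image_path))
    if label_path is not None and record.label is not None:
        lab = record.label.transpose(1, 2, 0).astype(np.int16)
        nib.save(nib.Nifti1Image(lab, aff), str(label_path))


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def _resize_image(slc: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    if slc.shape == target:
        return slc.astype(np.float32)
    return _sk_resize(slc, target, order=1, mode="reflect",
                      anti_aliasing=False, preserve_range=True).astype(np.float32)


def _resize_label(slc: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    if slc.shape == target:
        return slc
    return _sk_resize(slc, target, order=0, mode="edge",
                      anti_aliasing=False, preserve_range=True).astype(slc.dtype)


def preprocess_volume(volume: VolumeRecord,
                      target_size: tuple[int, int] = (256, 256),
                      modalities: tuple[int, ...] = (0,),
                      clip_sigma: float = 5.0) -> list[SliceSample]:
    """Uniform size, per-volume z-score normalization, per-slice extraction.

    Every axial slice is resized to ``target_size`` (bilinear image /
    nearest label), the selected modalities are normalized per volume to
    zero mean and unit variance (clipped at ±``clip_sigma``), and the
    label is expanded to disjoint binary PZ/TZ masks.
    """
    h, w = target_size
    if h % 16 or w % 16:
        raise ValueError(
            f"target size {target_size} must be divisible by 16")
    if volume.image.shape[1] == 0:
        raise ValueError(f"volume {volume.volume_id} has no slices")

    n_slices = volume.image.shape[1]
    stacks = []
    for m in modalities:
        resized = np.stack([
            _resize_image(volume.image[m, s], (h, w)) for s in range(n_slices)
        ])
        mu, sd = float(resized.mean()), float(resized.std())
        sd = sd if sd > 1e-8 else 1.0
        stacks.append(np.clip((resized - mu) / sd, -clip_sigma, clip_sigma))
    image_stack = np.stack(stacks, axis=0)  # (C, S, H, W)

    labels = None
    if volume.labeled:
        labels = np.stack([
            _resize_label(volume.label[s], (h, w)) for s in range(n_slices)
        ])

    samples = []
    for s in range(n_slices):
        if labels is not None:
            target = np.stack([(labels[s] == 1), (labels[s] == 2)]).astype(np.uint8)
        else:
            target = np.zeros((2, h, w), dtype=np.uint8)
        samples.append(SliceSample(
            image=image_stack[:, s].astype(np.float32),
            target=target,
            volume_id=volume.volume_id,
            slice_index=s,
        ))
    return samples


# ----------------------------------------------------------------------
# offline augmentation
# ----------------------------------------------------------------------

def _augment_once(sample: SliceSample, cfg: AugmentationConfig,
                  rng: np.random.Generator, tag: str) -> SliceSample:
    img = sample.image.copy()
    tgt = sample.target.copy()
    applied = []

    choices = []
    if cfg.horizontal_flip:
        choices.append("hflip")
    if cfg.vertical_flip:
        choices.append("vflip")
    if cfg.rotation_degrees > 0:
        choices.append("rotate")
    if cfg.noise_sigma_range[1] > 0:
        choices.append("noise")
    choices.append("brightness_contrast")

    mask = rng.random(len(choices)) < 0.5
    if not mask.any():
        mask[rng.integers(len(choices))] = True
    active = [c for c, m in zip(choices, mask) if m]

    if "hflip" in active:
        img = img[..., ::-1].copy()
        tgt = tgt[..., ::-1].copy()
        applied.append("hflip")
    if "vflip" in active:
        img = img[:, ::-1].copy()
        tgt = tgt[:, ::-1].copy()
        applied.append("vflip")
    if "rotate" in active:
        angle = float(rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees))
        img = np.stack([
            ndi.rotate(ch, angle, reshape=False, order=1, mode="reflect")
            for ch in img
        ]).astype(np.float32)
        tgt = np.stack([
            ndi.rotate(ch, angle, reshape=False, order=0, mode="constant")
            for ch in tgt
        ]).astype(np.uint8)
        applied.append(f"rotate{angle:+.1f}")
    if "noise" in active:
        sigma = float(rng.uniform(*cfg.noise_sigma_range)) * max(
            float(img.std()), 1e-6)
        img = (img + rng.normal(0.0, sigma, img.shape)).astype(np.float32)
        applied.append("noise")
    if "brightness_contrast" in active:
        b = float(rng.uniform(*cfg.brightness_range))
        c = float(rng.uniform(*cfg.contrast_range))
        mean = img.mean()
        img = ((img - mean) * c + mean * b).astype(np.float32)
        applied.append("bc")

    return SliceSample(image=img, target=tgt, volume_id=sample.volume_id,
                       slice_index=sample.slice_index,
                       augmentation=f"{tag}:" + "+".join(applied))


def augment_offline(samples: list[SliceSample],
                    cfg: AugmentationConfig) -> list[SliceSample]:
    """Expand ``samples`` to (1 + copies_per_image) times its size.

    Emits each original followed by its augmented variants; deterministic
    given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[SliceSample] = []
    for sample in samples:
        out.append(sample)
        for k in range(cfg.copies_per_image):
            out.append(_augment_once(sample, cfg, rng, tag=f"aug{k + 1}"))
    return out


# ----------------------------------------------------------------------
# splitting
# ----------------------------------------------------------------------

def split_dataset(volumes: list[VolumeRecord], fraction: float = 0.8,
                  seed: int = 0) -> DatasetSplit:
    """Partition labeled volumes by subject, never by slice.

    ``fraction`` of the labeled volumes (rounded, clamped so both sides
    are nonempty) go to training; unlabeled volumes are dropped.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    labeled = [v for v in volumes if v.labeled]
    if len(labeled) < 2:
        raise ValueError(
            f"need at least 2 labeled volumes to split, got {len(labeled)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labeled))
    n_train = int(round(fraction * len(labeled)))
    n_train = min(max(n_train, 1), len(labeled) - 1)
    train = [labeled[i] for i in order[:n_train]]
    val = [labeled[i] for i in order[n_train:]]
    return DatasetSplit(train_volumes=train, val_volumes=val)


def prepare_split(volumes: list[VolumeRecord], fraction: float = 0.8,
                  split_seed: int = 0,
                  target_size: tuple[int, int] = (256, 256),
                  augmentation: AugmentationConfig | None = None,
                  modalities: tuple[int, ...] = (0,)) -> DatasetSplit:
    """Split by volume and materialize slice samples.

    Training slices are augmented offline (3x by default); validation
    keeps only original slices.
    """
    split = split_dataset(volumes, fraction=fraction, seed=split_seed)
    for v in split.train_volumes:
        split.train_samples.extend(
            preprocess_volume(v, target_size, modalities))
    for v in split.val_volumes:
        split.val_samples.extend(
            preprocess_volume(v, target_size, modalities))
    if augmentation is not None:
        split.train_samples = augment_offline(split.train_samples, augmentation)
    return split


# ----------------------------------------------------------------------
# synthetic phantoms
# ----------------------------------------------------------------------

def _ellipse_mask(size: int, center: tuple[float, float],
                  radii: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    return ((rr - center[0]) / radii[0]) ** 2 + \
           ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def generate_phantom_dataset(cfg: PhantomConfig,
                             out_dir: str | Path | None = None
                             ) -> list[VolumeRecord]:
    """Generate synthetic prostate-like volumes (optionally written to disk).

    Each slice holds a bright TZ ellipse (label 2) nested in a PZ annulus
    (label 1) over a noisy background, with per-slice jitter of center
    and radii and a through-plane size profile shrinking toward the
    first/last slices. With ``out_dir`` set, volumes are written as
    NIfTI pairs under ``imagesTr``/``labelsTr`` plus a ``dataset.json``
    manifest.
    """
    rng = np.random.default_rng(cfg.seed)
    size = cfg.slice_size
    volumes: list[VolumeRecord] = []
    n_labeled = int(round(cfg.labeled_fraction * cfg.num_volumes))

    for v in range(cfg.num_volumes):
        center0 = size / 2 + rng.uniform(-0.08, 0.08, size=2) * size
        pz_r0 = rng.uniform(*cfg.pz_radius_range, size=2) * size
        tz_frac = rng.uniform(*cfg.tz_fraction_range)
        image = np.empty((cfg.num_modalities, cfg.slices_per_volume, size, size),
                         dtype=np.float32)
        label = np.zeros((cfg.slices_per_volume, size, size), dtype=np.int16)

        for s in range(cfg.slices_per_volume):
            # gland widest mid-volume, narrower at the poles
            u = (s + 0.5) / cfg.slices_per_volume
            profile = 0.6 + 0.4 * np.sin(np.pi * u)
            center = center0 + rng.uniform(-1.0, 1.0, size=2)
            pz_r = pz_r0 * profile * rng.uniform(0.95, 1.05, size=2)
            tz_r = pz_r * tz_frac * rng.uniform(0.95, 1.05, size=2)
            outer = _ellipse_mask(size, tuple(center), tuple(pz_r))
            core = _ellipse_mask(size, tuple(center), tuple(tz_r))
            label[s][outer & ~core] = 1
            label[s][core] = 2
            for m in range(cfg.num_modalities):
                base = np.full((size, size), cfg.background_mean, np.float32)
                base[outer & ~core] = cfg.pz_mean
                base[core] = cfg.tz_mean
                noise = rng.normal(0.0, cfg.noise_sigma, (size, size))
                image[m, s] = base + noise.astype(np.float32)

        volumes.append(VolumeRecord(
            volume_id=f"phantom_{v:03d}",
            image=image,
            label=label if v < n_labeled else None,
            spacing=(0.6, 0.6, 4.0),
        ))

    if out_dir is not None:
        _write_phantom_dir(volumes, Path(out_dir), cfg)
    return volumes


def _write_phantom_dir(volumes: list[VolumeRecord], out_dir: Path,
                       cfg: PhantomConfig) -> None:
    images_dir = out_dir / "imagesTr"
    labels_dir = out_dir / "labelsTr"
    images_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)
    training = []
    for rec in volumes:
        img_path = images_dir / f"{rec.volume_id}.nii.gz"
        lab_path = labels_dir / f"{rec.volume_id}.nii.gz" if rec.labeled else None
        save_volume(rec, img_path, lab_path)
        entry = {"image": f"./imagesTr/{rec.volume_id}.nii.gz"}
        if rec.labeled:
            entry["label"] = f"./labelsTr/{rec.volume_id}.nii.gz"
        training.append(entry)
    manifest = {
        "name": "SyntheticProstatePhantom",
        "description": "synthetic TZ/PZ phantom volumes (not real MRI)",
        "modality": {str(i): ("T2" if i == 0 else "ADC")
                     for i in range(cfg.num_modalities)},
        "labels": {str(k): v for k, v in LABEL_CODES.items()},
        "numTraining": len(training),
        "training": training,
        "phantom_config": asdict(cfg),
    }
    (out_dir / "dataset.json").write_text(json.dumps(manifest, indent=2))


def load_phantom_dataset(data_dir: str | Path) -> list[VolumeRecord]:
    """Load a dataset written by :func:`generate_phantom_dataset`."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "dataset.json").read_text())
    volumes = []
    for entry in manifest["training"]:
        image_path = data_dir / entry["image"]
        label_path = data_dir / entry["label"] if "label" in entry else None
        volumes.append(load_msd_volume(image_path, label_path))
    return volumes


# ----------------------------------------------------------------------
# overlay rendering (green PZ, red TZ)
# ----------------------------------------------------------------------

def save_overlay(image2d: np.ndarray, label2d: np.ndarray,
                 path: str | Path, alpha: float = 0.45) -> None:
    """Write a PNG of the slice with PZ tinted green and TZ tinted red."""
    import imageio.v3 as iio

    img = np.asarray(image2d, dtype=np.float64)
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.stack([gray, gray, gray], axis=-1)
    pz = np.asarray(label2d) == 1
    tz = np.asarray(label2d) == 2
    rgb[pz] = (1 - alpha) * rgb[pz] + alpha * np.array([0.0, 1.0, 0.0])
    rgb[tz] = (1 - alpha) * rgb[tz] + alpha * np.array([1.0, 0.0, 0.0])
    iio.imwrite(str(path), (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
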