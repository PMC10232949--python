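# masunet

Automatic zonal segmentation of the prostate on T2-weighted MRI.

Radiologists delineate the **transition zone (TZ)** and **peripheral
zone (PZ)** of the prostate slice by slice; the PZ is where most
prostate cancers arise, and manual contouring is slow and
operator-dependent. `masunet` implements an attention-gated U-shaped
segmentation network for this task, with three ingredients aimed at
small-batch MRI training:

- **group normalization** in every conv block (batch-size independent),
- an **atrous-spatial-pyramid-pooling (ASPP) bottleneck** — parallel
  3×3 dilated convolutions at rates 1/6/12/18 — widening the receptive
  field at the coarsest scale,
- **dual attention gates** on the skip connections, scaling the encoder
  feature x by a per-pixel and a per-channel coefficient:

  α = σ(W₂ ReLU(Wₓx + W_g g)),  β = σ(W₁W₀ ReLU(AvgPool(x) + AvgPool(g))),
  gated = α ⊙ β ⊙ x,

  with g the same-scale decoder feature and all W realized as 1×1
  convolutions.

The network emits one sigmoid logit channel per zone; training minimizes
BCE + soft-dice with Adam (lr 3e-4, batch 4, early stopping on
validation mean dice), and evaluation reports per-zone Dice
(2|P∩T|/(|P|+|T|)), PPV (precision) and sensitivity (recall) pooled per
volume.

Everything — including the neural network and its backpropagation — runs
on NumPy via a small gradient-checked autodiff engine, so the package
has no deep-learning-framework dependency and is exercisable end-to-end
on a laptop CPU. A **synthetic phantom generator** produces
prostate-like volumes (a bright elliptical TZ core nested in a PZ
annulus over a noisy background, NIfTI + `dataset.json` in Medical
Segmentation Decathlon layout), so the whole pipeline is testable with
no external data download.

## Worked example

Fit a reduced-width model (base 8, ~0.7 M parameters) on ten synthetic
phantom volumes at 64×64 — an 80/20 volume-level split with 3× offline
augmentation of the training slices — then print the results table:

```python
from masunet import (PhantomConfig, generate_phantom_dataset,
                     ZonalSegmentationModel, MASUNetConfig, TrainConfig)

volumes = generate_phantom_dataset(PhantomConfig(seed=1))
model = ZonalSegmentationModel(
    volumes,
    net_config=MASUNetConfig(base_channels=8),
    train_config=TrainConfig(seed=1, max_epochs=20),
    target_size=(64, 64),
)
results = model.fit(max_steps=600)   # ~4 min on one CPU
print(results.summary())
```

```
Zonal Segmentation Model Results
================================================================
Network:                    attention-gated U-Net + ASPP (GN)
Base width / classes:       8 / 2
Parameters:                 710,826
Loss / optimizer:           bce_dice / adam (lr 0.0003)
Epochs run (best):          7 (6)
Stop reason:                reached max_steps=600
----------------------------------------------------------------
class         dice       PPV   sensitivity
PZ          0.9783    0.9645        0.9925
TZ          0.9791    0.9765        0.9821
================================================================
```

The table reads: after 600 optimizer steps the model segments held-out
phantom volumes with ~0.98 Dice in both zones; PPV ≈ precision and
sensitivity ≈ recall of the predicted masks. `results.history` is a
DataFrame of per-epoch losses and validation dice;
`results.save("run/ckpt")` writes a weight archive plus a JSON config
sidecar. On real MRI the same recipe applies at `base_channels=64` and
256×256 slices (≈45 M parameters), which calls for GPU-class hardware
rather than this NumPy engine.

The same pipeline is scriptable from the shell:

```bash
masunet generate-synthetic --out data/ --seed 1
masunet train --data data/ --out run/ --config cfg.yaml
masunet evaluate --checkpoint run/checkpoint --data data/ --report report.csv
masunet predict --checkpoint run/checkpoint --image vol.nii.gz \
    --out pred.nii.gz --overlay overlays/
masunet augment --data data/ --out aug/ --copies 2 --seed 1
```

Overlay PNGs follow the usual convention: green = PZ, red = TZ.

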