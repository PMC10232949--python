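# Methods

## Problem and model

`masunet` segments the two clinically relevant zones of the prostate —
the transition zone (TZ) and the peripheral zone (PZ) — on 2-D slices of
T2-weighted MRI. The network is a U-shaped encoder–decoder with three
modifications relative to a plain attention U-Net:

1. **Group normalization (GN)** after every convolution instead of batch
   normalization, so normalization statistics do not degrade at the
   small batch sizes (4) that large MRI slices force.
2. **An ASPP bottleneck**: four parallel 3×3 dilated convolutions at
   rates 1, 6, 12 and 18 (padding equal to the rate, so spatial size is
   preserved), concatenated and reduced by a 1×1 convolution. This
   widens the receptive field at the coarsest scale without further
   pooling.
3. **Dual attention gates** on every skip connection, multiplying the
   encoder feature x elementwise by a per-pixel spatial coefficient and
   a per-channel coefficient:

       alpha = sigmoid(W2(ReLU(Wx·x + Wg·g)))            (per pixel)
       beta  = sigmoid(W1(W0(ReLU(AvgPool(x)+AvgPool(g)))))  (per channel)
       gated = alpha ⊙ beta ⊙ x

   where g is the decoder feature after up-convolution (same resolution
   and width as x), all W are 1×1 convolutions with biases, and AvgPool
   is global average pooling. Note the channel branch applies ReLU to
   the pooled sum and then the two linear maps with *no* nonlinearity
   between them; this differs from the classic squeeze–excitation order
   `W1(ReLU(W0(·)))`, which is available behind the `se_order` flag.

The encoder holds five conv blocks (two rounds of 3×3 conv → GN → ReLU
each) separated by four 2×2 max-pools, widths doubling from
`base_channels` (default 64) to 16× base at the bottleneck; the fifth
block carries spatial dropout (p = 0.5, training mode only). The decoder
has four up-conv blocks (nearest-neighbour ×2 upsampling then a
channel-halving 3×3 conv + GN + ReLU), four attention gates, three conv
blocks, and a final 1×1 convolution emitting one logit channel per zone.
The head is two independent sigmoid channels (background implicit), not
a 3-way softmax, because the training loss is per-channel binary
cross-entropy plus soft dice. Upsampling uses the floor-index map
`out(X, Y) = in(floor(W/w·X), floor(H/h·Y))`, which for integer factors
reduces to pixel repetition.

At the fourth (finest) decoder scale the concatenation feeds the output
convolution directly rather than another conv block; this matches the
block census above (three decoder conv blocks for four scales) and keeps
the head cheap.

## Numeric substrate

The network runs on a small reverse-mode automatic-differentiation
engine over NumPy (`masunet.autodiff`): broadcast arithmetic,
im2col-based stride-1 dilated convolution, 2×2 max pooling, nearest
upsampling, concatenation, reductions and the ReLU/sigmoid/log/exp
nonlinearities, all with hand-written adjoints. Every adjoint is checked
against central finite differences in the test suite (relative error
≤ 1e-6 demanded, ≤ 1e-8 observed). Tensors are float32 by default;
float64 inputs are preserved, which the gradient checks use.

Numerical choices:

- GN epsilon 1e-5; statistics are biased (population) moments.
- Sigmoid is computed in the two-branch numerically stable form; BCE
  from logits uses `max(z,0) − z·t + log(1 + exp(−|z|))`.
- The pixel-softmax reference op subtracts the per-pixel max; the
  cross-entropy energy floors probabilities at 1e-12, so it is never
  infinite.
- Max-pool gradients route to the first maximum on ties.

## Initialization

Convolution weights are Kaiming-uniform in the parameterization the
mainstream deep-learning frameworks use as their conv default
(negative-slope a = √5, i.e. bound 1/√fan_in); biases start at zero —
they are redundant under the GN that follows almost every convolution,
and a zero output-head bias makes the initial prediction p = 0.5 for
every class. GN starts at γ = 1, β = 0. Building a network from a seed
is bitwise deterministic.

## Group-count policy

GN uses 8 groups at the default widths. At reduced widths the group
count shrinks so that no group gets narrower than 8 channels
(`resolve_gn_groups`): with one channel per group GN degenerates to
instance normalization, which discards the relative scale between
channels; in the overfit experiments below this cost roughly 0.07 dice
at step 200 on the narrow (base 8) network, with everything else
identical. At base 64 the policy is indistinguishable from a flat
8 groups.

## Attention-gate wiring

The gate needs x and g at the same resolution (the spatial branch sums
them pixelwise) and the same width (the channel branch sums their pooled
vectors), so g is taken *after* the up-conv block. The spatial branch's
intermediate width F_int defaults to half the gate width; the channel
branch's bottleneck divisor is 16, with the hidden width floored at one
channel so reduced-width test networks remain constructible. Saturating
the output maps' biases (±40) drives both coefficients to exactly 1.0 in
float32, which is how the gated network is shown to reduce bitwise to
the gate-free network — the plain-U-Net baseline is exactly this
reduction.

## Training recipe

Defaults follow the published recipe: BCE-dice loss (equal weights,
dice smoothing 1.0), Adam with learning rate 3e-4, β1 = 0.9 (the
recipe's "momentum 0.9" read as Adam's first-moment coefficient — Adam
has no classical momentum knob; an SGD-momentum optimizer is available
as the alternative reading), β2 = 0.999, weight decay 1e-4 applied as L2
on gradients, batch size 4, up to 1000 epochs with early stopping after
20 epochs without improvement (> 1e-6) of the validation mean dice
(mean of PZ and TZ; monitoring validation loss instead is a flag).
Model selection keeps the best-validation weights, restored at the end.
Validation runs once per epoch. The learning rate is constant.

Dice/PPV/sensitivity are computed on binary masks
(sigmoid(logit) > 0.5), with pixel counts pooled over all slices of a
volume and metrics computed once per volume per class; the dataset score
is the mean over volumes (per-slice averaging and global pooling are
available by flag). Empty/empty cases score 1.0 so slices without a zone
do not poison volume means.

## Synthetic phantoms

The generator emulates the geometry and contrast of transverse prostate
MRI at the resolution the loader expects: per volume, an elliptical
bright TZ core (label 2) nested concentrically inside a PZ annulus
(label 1) of intermediate intensity over a darker noisy background
(means 0.8 / 0.5 / 0.2, Gaussian noise σ = 0.05), with per-slice jitter
of centre (±1 px) and radii (±5%) and a through-plane profile that
shrinks the gland toward the first and last slices, mimicking the
apex/base taper. Default: 10 volumes × 15 slices × 64×64, written as
MSD-style NIfTI pairs with a `dataset.json` manifest when a directory is
given. Construction guarantees the invariants the tests assert: TZ
strictly inside the PZ outer ellipse, labels disjoint, TZ brighter than
PZ brighter than background.

What the phantoms do *not* emulate: anatomical shape variability beyond
ellipses, the low gland/background contrast of real T2 images, coil
intensity bias, partial-volume boundaries, inter-modality misregistration
(the ADC channel, when generated, is a second noisy copy, not a
diffusion contrast). Passing the phantom tests therefore demonstrates
that the architecture, losses and pipeline are implemented correctly and
can fit zonal geometry — not that the network reaches any particular
accuracy on real MRI.

## Preprocessing, augmentation, splitting

Slices are resized to a uniform size divisible by 16 (bilinear for
images, nearest for labels — no new label codes can appear), intensity
is z-scored per volume (clipped at ±5), and labels are expanded to
disjoint per-class binary masks. Offline augmentation emits each
original plus two augmented copies (3× total), each copy applying a
random subset of: horizontal/vertical flip, rotation (±15°, bilinear
image / nearest mask, reflect padding), Gaussian noise (σ uniform in
1–5% of the image standard deviation), and brightness/contrast scaling
(factors 0.8–1.2). Geometric transforms hit image and masks
identically; intensity transforms hit the image only. The 80/20 split is
by volume — never by slice — so no subject leaks across sets, and
augmented copies exist only in the training set. Generation,
preprocessing, augmentation and splitting are each deterministic given
their seeds, which the manifests record.

## Problem sizes used in the checks

The self-contained checks run a reduced-width network (base 8,
~0.7 M parameters) on 64×64 phantoms: an overfit run (4 slices, 200
steps of the default recipe, training dice > 0.95 per zone) and a short
generalization run (10 volumes, 8/2 split, 3× augmentation, 600 steps)
whose validation metrics the acceptance script reports. The full-width
network (base 64, ~45 M parameters) is built and run once at 64×64 to
verify width scaling. These sizes were chosen so the whole suite runs on
a single CPU in well under an hour; the architecture itself is
unchanged at full width.

## Known limitations

- CPU-only NumPy execution: full-width training at 256×256 is not
  practical here; the package is a faithful, testable implementation,
  not a high-throughput trainer.
- Single-modality default: how (or whether) the T2 and ADC modalities
  should be fused is left open; the loader accepts both, the network
  defaults to T2 only (`in_channels=2` enables naive channel stacking).
- The printed channel-attention operator order is implemented as the
  default even though squeeze–excitation convention differs; switch
  with `se_order=True` if the conventional order is wanted.
- Rotation augmentation of masks uses nearest interpolation, so mask
  pixel counts drift by a few percent per rotated copy.
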