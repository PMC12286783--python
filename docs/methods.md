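# Methods

`volseg` implements a hybrid volumetric segmentation network — a transformer
encoder whose token mixing happens in the Fourier domain, feeding a
skip-connected convolutional decoder — together with everything needed to
exercise it end to end at desk scale: seeded synthetic phantoms, the training
recipe, sliding-window inference, and Dice / HD95 evaluation. This note
records the model, the choices made where the design was open, and what the
synthetic experiments do and do not demonstrate.

## Model

**Tokenisation.** The input volume `(H, W, D, C)` is cut into non-overlapping
cubic patches which are flattened and linearly projected,

    E_patch = Flatten(x_v) · W_proj + E_pos,

with a learned positional table `E_pos` holding one row per 3D token-grid
position (initialised N(0, 0.02)). The tokenisation stride (`patch_size`)
defaults to 2 so that stage 1 of the encoder sits at half the input
resolution; this is the stride that reproduces the documented stage geometry
`S/2, S/4, S/8, S/16` with channel widths 48, 96, 192, 384. Volumes whose
axes are not multiples of the stride are zero-padded at the high end and the
pad amounts recorded; the decoder crops them off again, so any input size
above the minimum (`patch_size · 2^n_stages` per axis) round-trips exactly.

**Transformer blocks.** Pre-norm ordering with residuals outside the norms:

    z′ = Mix(Norm(z)) + z
    z  = MLP(Norm(z′)) + z′

The MLP uses a hidden ratio of 4 and the exact GELU nonlinearity (ViT
convention). `Mix` is selected by `mixing_mode`:

* `afno_3d` (default): the adaptive Fourier path. Token features on their
  3D grid are transformed with the separable DFT along the three grid axes
  per channel, multiplied elementwise by a learned complex filter `W(k)`
  (one weight per frequency per channel), inverse-transformed, and passed
  through a channel-mixing linear projection. `W` is initialised to `1+0i`,
  so the transform path starts as the exact identity.
* `afno_1d`: the same filter applied to the literal 1D transform over the
  flattened token index — the equation as printed rather than its evident
  3D intent — kept for comparison.
* `msa_only`: standard multi-head self-attention, `softmax(QKᵀ/√d_h)V`.
  Attention is O(N²) in the token count, which is precisely what the
  Fourier path avoids; it is exercised at small N in the tests.

In the default mode the Fourier path *replaces* attention inside each
block; `msa_only` provides the attention-only alternative, so both
combinations of the block are available.

**Spectral filter details.** The learnable filter is stored on the full
frequency grid as two real tensors and applied as
`y = Re(IFFT(W ⊙ FFT(x)))`. For real inputs, anti-Hermitian components of
`W` map to purely imaginary outputs and are discarded by the real part, so
they lie in the kernel of the map and receive zero gradient: the effective
learned filter is Hermitian and the output is real by construction. The
filter grid is fixed at construction from `base_input_shape`; inputs on
other grids reuse the same weights through nearest-normalised-frequency
resampling, so one model serves any window size (identical grids resample
to the identity). The positional table is resampled the same way in the
spatial domain. All adjoints (including the scatter-add through the
resampling) are exact and verified against finite differences.

**Hierarchy.** Four stages by default. Between stages, patch merging
concatenates 2×2×2 token neighbourhoods (8·C features) and applies a learned
linear reduction to the next width, halving the grid; odd axes are padded by
one and cropped again in the decoder. A constant-resolution variant
(`constant_resolution=True`, 12 layers at one grid, width 768, pyramid taps
every quarter of the depth resampled to the hierarchical geometry) is kept
as a first-class configuration for comparison; the hierarchical form is the
default.

**Decoder.** Mirror-wired U-Net. Each decoder stage applies

    F_dec_i = Conv( Up(F_dec_{i-1}) ⊕ F_enc_i )

with `Up` a learned transposed convolution (kernel 2, stride 2 — chosen
over fixed trilinear interpolation so the whole upsampling path remains
trainable), `⊕` channel concatenation, and `Conv` two 3×3×3 convolutions
each followed by channel layer-norm and GELU. After the finest stage the map
is upsampled back to the padded input resolution, the tokenisation padding
cropped, and a 1×1×1 convolution produces K logits; softmax yields the
per-voxel class distribution. Ties in the argmax break toward the lowest
class index. The skip wiring is standard symmetric mirroring: decoder
stage i consumes encoder stage n−i.

## Training recipe

AdamW with learning rate 1e-4 and weight decay 0.01, up to 150 epochs with
early stopping. The package fixes the remaining knobs explicitly:

* **Objective**: equally weighted soft-Dice (foreground classes, smoothing
  ε = 1e-5) plus cross-entropy, computed from logits with a stable
  log-softmax. This is the field-standard pairing and directly optimises
  the reported metric.
* **Early stopping**: monitors validation mean Dice, patience 20; the best
  epoch's parameters are restored, never a later epoch's.
* **Splits**: 80/20 train/test via seeded shuffle (`round(0.8·n)`);
  validation items are carved from the training portion (90/10) so the test
  fraction is untouched.
* **Augmentation**: random per-axis rotations ±15°, isotropic scaling
  0.9–1.1, elastic deformation (displacement field smoothed with σ = 4
  voxels, magnitude α = 10 voxels). The same transform is applied to the
  volume (trilinear) and the labels (nearest neighbour). The magnitudes
  are package defaults typical for 3D medical augmentation.
* **Batch size** 2, a size that keeps desk-scale steps responsive.
* **Desk-scale learning rate**: the reduced-width models used in the
  synthetic experiments (stage widths 8/16/32/64, ~6·10⁵ parameters) train
  with lr 3e-3; 1e-4 is tuned for the full-width GPU-scale recipe and is
  kept as the `TrainConfig` default.

All computation runs on a small tape-based reverse-mode autodiff engine over
NumPy (`volseg.nn`): the forward/backward passes of every op — matrix
products, im2col 3D convolutions, transposed convolutions, layer norm,
softmax, GELU, the FFT filter and the table resampling — are hand-derived
and finite-difference-tested. Training is single-threaded deterministic
given the seed.

## Inference

Sliding-window prediction tiles the volume with fixed-size blocks (64³ by
default) at stride
`window · (1 − overlap)`, blends per-window class probabilities with a
Gaussian importance map (σ = window/8), and normalises by the accumulated
weight, so the effective blending weights sum to one at every voxel. A
volume that fits one window is forwarded directly, making the single-tile
case bit-identical to a plain forward pass.

## Evaluation

Per-class one-vs-rest, background excluded. Dice is `2|T∩S|/(|T|+|S|)`;
both-empty returns 1 with an explicit flag, one-empty returns 0. HD95
extracts surface voxels (foreground with a background 6-neighbour;
out-of-bounds counts as background), converts to physical mm via the voxel
spacing (index × spacing, voxel-centre convention), computes directed
nearest-neighbour distance distributions both ways, takes the 95th
percentile of each (linear interpolation between order statistics) and
returns the maximum of the two directed values. The percentile is a
parameter; 100 recovers the classical (max) Hausdorff distance. Distances
are reported in mm, the physical units the voxel spacing defines. Undefined values (empty surfaces) are flagged and excluded from
means with a note, never silently dropped.

## Synthetic phantoms

The generator rasterises parametric organs (ellipsoids, tubes along the
D axis, and lobed "blobs") into a label grid in list order — later organs
overwrite earlier ones, so small structures can sit on large ones — then
assigns intensities from a per-(class, channel) table, adds Gaussian noise,
and smooths intensities (never labels) with a Gaussian kernel as a
partial-volume stand-in. Two packaged presets mirror the two evaluation
settings the architecture targets: `btcv-like` (one CT-like channel,
14 classes mixing large and small structures) and `msd-like` (four
MRI-like channels, three strictly nested foreground shells). A reduced
`btcv-like-mini` preset (48³, 3 classes) drives the desk-scale experiments.
Intensity gaps are at least four noise standard deviations, so a per-voxel
nearest-mean classifier attains ≥99 % accuracy — the phantoms are learnable
by construction, and the tests pin this property.

What the phantoms do **not** emulate: anatomical shape statistics, CT/MRI
physics (beam hardening, bias fields, Rician noise), inter-subject
variability beyond centre jitter, or class imbalance as extreme as real
cohorts. Passing the synthetic generalisation test therefore demonstrates
that the architecture, gradients, recipe and inference machinery work end
to end — not that the model would reach any particular accuracy on real
benchmark data.

## Problem sizes and numerical choices

The synthetic experiments use reduced widths (8/16/32/64) on 32³–48³ grids:
single-phantom overfitting (200 optimisation steps, one 32³ two-class
sphere), and generalisation (train 20 / test 5 phantoms at 48³, 3 classes,
25 epochs, z-score-normalised inputs). These sizes were chosen as the
smallest at which the behaviours of interest (both foreground classes
learned, held-out Dice well above 0.8) are stable across seeds. Other
numerics: z-score guard threshold 1e-8 (degenerate channels map to zeros);
soft-Dice smoothing 1e-5; layer-norm ε 1e-6; imaginary-residue tolerance of
the inverse transform 1e-8; argmax tie-break toward the lowest class.

## Known limitations

* CPU NumPy training: practical up to ~10⁶ parameters and ~64³ volumes;
  the full-width configuration is validated by forward passes and
  shape tracing, not by full training.
* The spectral filter's nearest-frequency resampling is exact only when
  the runtime grid equals the reference grid; across sizes it is an
  approximation (the windowed-vs-whole-volume inference test bounds the
  effect).
* No deep supervision, test-time augmentation, mixed precision, or
  multi-device training.
* `afno_1d` and `constant_resolution` are faithful alternatives kept for
  comparison; they are exercised for correctness, not performance.
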