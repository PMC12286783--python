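# volseg

Volumetric semantic segmentation with a Fourier-mixing transformer encoder
and a convolutional decoder — a complete, desk-scale, NumPy implementation
for 3D medical images (multi-organ CT, multi-modal brain MRI), exercisable
end to end on seeded synthetic phantoms.

## The problem and the model

Segmenting 3D medical volumes needs both global context (organ layout,
long-range anatomy) and local precision (thin boundaries, small
structures). Convolutions capture the latter; token mixing captures the
former, but full self-attention over a dense 3D token grid is O(N²) in the
token count. `volseg` implements a hybrid:

* **Encoder** — the volume is cut into cubic patches and embedded,
  `E_patch = Flatten(x_v)·W_proj + E_pos`; four hierarchical stages of
  pre-norm transformer blocks follow, with patch merging halving the grid
  between stages (widths 48, 96, 192, 384 at `S/2 … S/16`). Inside each
  block, token mixing runs through an **adaptive Fourier filter**:

      F(k) = Σₙ e(n)·exp(−2πi·nk/N),   F_mod(k) = F(k)·W(k),
      e′(n) = (1/N)·Σₖ F_mod(k)·exp(+2πi·nk/N)

  a learned complex weight per frequency per channel between a forward and
  an inverse DFT over the token grid — global mixing at FFT cost.
  Multi-head self-attention is available as an alternative mixing mode.
* **Decoder** — mirror-wired U-Net: `F_dec_i = Conv(Up(F_dec_{i-1}) ⊕ F_enc_i)`
  with learned 2× transposed-convolution upsampling, channel concatenation
  of the encoder skip, two-convolution refinement, and a final 1×1×1
  convolution + softmax to per-voxel class probabilities.
* **Recipe** — soft-Dice + cross-entropy from logits, AdamW (lr 1e-4,
  weight decay 0.01), rotation/scale/elastic augmentation, 80/20 split,
  early stopping on validation mean Dice; Gaussian-blended sliding-window
  inference over fixed-size blocks; per-class Dice and 95th-percentile
  Hausdorff (mm, spacing-aware) evaluation.

There is no deep-learning framework underneath: the network runs on a small
tape-based autodiff engine over NumPy (`volseg.nn`) with hand-derived,
finite-difference-verified adjoints for every op, including the FFT filter
and the im2col 3D convolutions. See `docs/methods.md` for the full account.

## Worked example

Train a reduced-width model to segment a noisy sphere phantom (CPU, ~30 s):

```python
import numpy as np
from volseg import (
    ModelConfig, EncoderConfig, OrganSpec, PhantomSpec, SegmentationModel,
    TrainConfig, generate_phantom, train, evaluate,
)

# a 32^3 two-class phantom: one noisy sphere on background
spec = PhantomSpec(
    grid=(32, 32, 32), channels=1, num_classes=2,
    organs=[OrganSpec(1, "ellipsoid", (0.5, 0.5, 0.5), (0.3, 0.3, 0.3))],
    intensity_table=np.array([[0.0], [100.0]]),
    noise_sigma=5.0, blur_sigma=0.5,
)
phantom = generate_phantom(spec, seed=0)

# reduced-width model (the full-width default is 48/96/192/384)
encoder = EncoderConfig(stage_channels=(8, 16, 32, 64),
                        blocks_per_stage=(1, 1, 1, 1), heads=(2, 2, 2, 2),
                        base_input_shape=(32, 32, 32))
model = SegmentationModel(ModelConfig(encoder=encoder, in_channels=1,
                                      num_classes=2, init_seed=0))

config = TrainConfig(learning_rate=3e-3, max_epochs=200, max_steps=200,
                     batch_size=1, early_stop_patience=1000,
                     augment=None, seed=0)
model, history = train(model, [phantom], config)

result = model.predict(phantom.volume)
report = evaluate(result.labels, phantom.labels)
print(f"train loss {history.train_losses[0]:.3f} -> {history.train_losses[-1]:.3f}")
print(f"sphere Dice {report.per_class[1].dice:.3f}, "
      f"HD95 {report.per_class[1].hd95:.2f} mm")
```

Output:

```
train loss 1.578 -> 0.050
sphere Dice 0.979, HD95 1.00 mm
```

The loss falls by ~30× over 200 optimisation steps and the recovered sphere
overlaps the ground truth at Dice 0.979 with sub-voxel-to-1-voxel boundary
error — the network memorises one phantom, demonstrating that gradients
flow through the whole Fourier-mixing/decoder path. The same machinery
generalises: trained on 20 multi-class 48³ phantoms and evaluated on 5
held-out ones it reaches held-out mean Dice ≈ 0.94 (recomputed by the
acceptance script below).

An sklearn-style facade wraps the same pipeline:

```python
from volseg import VolumeSegmenter
seg = VolumeSegmenter(num_classes=3, stage_channels=(8, 16, 32, 64),
                      max_epochs=25, learning_rate=3e-3, seed=0)
seg.fit(train_volumes, train_labels)
mean_dice = seg.score(test_volumes, test_labels)
```

and a CLI covers the tool workflow:

```bash
volseg generate --preset btcv-like-mini --n 25 --seed 7 --out data/
volseg train    --config run.yaml --data data/ --out runs/r1/
volseg predict  --ckpt runs/r1/best.ckpt --in img.nii.gz --out seg.nii.gz \
                --window 64 64 64 --overlap 0.5
volseg evaluate --pred seg.nii.gz --ref gt.nii.gz --report report.json
```

## Phantom presets

`btcv-like` — one CT-like channel, 14 classes, large and small structures
(ellipsoids, tubes, lobed blobs). `msd-like` — four MRI-like channels,
three strictly nested foreground shells. `btcv-like-mini` — reduced 48³
3-class preset for desk-scale experiments. Phantoms are fully determined by
(spec, seed); intensity gaps exceed 4× the noise level, so the tasks are
learnable by construction.

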