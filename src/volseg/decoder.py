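"""Convolutional decoder: upsample, fuse skips, per-voxel class probabilities.

Mirror-wired U-Net: the coarsest pyramid stage seeds the decoder, and each
decoder stage upsamples 2× with a learned transposed convolution, crops to
the skip's spatial shape if the merge path padded an odd axis, concatenates
the encoder skip along channels, and refines with two 3×3×3 convolutions:

    F_dec_i = Conv( Up(F_dec_{i-1}) ⊕ F_enc_i )

After the finest stage the map is upsampled to the padded input resolution,
the tokenisation padding is cropped, and a 1×1×1 convolution followed by a
per-voxel softmax yields the class distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import EncoderConfig
from .io import LabelMap
from .nn import ConvBlock, Linear, Module, ModuleList, Tensor, UpConv, no_grad, ops

__all__ = ["SegmentationResult", "DecoderStage", "CnnDecoder", "predict_labels"]


@dataclass
class SegmentationResult:
    """Per-voxel class distribution plus the argmax label map."""

    probabilities: np.ndarray        # (H, W, D, K), rows sum to 1
    labels: LabelMap
    logits: np.ndarray | None = None

    @property
    def num_classes(self) -> int:
        return self.probabilities.shape[3]


def predict_labels(result: SegmentationResult) -> LabelMap:
    """Argmax per voxel; ties break toward the lowest class index."""
    return LabelMap(labels=np.argmax(result.probabilities, axis=3),
                    num_classes=result.num_classes,
                    spacing=result.labels.spacing)


class DecoderStage(Module):
    """One fusion step: Up(prev) ⊕ skip, then a two-conv refinement block."""

    def __init__(self, c_prev: int, c_skip: int, c_out: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.up = UpConv(c_prev, c_skip, rng, dtype=dtype)
        self.refine = ConvBlock(2 * c_skip, c_out, rng, dtype=dtype)

    def forward(self, prev, skip):
        up = self.up(prev)
        us, ss = up.shape[:3], skip.shape[:3]
        if any(u < s for u, s in zip(us, ss)):
            raise ValueError(
                f"upsampled shape {us} smaller than skip shape {ss}"
            )
        if us != ss:  # odd-axis padding introduced by patch merging
            up = ops.crop3d(up, tuple(slice(0, s) for s in ss))
        fused = ops.concat([up, skip], axis=-1)
        return self.refine(fused)


class CnnDecoder(Module):
    """Full decoder over an encoder feature pyramid.

    Stage ``i`` of the decoder consumes encoder stage ``n_stages − i`` as
    its skip source; widths mirror the encoder widths on the way up, with a
    configurable stem width before the segmentation head.
    """

    def __init__(self, config: EncoderConfig, num_classes: int,
                 rng: np.random.Generator, stem_width: int | None = None,
                 dtype=np.float32):
        if num_classes < 2:
            raise ValueError(f"num_classes must be >= 2, got {num_classes}")
        self.config = config
        self.num_classes = num_classes
        ch = config.stage_channels
        self.stages = ModuleList(
            DecoderStage(ch[s + 1], ch[s], ch[s], rng, dtype=dtype)
            for s in reversed(range(config.num_stages - 1))
        )
        stem = stem_width or max(ch[0] // 2, num_classes)
        self.stem_width = stem
        # final ×P upsampling back to the padded input resolution
        ups, c = [], ch[0]
        p = config.patch_size
        while p > 1:
            ups.append(UpConv(c, stem, rng, dtype=dtype))
            c, p = stem, p // 2
        self.final_ups = ModuleList(ups)
        self.head = Linear(c, num_classes, rng, dtype=dtype)

    def forward(self, pyramid, pad_amounts=(0, 0, 0)):
        """Logits ``(H, W, D, K)`` at the original (pre-padding) resolution."""
        if len(pyramid) != self.config.num_stages:
            raise ValueError(
                f"expected a {self.config.num_stages}-stage pyramid, "
                f"got {len(pyramid)}"
            )
        x = pyramid[-1]
        for stage, skip in zip(self.stages, reversed(pyramid[:-1])):
            x = stage(x, skip)
        for up in self.final_ups:
            x = up(x)
        ph, pw, pd = pad_amounts
        h, w, d = x.shape[:3]
        if any(pad_amounts):
            x = ops.crop3d(x, (slice(0, h - ph), slice(0, w - pw),
                               slice(0, d - pd)))
        return self.head(x)

    def decode(self, pyramid, pad_amounts=(0, 0, 0),
               spacing=(1.0, 1.0, 1.0), keep_logits: bool = False
               ) -> SegmentationResult:
        """Forward plus softmax and argmax, packaged as a result object."""
        logits = self.forward(pyramid, pad_amounts)
        probs = ops.softmax(logits, axis=-1)
        probs_np = np.asarray(probs.data)
        labels = LabelMap(labels=np.argmax(probs_np, axis=3),
                          num_classes=self.num_classes, spacing=spacing)
        return SegmentationResult(
            probabilities=probs_np, labels=labels,
            logits=np.asarray(logits.data) if keep_logits else None,
        )
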