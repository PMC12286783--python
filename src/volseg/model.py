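"""End-to-end segmentation model: encoder pyramid → decoder → probabilities."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .decoder import CnnDecoder, SegmentationResult
from .encoder import AfnoEncoder, EncoderConfig
from .io import Volume
from .nn import Module, no_grad, ops

__all__ = ["ModelConfig", "SegmentationModel", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    in_channels: int = 1
    num_classes: int = 2
    stem_width: int | None = None
    init_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "encoder": self.encoder.to_dict(),
            "in_channels": self.in_channels,
            "num_classes": self.num_classes,
            "stem_width": self.stem_width,
            "init_seed": self.init_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["encoder"] = EncoderConfig.from_dict(d["encoder"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


class SegmentationModel(Module):
    """Encoder + decoder with a convenience inference path."""

    def __init__(self, config: ModelConfig, dtype=np.float32):
        rng = np.random.default_rng(config.init_seed)
        self.config = config
        self.encoder = AfnoEncoder(config.encoder, config.in_channels, rng,
                                   dtype=dtype)
        self.decoder = CnnDecoder(config.encoder, config.num_classes, rng,
                                  stem_width=config.stem_width, dtype=dtype)

    def forward(self, data: np.ndarray):
        """Differentiable forward pass returning logits ``(H, W, D, K)``."""
        pyramid, pads = self.encoder(data)
        return self.decoder(pyramid, pads)

    def predict(self, vol: Volume | np.ndarray,
                keep_logits: bool = False) -> SegmentationResult:
        """Inference (no tape): per-voxel probabilities and labels."""
        data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
        spacing = vol.spacing if isinstance(vol, Volume) else (1.0, 1.0, 1.0)
        with no_grad():
            pyramid, pads = self.encoder(data)
            return self.decoder.decode(pyramid, pads, spacing=spacing,
                                       keep_logits=keep_logits)

    def predict_proba(self, vol: Volume | np.ndarray) -> np.ndarray:
        return self.predict(vol).probabilities


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    """Write weights (.npz) with a JSON sidecar recording the config hash."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez_compressed(path, **model.state_dict())
    sidecar = {
        "config": model.config.to_dict(),
        "config_hash": model.config.config_hash(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> SegmentationModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig.from_dict(sidecar["config"])
    if config.config_hash() != sidecar["config_hash"]:
        raise ValueError("checkpoint sidecar hash does not match its config")
    model = SegmentationModel(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
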