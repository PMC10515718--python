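"""Full segmentation model: encoder -> ASPP -> decoder.

``build_model`` wires a (MobileNetV2 or dense ablation) backbone, an ASPP
variant and the decoder head into one trainable module with deterministic
seeded initialization, and handles checkpoint (de)serialization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .aspp import AsppConfig, build_aspp
from .backbone import DenseEncoder, MobileNetV2Encoder
from .decoder import DecoderConfig, DecoderHead
from .nn import Module

__all__ = ["ModelConfig", "SegmentationModel", "build_model",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    backbone_variant: str = "mobilenetv2"   # or "dense" (heavier ablation)
    width_mult: float = 1.0
    in_channels: int = 3
    aspp: AsppConfig = field(default_factory=AsppConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        if "aspp" in d and isinstance(d["aspp"], dict):
            a = dict(d["aspp"])
            if "rates" in a:
                a["rates"] = tuple(a["rates"])
            d["aspp"] = AsppConfig(**a)
        if "decoder" in d and isinstance(d["decoder"], dict):
            d["decoder"] = DecoderConfig(**d["decoder"])
        return ModelConfig(**d)


class SegmentationModel(Module):
    """Encoder + ASPP + decoder; forward emits per-pixel class scores at
    input resolution (input sides must be multiples of 16)."""

    def __init__(self, config: ModelConfig) -> None:
        super().__init__()
        self.config = config
        if config.backbone_variant == "mobilenetv2":
            self.encoder = MobileNetV2Encoder(
                in_channels=config.in_channels, width_mult=config.width_mult,
                seed=config.seed)
        elif config.backbone_variant == "dense":
            self.encoder = DenseEncoder(
                in_channels=config.in_channels, width_mult=config.width_mult,
                seed=config.seed)
        else:
            raise ValueError(
                f"unknown backbone variant {config.backbone_variant!r} "
                "(expected 'mobilenetv2' or 'dense')")
        rng = np.random.default_rng(config.seed + 1)
        self.aspp = build_aspp(self.encoder.high_level_channels, config.aspp, rng=rng)
        self.decoder = DecoderHead(self.encoder.low_level_channels,
                                   self.aspp.out_channels, config.decoder,
                                   rng=np.random.default_rng(config.seed + 2))
        self.add_module("encoder", self.encoder)
        self.add_module("aspp", self.aspp)
        self.add_module("decoder", self.decoder)

    def forward(self, x: np.ndarray) -> np.ndarray:
        from .nn import DTYPE
        x = np.asarray(x, dtype=DTYPE)
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(
                f"input sides must be multiples of 16 (stride-16 encoder with "
                f"two x4 decoder upsamplings), got {h}x{w}")
        enc = self.encoder(x)
        high = self.aspp(enc.high_level)
        return self.decoder(enc.low_level, high)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        glow, ghigh = self.decoder.backward(grad)
        ghigh = self.aspp.backward(ghigh)
        return self.encoder.backward(glow, ghigh)

    def predict_mask(self, x: np.ndarray) -> np.ndarray:
        """Argmax class map, (N, H, W) uint8 in {0, 1}."""
        scores = self.forward(x)
        return scores.argmax(axis=1).astype(np.uint8)

    def checksum(self) -> str:
        """Order-stable hash of all parameters and buffers."""
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.state_dict()):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.state_dict()[k]).tobytes())
        return h.hexdigest()


def build_model(config: ModelConfig) -> SegmentationModel:
    """Build the segmentation network from a config, seeded and validated."""
    return SegmentationModel(config)


def save_checkpoint(model: SegmentationModel, path: str | Path,
                    extra: dict | None = None,
                    optimizer_state: list[np.ndarray] | None = None) -> None:
    path = Path(path)
    state = {f"state/{k}": v for k, v in model.state_dict().items()}
    if optimizer_state is not None:
        state.update({f"opt/{i}": v for i, v in enumerate(optimizer_state)})
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str | Path) -> tuple[SegmentationModel, dict]:
    path = Path(path)
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
        opt = [data[f"opt/{i}"] for i in range(len([k for k in data.files
                                                    if k.startswith("opt/")]))]
    model = build_model(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    extra = dict(meta.get("extra", {}))
    if opt:
        extra["optimizer_state"] = opt
    return model, extra
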