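"""Training, prediction and dataset evaluation for the segmentation model.

The defaults mirror the published configuration: learning rate 0.01, 200
epochs, batch size 2, SGD with momentum 0.9, pixel-wise cross-entropy,
512x512 inputs.  Images are resized bilinearly to the configured square and
masks with nearest-neighbor; grayscale inputs are replicated to three
channels and scaled to [0, 1].  The best-validation (MIoU) parameters are
retained alongside the final ones.  Every random choice (initialization,
shuffling) derives from the config seed, so a run is reproducible
bit-for-bit in single-threaded execution.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .metrics import ConfusionCounts, confusion_counts, metric_report
from .model import ModelConfig, SegmentationModel, build_model, save_checkpoint
from .nn import SGD, softmax_cross_entropy

__all__ = ["TrainingConfig", "train", "predict", "evaluate_dirs",
           "load_image", "load_mask", "list_pairs"]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.01
    total_epochs: int = 200
    batch_size: int = 2
    loss: str = "cross_entropy"            # or "weighted_cross_entropy"
    class_weights: tuple[float, ...] = (1.0, 3.0)  # used by the weighted loss
    optimizer: str = "sgd"
    momentum: float = 0.9
    lr_schedule: str = "constant"          # or "poly"
    poly_power: float = 0.9
    seed: int = 0
    input_size: int = 512
    resize_inputs: bool = True
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.total_epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")
        if self.input_size % 16:
            raise ValueError("input_size must be a multiple of 16")
        if self.loss not in ("cross_entropy", "weighted_cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer != "sgd":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("constant", "poly"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "TrainingConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig.from_dict(d["model"])
        if "class_weights" in d:
            d["class_weights"] = tuple(d["class_weights"])
        return TrainingConfig(**d)


# ---------------------------------------------------------------------------
# dataset IO

def list_pairs(directory: str | Path) -> list[tuple[Path, Path]]:
    """Image/mask pairs in a directory: ``X.png`` paired with ``X_mask.png``."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {directory}")
    pairs = []
    for img in sorted(directory.glob("*.png")):
        if img.stem.endswith("_mask"):
            continue
        mask = img.with_name(img.stem + "_mask.png")
        if not mask.exists():
            raise FileNotFoundError(f"no mask found for image {img} "
                                    f"(expected {mask.name})")
        pairs.append((img, mask))
    if not pairs:
        raise FileNotFoundError(f"no image/mask pairs in {directory}")
    return pairs


def load_image(path: str | Path, size: int | None = None) -> np.ndarray:
    """Load a grayscale/RGB image as (3, H, W) float in [0, 1]."""
    try:
        img = Image.open(path)
    except OSError as exc:
        raise OSError(f"unreadable image {path}: {exc}") from exc
    img = img.convert("L")
    if size is not None and img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    return np.repeat(arr[None], 3, axis=0)


def load_mask(path: str | Path, size: int | None = None) -> np.ndarray:
    """Load a mask PNG; values > 127 map to 1 (0/255 storage convention)."""
    try:
        img = Image.open(path)
    except OSError as exc:
        raise OSError(f"unreadable mask {path}: {exc}") from exc
    img = img.convert("L")
    if size is not None and img.size != (size, size):
        img = img.resize((size, size), Image.NEAREST)
    return (np.asarray(img) > 127).astype(np.uint8)


def _load_split(directory: str | Path, size: int) -> tuple[np.ndarray, np.ndarray]:
    pairs = list_pairs(directory)
    xs = np.stack([load_image(p, size) for p, _ in pairs])
    ys = np.stack([load_mask(m, size) for _, m in pairs])
    return xs, ys


# ---------------------------------------------------------------------------
# training

def _epoch_lr(config: TrainingConfig, epoch: int) -> float:
    if config.lr_schedule == "poly":
        frac = epoch / max(1, config.total_epochs)
        return config.learning_rate * (1.0 - frac) ** config.poly_power
    return config.learning_rate


def _dataset_miou(model: SegmentationModel, xs: np.ndarray, ys: np.ndarray,
                  batch: int = 4) -> float:
    model.eval()
    total = ConfusionCounts(np.zeros((2, 2), dtype=np.int64))
    for i in range(0, len(xs), batch):
        pred = model.predict_mask(xs[i:i + batch])
        total = total + confusion_counts(pred, ys[i:i + batch])
    return metric_report(total).MIoU


def train(config: TrainingConfig, train_dir: str | Path,
          val_dir: str | Path | None = None,
          out_dir: str | Path | None = None,
          model: SegmentationModel | None = None,
          resume_from: str | Path | None = None,
          log_fn=None) -> dict:
    """Train a model on paired PNG directories; return a result dict with the
    trained model, the best-validation state and the per-epoch log.

    ``resume_from`` continues a checkpointed run: model parameters, optimizer
    momentum and the epoch counter are restored, and the per-epoch shuffle is
    derived from (seed, epoch), so a resumed run retraces the uninterrupted
    one exactly.
    """
    from .model import load_checkpoint

    size = config.input_size
    xs, ys = _load_split(train_dir, size)
    val = _load_split(val_dir, size) if val_dir is not None else None
    start_epoch = 0
    opt_state = None
    if resume_from is not None:
        if model is not None:
            raise ValueError("pass either a model or resume_from, not both")
        model, extra = load_checkpoint(resume_from)
        start_epoch = int(extra.get("epoch_next", 0))
        opt_state = extra.get("optimizer_state")
    if model is None:
        model = build_model(replace(config.model, seed=config.seed))
    params = model.parameters()
    opt = SGD(params, lr=config.learning_rate, momentum=config.momentum)
    if opt_state is not None:
        for v, saved in zip(opt._velocity, opt_state):
            v[...] = saved
    weights = (np.asarray(config.class_weights, dtype=np.float32)
               if config.loss == "weighted_cross_entropy" else None)
    log: list[dict] = []
    best = {"epoch": -1, "val_miou": -1.0, "state": None}
    for epoch in range(start_epoch, config.total_epochs):
        model.train()
        opt.lr = _epoch_lr(config, epoch)
        order = np.random.default_rng([config.seed, 7919 + epoch]).permutation(len(xs))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            scores = model(xs[idx])
            loss, grad = softmax_cross_entropy(scores, ys[idx], weights)
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        entry = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if val is not None:
            entry["val_miou"] = _dataset_miou(model, *val)
            if entry["val_miou"] > best["val_miou"]:
                best = {"epoch": epoch, "val_miou": entry["val_miou"],
                        "state": {k: v.copy() for k, v in model.state_dict().items()}}
        log.append(entry)
        if log_fn is not None:
            log_fn(entry)
    result = {"model": model, "log": log, "best": best, "config": config}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, out / "last.npz",
                        extra={"log": log, "train_config": config.to_dict(),
                               "epoch_next": config.total_epochs},
                        optimizer_state=opt._velocity)
        if best["state"] is not None:
            final_state = model.state_dict()
            model.load_state_dict(best["state"])
            save_checkpoint(model, out / "best.npz",
                            extra={"epoch": best["epoch"],
                                   "val_miou": best["val_miou"],
                                   "train_config": config.to_dict()})
            model.load_state_dict(final_state)
        import json

        (out / "train_log.json").write_text(json.dumps(log, indent=1))
    return result


def predict(model: SegmentationModel, image_paths: list[str | Path],
            out_dir: str | Path, input_size: int | None = None) -> dict:
    """Write argmax masks (0/255 PNG) for a list of images; log inference FPS."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.eval()
    t0 = time.perf_counter()
    written = []
    for p in image_paths:
        p = Path(p)
        x = load_image(p, input_size)[None]
        mask = model.predict_mask(x)[0]
        dest = out / (p.stem + "_pred.png")
        Image.fromarray((mask * 255).astype(np.uint8)).save(dest)
        written.append(str(dest))
    elapsed = time.perf_counter() - t0
    return {"masks": written, "frame_num": len(image_paths),
            "elapsed_time": elapsed, "fps": len(image_paths) / elapsed}


def evaluate_dirs(pred_dir: str | Path, true_dir: str | Path,
                  overlay_dir: str | Path | None = None) -> dict:
    """Micro-averaged metric report over directories of 0/255 mask PNGs.

    Predictions named ``X_pred.png`` (or ``X.png``) are matched to truths
    ``X_mask.png`` (or ``X.png``) by stem.
    """
    from .metrics import render_overlay

    pred_dir, true_dir = Path(pred_dir), Path(true_dir)
    truths = {}
    for t in sorted(true_dir.glob("*.png")):
        stem = t.stem[:-5] if t.stem.endswith("_mask") else t.stem
        truths[stem] = t
    total = ConfusionCounts(np.zeros((2, 2), dtype=np.int64))
    per_image = {}
    n = 0
    for pr in sorted(pred_dir.glob("*.png")):
        stem = pr.stem[:-5] if pr.stem.endswith("_pred") else pr.stem
        if stem not in truths:
            continue
        pm, tm = load_mask(pr), load_mask(truths[stem])
        counts = confusion_counts(pm, tm)
        total = total + counts
        per_image[stem] = metric_report(counts).to_dict(percent=True)
        n += 1
        if overlay_dir is not None:
            od = Path(overlay_dir)
            od.mkdir(parents=True, exist_ok=True)
            Image.fromarray(render_overlay(pm, tm)).save(od / f"{stem}_overlay.png")
    if n == 0:
        raise FileNotFoundError(
            f"no prediction/truth stem matches between {pred_dir} and {true_dir}")
    return {"n_images": n, "micro": metric_report(total).to_dict(percent=True),
            "per_image": per_image}
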