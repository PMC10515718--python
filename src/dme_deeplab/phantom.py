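"""Synthetic OCT B-scan phantoms with ground-truth edema masks.

A phantom emulates the gross statistical structure of a macula-centered OCT
B-scan: a stack of horizontally smooth bright bands (retinal layers) over a
dark background, with dark fluid pockets (lesions) of mixed scale embedded in
the band region, under multiplicative speckle noise.  Fluid appears as
elliptical hypo-reflective regions whose mean intensity is a fixed fraction
below the surrounding band — the contrast cue a segmentation model must
learn.  A configurable fraction of lesions is small (radius < 8 px), so the
small-lesion recall failure mode of gridded receptive fields is measurable.

Everything is deterministic given the spec's seed.  The generator makes no
attempt at A-scan physics (shadowing, attenuation, axial PSF): it provides
the contrast/scale/noise structure needed to train and evaluate, not a
physically realistic simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset",
           "SMALL_LESION_RADIUS"]

SMALL_LESION_RADIUS = 8  # px; lesions below this count as "small"


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 256
    width: int = 256
    n_layers: int = 6
    n_lesions: int = 4
    lesion_radius_range: tuple[float, float] = (3.0, 24.0)
    small_lesion_fraction: float = 0.35
    speckle_sigma: float = 0.15
    contrast_drop: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom must be at least 32x32 pixels")
        if self.n_layers < 1:
            raise ValueError("need at least one retinal band")
        if self.n_lesions < 0:
            raise ValueError("lesion count must be non-negative")
        rmin, rmax = self.lesion_radius_range
        if rmin < 1 or rmax < rmin:
            raise ValueError("lesion radii must satisfy 1 <= min <= max")
        for name in ("small_lesion_fraction", "contrast_drop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be non-negative")


def _smooth_curve(rng: np.random.Generator, width: int, base: float,
                  amplitude: float) -> np.ndarray:
    """Horizontally smooth boundary: a few random low-frequency sinusoids."""
    x = np.linspace(0.0, 2.0 * np.pi, width)
    y = np.full(width, base)
    for _ in range(3):
        freq = rng.uniform(0.5, 2.5)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        y += rng.uniform(0.2, 1.0) * amplitude * np.sin(freq * x + phase)
    return y


def _sample_radius(rng: np.random.Generator, spec: PhantomSpec) -> float:
    rmin, rmax = spec.lesion_radius_range
    small_cap = min(float(SMALL_LESION_RADIUS) - 1e-6, rmax)
    if rmin < SMALL_LESION_RADIUS and rng.uniform() < spec.small_lesion_fraction:
        return rng.uniform(rmin, max(rmin, small_cap))
    lo = min(max(rmin, float(SMALL_LESION_RADIUS)), rmax)
    return rng.uniform(lo, rmax)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (image, mask): float image in [0, 1] and uint8 mask in {0, 1}."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    image = np.full((h, w), 0.05)

    # Retina band region between two smooth boundaries.
    top = _smooth_curve(rng, w, base=0.22 * h, amplitude=0.03 * h)
    bottom = _smooth_curve(rng, w, base=0.80 * h, amplitude=0.03 * h)
    top = np.clip(top, 2, h - 4)
    bottom = np.clip(bottom, top + max(8, h // 4), h - 2)

    rows = np.arange(h)[:, None]
    # Layer boundaries: evenly spaced fractions of the band, jittered a little.
    fracs = np.linspace(0.0, 1.0, spec.n_layers + 1)
    jitter = rng.uniform(-0.02, 0.02, size=spec.n_layers + 1)
    jitter[0] = jitter[-1] = 0.0
    fracs = np.clip(fracs + jitter, 0.0, 1.0)
    bounds = top[None, :] + np.sort(fracs)[:, None] * (bottom - top)[None, :]
    # Alternate brighter / dimmer bands, as in layered retina reflectivity.
    intensities = rng.uniform(0.45, 0.9, size=spec.n_layers)
    intensities[1::2] *= rng.uniform(0.55, 0.8, size=len(intensities[1::2]))
    band_map = np.zeros((h, w))
    for li in range(spec.n_layers):
        sel = (rows >= bounds[li][None, :]) & (rows < bounds[li + 1][None, :])
        band_map[sel] = intensities[li]
    in_band = band_map > 0
    image[in_band] = band_map[in_band]

    # Dark elliptical fluid pockets inside the band region, non-overlapping.
    mask = np.zeros((h, w), dtype=np.uint8)
    for li in range(spec.n_lesions):
        placed = False
        for _ in range(300):
            r = _sample_radius(rng, spec)
            a = r
            b = r * rng.uniform(0.55, 1.0)
            theta = rng.uniform(0.0, np.pi)
            cx = rng.uniform(a + 2, w - a - 2)
            col = int(np.clip(cx, 0, w - 1))
            lo, hi = top[col] + a + 2, bottom[col] - a - 2
            if hi <= lo:
                continue
            cy = rng.uniform(lo, hi)
            rr, cc = draw_ellipse(cy, cx, b, a, shape=(h, w), rotation=theta)
            if rr.size == 0:
                continue
            if not in_band[rr, cc].all():
                continue
            if mask[rr, cc].any():
                continue
            image[rr, cc] = band_map[rr, cc] * (1.0 - spec.contrast_drop)
            mask[rr, cc] = 1
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place lesion {li + 1}/{spec.n_lesions}: the band "
                f"region of a {h}x{w} phantom cannot fit a lesion of the "
                f"requested radius range {spec.lesion_radius_range} without overlap")

    if spec.speckle_sigma > 0:
        # Multiplicative log-normal speckle, mean-one so band contrast is kept.
        noise = rng.normal(0.0, spec.speckle_sigma, size=(h, w))
        image = image * np.exp(noise - 0.5 * spec.speckle_sigma**2)
    return np.clip(image, 0.0, 1.0), mask


def _save_pair(img: np.ndarray, mask: np.ndarray, img_path: Path,
               mask_path: Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(img_path, (np.clip(img, 0, 1) * 255).astype(np.uint8))
    iio.imwrite(mask_path, (mask * 255).astype(np.uint8))


def generate_dataset(spec: PhantomSpec, n_train: int, n_val: int, n_test: int,
                     seed: int, out_dir: str | Path) -> dict:
    """Write disjoint seeded train/val/test splits of phantom pairs.

    Each image gets its own child seed derived from ``seed``, so split
    membership and every pixel are reproducible from the master seed.
    Returns the manifest (also written to ``manifest.json``).
    """
    for name, n in (("n_train", n_train), ("n_val", n_val), ("n_test", n_test)):
        if n < 1:
            raise ValueError(f"{name} must be >= 1")
    out = Path(out_dir)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(n_train + n_val + n_test)]
    manifest: dict = {"master_seed": seed, "spec": {
        "height": spec.height, "width": spec.width, "n_layers": spec.n_layers,
        "n_lesions": spec.n_lesions,
        "lesion_radius_range": list(spec.lesion_radius_range),
        "small_lesion_fraction": spec.small_lesion_fraction,
        "speckle_sigma": spec.speckle_sigma, "contrast_drop": spec.contrast_drop,
    }, "splits": {}}
    idx = 0
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        split_dir = out / split
        split_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for i in range(n):
            child = replace(spec, seed=child_seeds[idx])
            idx += 1
            img, mask = generate_phantom(child)
            img_name = f"phantom_{i:04d}.png"
            mask_name = f"phantom_{i:04d}_mask.png"
            try:
                _save_pair(img, mask, split_dir / img_name, split_dir / mask_name)
            except OSError as exc:
                raise OSError(f"failed writing {split_dir / img_name}: {exc}") from exc
            entries.append({"image": f"{split}/{img_name}",
                            "mask": f"{split}/{mask_name}", "seed": child.seed})
        manifest["splits"][split] = entries
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
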