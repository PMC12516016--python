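"""Seeded generator of synthetic long-bone images.

Non-fracture images contain a bright, smoothly shaded, slightly curved
elongated band (an anti-aliased capsule with a longitudinal intensity
gradient) at a random orientation on a dark background, plus optional
Gaussian noise.  Fracture images additionally carve a dark, jagged,
roughly transverse polyline discontinuity across the band.  The crack is
the only sharp structure, so fracture images carry elevated
high-frequency (diagonal-detail) subband energy — the statistical signal
the multiband classifier exploits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["SyntheticSpec", "generate_arrays", "generate_dataset", "generate_image"]

FRACTURE_DIR = "fracture"
NON_FRACTURE_DIR = "non_fracture"


@dataclass
class SyntheticSpec:
    image_size: int = 128
    n_fracture: int = 100
    n_nonfracture: int = 100
    bone_width_range: tuple[float, float] = (12.0, 20.0)   # capsule half-width, px
    bone_curvature_range: tuple[float, float] = (0.0, 6.0)  # lateral bow, px
    crack_width_range: tuple[float, float] = (2.0, 4.0)     # crack thickness, px
    crack_contrast: float = 0.65                            # intensity drop inside the crack
    noise_sd: float = 0.02                                  # additive Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fracture < 0 or self.n_nonfracture < 0:
            raise ValueError("image counts must be nonnegative")
        if self.crack_contrast <= 0:
            raise ValueError("crack_contrast must be positive")


def _segment_distance(px: np.ndarray, py: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from every grid point to segment a-b."""
    ab = b - a
    denom = float(ab @ ab) or 1.0
    t = np.clip(((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))


def generate_image(spec: SyntheticSpec, label: int, rng: np.random.Generator) -> np.ndarray:
    """One (size, size, 3) float image in [0, 1]; label 1 adds a crack."""
    size = spec.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)

    theta = rng.uniform(0.0, np.pi)
    axis = np.array([np.cos(theta), np.sin(theta)])     # along the bone
    normal = np.array([-np.sin(theta), np.cos(theta)])  # across the bone
    centre = size / 2.0 + rng.uniform(-8.0, 8.0, size=2)
    half_width = rng.uniform(*spec.bone_width_range)
    curvature = rng.uniform(*spec.bone_curvature_range) * rng.choice([-1.0, 1.0])

    dx, dy = xx - centre[0], yy - centre[1]
    along = dx * axis[0] + dy * axis[1]
    across = dx * normal[0] + dy * normal[1]
    # bowed centreline: lateral offset grows quadratically along the axis
    offset = curvature * (along / size) ** 2
    dist = np.abs(across - offset)

    profile = np.clip((half_width - dist) / 3.0, 0.0, 1.0)  # soft capsule edge
    shade = 0.75 + 0.25 * (along - along.min()) / (along.max() - along.min())
    bone = 0.08 + 0.82 * profile * shade
    bone = gaussian_filter(bone, sigma=1.5)

    if label == 1:
        crack_width = rng.uniform(*spec.crack_width_range)
        t0 = rng.uniform(-0.25, 0.25) * size  # crack position along the bone
        s_vals = np.arange(-half_width - 4.0, half_width + 4.0 + 1e-9, 4.0)
        jitter = rng.uniform(-3.0, 3.0, size=s_vals.size)
        points = [
            centre + (t0 + j) * axis + s * normal for s, j in zip(s_vals, jitter)
        ]
        crack_dist = np.full((size, size), np.inf)
        for a, b in zip(points[:-1], points[1:]):
            crack_dist = np.minimum(crack_dist, _segment_distance(xx, yy, a, b))
        crack_mask = np.clip((crack_width / 2.0 - crack_dist) / 0.75 + 1.0, 0.0, 1.0)
        bone = bone - spec.crack_contrast * crack_mask * np.clip(profile, 0.0, 1.0)

    if spec.noise_sd > 0:
        bone = bone + rng.normal(0.0, spec.noise_sd, size=bone.shape)
    bone = np.clip(bone, 0.0, 1.0)
    return np.repeat(bone[..., None], 3, axis=-1)


def _image_seed(spec: SyntheticSpec, index: int) -> list[int]:
    return [spec.seed, index]


def generate_arrays(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """All images of the dataset as one (n, size, size, 3) array plus binary
    labels (fractures first).  Each image is generated from its own child
    seed, so regeneration is bitwise reproducible image by image."""
    n = spec.n_fracture + spec.n_nonfracture
    images = np.zeros((n, spec.image_size, spec.image_size, 3))
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        label = 1 if i < spec.n_fracture else 0
        rng = np.random.default_rng(_image_seed(spec, i))
        images[i] = generate_image(spec, label, rng)
        labels[i] = label
    return images, labels


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write the dataset as 8-bit PNGs in a class-folder layout
    (fracture/, non_fracture/) with a manifest CSV; returns the manifest
    path.  Empty specs produce an empty manifest without error."""
    from PIL import Image

    out_dir = Path(out_dir)
    for sub in (FRACTURE_DIR, NON_FRACTURE_DIR):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    images, labels = generate_arrays(spec)
    with manifest.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "seed"])
        for i, (img, label) in enumerate(zip(images, labels)):
            sub = FRACTURE_DIR if label == 1 else NON_FRACTURE_DIR
            name = f"{sub}/{'frac' if label else 'nonfrac'}_{i:05d}.png"
            data = (img * 255.0).round().astype(np.uint8)
            Image.fromarray(data).save(out_dir / name)
            writer.writerow([name, int(label), "-".join(map(str, _image_seed(spec, i)))])
    return manifest
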