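"""Grad-CAM saliency maps for the per-subband branches.

The channel-importance weights are the spatially averaged gradients of
the fused model output with respect to the branch's frozen feature map;
the map is the ReLU of the weighted feature sum, min-max normalised to
[0, 1] and bilinearly upsampled to the model input size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize

from fracband.model import INPUT_SIZE, FractureClassifier

__all__ = ["SaliencyMap", "cam_from_activations", "gradcam", "overlay", "save_overlay_png"]


@dataclass
class SaliencyMap:
    heatmap: np.ndarray  # (H, W) in [0, 1]
    branch_id: str
    target_layer: str = "backbone_output"


def cam_from_activations(activations: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """Raw class-activation map from one (h, w, c) feature map and the
    matching output gradients: ReLU of the gradient-weighted channel sum,
    min-max normalised (all-zero maps stay zero)."""
    if activations.shape != gradients.shape:
        raise ValueError(
            f"activation/gradient shape mismatch: {activations.shape} vs {gradients.shape}"
        )
    channel_weights = gradients.mean(axis=(0, 1))  # spatial average per channel
    cam = np.maximum(np.tensordot(activations, channel_weights, axes=([2], [0])), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam


def gradcam(model: FractureClassifier, branch: str, image: np.ndarray) -> SaliencyMap:
    """Saliency map of one branch for a single (H, W, 3) input image.

    Gradients are taken from the fused model output (the decision actually
    made), not from the branch's own sigmoid score.
    """
    if branch not in model.subbands:
        raise ValueError(
            f"branch {branch!r} is not part of this model (subbands: {model.subbands})"
        )
    feats = model.band_features(np.asarray(image)[None])
    _, _ = model._forward_features(feats, training=False)
    grads = model._backward(np.array([1.0]))
    cam = cam_from_activations(
        feats[branch][0].astype(np.float64), grads[branch][0].astype(np.float64)
    )
    heatmap = resize(cam, (INPUT_SIZE, INPUT_SIZE), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return SaliencyMap(heatmap=np.clip(heatmap, 0.0, 1.0), branch_id=branch)


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4) -> np.ndarray:
    """Blend a colormapped heatmap over an RGB image in [0, 1].

    ``alpha=0`` returns the original image, ``alpha=1`` the pure
    colormapped heatmap.  The input image is not modified.
    """
    from matplotlib import colormaps

    image = np.asarray(image, dtype=float)
    heatmap = np.asarray(heatmap, dtype=float)
    if image.shape[:2] != heatmap.shape:
        raise ValueError(f"shape mismatch: image {image.shape[:2]} vs heatmap {heatmap.shape}")
    if image.ndim == 2:
        image = np.repeat(image[..., None], 3, axis=-1)
    coloured = colormaps["jet"](heatmap)[..., :3]
    return np.clip((1.0 - alpha) * image + alpha * coloured, 0.0, 1.0)


def save_overlay_png(blended: np.ndarray, path: str | Path) -> Path:
    from PIL import Image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((np.clip(blended, 0, 1) * 255.0).round().astype(np.uint8)).save(path)
    return path
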