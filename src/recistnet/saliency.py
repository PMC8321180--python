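"""Grad-CAM saliency for the 3D backbone.

Channel weights are the spatial averages of the target-class logit
gradient at the tapped convolutional stage; the map is the ReLU of the
weighted activation sum, tri-linearly upsampled to the input grid and
max-normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .network import ResponseNet

CLASS_INDEX = {"C2": 0, "C1": 1}


@dataclass
class SaliencyMap:
    weights: np.ndarray      # rank-3, nonnegative, in [0, 1], VOI-aligned
    target_class: str
    layer_name: str


def _upsample_trilinear(m: np.ndarray, out_shape: tuple[int, int, int]) -> np.ndarray:
    if m.shape == tuple(out_shape):
        return m
    grids = [np.linspace(0.0, s - 1.0, t) if s > 1 else np.zeros(t)
             for s, t in zip(m.shape, out_shape)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    return map_coordinates(m, [zz, yy, xx], order=1, mode="nearest")


def default_layer(model: ResponseNet) -> str:
    """Deepest dense block (the last spatial feature map before flattening)."""
    dense = [n for n in model.layer_names() if n.endswith(".dense")]
    return dense[-1]


def grad_cam(model: ResponseNet, voi: np.ndarray, clinical: np.ndarray | None,
             target_class: str, layer_name: str | None = None) -> SaliencyMap:
    if target_class not in CLASS_INDEX:
        raise ValueError(f"target_class must be one of {sorted(CLASS_INDEX)}")
    layer_name = layer_name or default_layer(model)
    if layer_name not in model.layer_names():
        raise KeyError(
            f"layer {layer_name!r} not found; valid layers: {model.layer_names()}")
    _, info = model.forward(voi, clinical, train=False)
    activation = info["activations"][layer_name]          # (1, C, d, h, w)
    # class score = evidence margin logit(target) - logit(other); for the
    # binary softmax this is the score whose sign decides the class, and it
    # cancels evidence shared by both logits
    idx = CLASS_INDEX[target_class]
    dlogits = np.zeros_like(info["logits"])
    dlogits[:, idx] = 1.0
    dlogits[:, 1 - idx] = -1.0
    grad = model.backward(dlogits, until=layer_name)       # d score / d activation
    alpha = grad.mean(axis=(2, 3, 4))                      # (1, C) channel weights
    cam = np.maximum((alpha[:, :, None, None, None] * activation).sum(axis=1), 0.0)[0]
    cam = _upsample_trilinear(cam, tuple(model.spec.input_shape))
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return SaliencyMap(weights=cam, target_class=target_class, layer_name=layer_name)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def overlay(voi: np.ndarray, smap: SaliencyMap | np.ndarray, slice_index: int,
            alpha: float = 0.6, cmap: str = "jet") -> np.ndarray:
    """Blend one grayscale VOI slice with the color-mapped saliency.

    Returns an (H, W, 3) uint8 image.  A zero map reproduces the grayscale
    slice exactly; blend weight at a voxel is ``alpha * map``.
    """
    import matplotlib

    weights = smap.weights if isinstance(smap, SaliencyMap) else np.asarray(smap)
    voi = np.asarray(voi, dtype=np.float64)
    if voi.shape != weights.shape:
        raise ValueError(f"VOI shape {voi.shape} != saliency shape {weights.shape}")
    if not 0 <= slice_index < voi.shape[0]:
        raise IndexError(f"slice {slice_index} out of range [0,{voi.shape[0]})")
    sl = voi[slice_index]
    lo, hi = sl.min(), sl.max()
    gray = (sl - lo) / (hi - lo) if hi > lo else np.zeros_like(sl)
    gray_rgb = np.repeat(gray[:, :, None], 3, axis=2)
    m = weights[slice_index]
    color = matplotlib.colormaps[cmap](m)[:, :, :3]
    w = (alpha * m)[:, :, None]
    blended = (1.0 - w) * gray_rgb + w * color
    return np.clip(blended * 255.0, 0, 255).astype(np.uint8)


def save_overlay(image: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(image).save(str(path))


def save_map_nifti(smap: SaliencyMap, path) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.ascontiguousarray(smap.weights.T).astype(np.float32), np.eye(4))
    nib.save(img, str(path))


def top_fraction_mask(smap: SaliencyMap, fraction: float = 0.05) -> np.ndarray:
    """Boolean mask of the top-``fraction`` most salient voxels."""
    w = smap.weights.ravel()
    k = max(1, int(round(fraction * w.size)))
    thresh = np.partition(w, -k)[-k]
    return smap.weights >= thresh
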