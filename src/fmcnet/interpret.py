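"""Class-activation heat-maps (CAM) for the merged-layer architectures.

The map for class c is M_c(x,y) = sum_k w_{c,k} f_k(x,y): a weighted sum of
the final convolutional feature maps, where w_{c,k} is the effective linear
weight from channel k's globally pooled response to the class-c logit.
Because the classifier here is separated from the feature maps by the
merged-layer projection and the dense stack, w_{c,k} is obtained by
composing those weight matrices along the linear path, ignoring the
intermediate nonlinearities (the standard CAM approximation).  The heat-map
is min-max normalized, bilinearly upsampled to the input size, pushed
through a red-emphasis colormap and alpha-blended over the grayscale input.
"""

from __future__ import annotations

import warnings

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize

from .fmc_core import MERGE_SOURCES, ModelGraph


class UnsupportedArchitectureError(ValueError):
    pass


def cam(feature_maps: np.ndarray, class_weights: np.ndarray) -> np.ndarray:
    """Raw class-activation map: (H,W,C) maps + length-C weights -> (H,W)."""
    f = np.asarray(feature_maps, dtype=float)
    w = np.asarray(class_weights, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"expected (H,W,C) feature maps, got shape {f.shape}")
    if w.shape != (f.shape[-1],):
        raise ValueError(
            f"need one weight per channel: {f.shape[-1]} channels, {w.shape} weights")
    return np.einsum("hwc,c->hw", f, w)


def class_weight_vector(model: ModelGraph, class_index: int,
                        source: str = "merged") -> np.ndarray:
    """Effective per-channel weights from pooled features to the class logit.

    Composes merged-projection, dense and classifier weight matrices
    (linear path only).  ``source='conv5'`` restricts the vector to the
    conv5 block of the merged concatenation.
    """
    s = model.spec
    if s.variant == "base":
        raise UnsupportedArchitectureError(
            "the base variant has no pooled merged-layer path; CAM needs a merged variant")
    if not 0 <= class_index < s.n_classes:
        raise ValueError(f"class_index must lie in [0, {s.n_classes})")
    w = model.params["merged.proj.weight"].data.astype(float)
    for i in range(1, len(s.dense_widths) + 1):
        w = w @ model.params[f"fc{i}.weight"].data.astype(float)
    vec = w @ model.params["classifier.weight"].data.astype(float)[:, class_index]
    if source == "merged":
        return vec
    if source == "conv5":
        sources = MERGE_SOURCES[s.variant]
        sizes = [s.conv_widths[int(name[4:]) - 1] for name in sources]
        bounds = np.cumsum([0] + sizes)
        i = sources.index("conv5")
        return vec[bounds[i]:bounds[i + 1]]
    raise ValueError(f"unknown CAM source {source!r} (use 'merged' or 'conv5')")


def heatmap_for_image(model: ModelGraph, image_tensor: np.ndarray,
                      class_index: int = 1, source: str = "merged") -> np.ndarray:
    """Raw CAM of one preprocessed input (H,W,C network tensor)."""
    _, acts = model.forward(image_tensor[None])
    key = "merged" if source == "merged" else "conv5"
    fmap = acts[key].data[0]
    weights = class_weight_vector(model, class_index, source)
    return cam(fmap, weights)


def normalize_heatmap(heatmap: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0,1]; constant maps become all-zeros (warned)."""
    h = np.asarray(heatmap, dtype=float)
    lo, hi = h.min(), h.max()
    if hi - lo <= 0:
        warnings.warn("constant heat-map; normalizing to all zeros", stacklevel=2)
        return np.zeros_like(h)
    return (h - lo) / (hi - lo)


def overlay(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend an upsampled heat-map over a grayscale image.

    Returns an (H, W, 3) RGB float array in [0,1]; red marks high activation.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    span = img.max() - img.min()
    gray = (img - img.min()) / span if span > 0 else np.zeros_like(img)
    base = np.repeat(gray[:, :, None], 3, axis=2)
    h = normalize_heatmap(heatmap)
    if h.shape != img.shape:
        h = resize(h, img.shape, order=1, mode="reflect",
                   anti_aliasing=False, preserve_range=True)
    colored = np.asarray(colormaps[cmap](h))[..., :3]
    out = (1.0 - alpha) * base + alpha * colored
    return np.clip(out, 0.0, 1.0)


def triptych(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.4,
             cmap: str = "jet") -> np.ndarray:
    """Side-by-side panels: original | colorized heat-map | superimposed."""
    img = np.asarray(image, dtype=float)
    span = img.max() - img.min()
    gray = (img - img.min()) / span if span > 0 else np.zeros_like(img)
    left = np.repeat(gray[:, :, None], 3, axis=2)
    middle = overlay(np.zeros_like(img), heatmap, alpha=1.0, cmap=cmap)
    right = overlay(image, heatmap, alpha=alpha, cmap=cmap)
    return np.concatenate([left, middle, right], axis=1)
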