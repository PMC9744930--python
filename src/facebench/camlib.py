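"""Class activation mapping: CAM, Grad-CAM, LayerCAM, stage maps, overlays,
and quantitative attention metrics.

Given a feature stack A (K channels x H x W) at some probe point and, for
the gradient-based variants, the gradients G = dy^c/dA of a class score,
the three map constructions are:

* CAM (GAP-head networks):        M(x,y) = sum_k w^c_k A^k(x,y)
* Grad-CAM:   alpha_k = mean_{x,y} G^k;  M = ReLU(sum_k alpha_k A^k)
* LayerCAM:   M = ReLU(sum_k ReLU(G^k) * A^k)   (element-wise weights)

Grad-CAM averages the gradient spatially into one weight per channel, so it
resolves only channel-level evidence; LayerCAM's element-wise clipped
weights stay informative at early, high-resolution stages.  Maps are
rendered by bilinear upsampling to input resolution, per-map min-max
normalization, and semi-transparent colormap overlay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from .geometry import Rect
from .netlab import TinyCNN


@dataclass
class CAMap:
    """An H x W class-evidence map plus its min-max normalized copy."""

    values: np.ndarray
    method: str  # "cam" | "grad_cam" | "layer_cam"
    stage: str = ""
    class_index: int = 0

    @property
    def normalized(self) -> np.ndarray:
        v = self.values
        lo, hi = float(v.min()), float(v.max())
        if hi - lo < 1e-30:
            return np.zeros_like(v)
        return (v - lo) / (hi - lo)

    @property
    def is_constant(self) -> bool:
        return float(self.values.max() - self.values.min()) < 1e-30


def _check_stack(features: np.ndarray) -> np.ndarray:
    features = np.asarray(features, dtype=float)
    if features.ndim != 3:
        raise ValueError("feature stack must be (K, H, W)")
    if not np.all(np.isfinite(features)):
        raise ValueError("feature stack must be finite")
    return features


def cam(features: np.ndarray, head_weights: np.ndarray,
        literal: bool = False, stage: str = "", class_index: int = 0) -> CAMap:
    """Classical GAP-head class activation map.

    ``M(x,y) = sum_k w^c_k A^k(x,y)`` with w the GAP head's per-channel
    weights for the class of interest; no outer ReLU.  With
    ``literal=True`` the class weights are replaced by each channel's own
    spatial average (a non-discriminative self-weighting variant, kept for
    fidelity experiments).
    """
    a = _check_stack(features)
    if literal:
        w = a.mean(axis=(1, 2))
    else:
        w = np.asarray(head_weights, dtype=float)
        if w.shape != (a.shape[0],):
            raise ValueError(
                f"head_weights has {w.shape} entries, stack has {a.shape[0]} channels")
    return CAMap(np.tensordot(w, a, axes=1), "cam", stage, class_index)


def grad_cam(features: np.ndarray, grads: np.ndarray,
             stage: str = "", class_index: int = 0) -> CAMap:
    """Grad-CAM: spatially averaged gradients as channel weights, outer ReLU."""
    a = _check_stack(features)
    g = np.asarray(grads, dtype=float)
    if g.shape != a.shape:
        raise ValueError(f"gradient shape {g.shape} != feature shape {a.shape}")
    alpha = g.mean(axis=(1, 2))
    m = np.maximum(np.tensordot(alpha, a, axes=1), 0.0)
    return CAMap(m, "grad_cam", stage, class_index)


def layer_cam(features: np.ndarray, grads: np.ndarray,
              stage: str = "", class_index: int = 0) -> CAMap:
    """LayerCAM: element-wise ReLU-clipped gradients as weights, outer ReLU."""
    a = _check_stack(features)
    g = np.asarray(grads, dtype=float)
    if g.shape != a.shape:
        raise ValueError(f"gradient shape {g.shape} != feature shape {a.shape}")
    m = np.maximum((np.maximum(g, 0.0) * a).sum(axis=0), 0.0)
    return CAMap(m, "layer_cam", stage, class_index)


METHODS = ("cam", "grad_cam", "layer_cam")


def stage_maps(model: TinyCNN, image: np.ndarray, class_index: int,
               method: str = "layer_cam",
               upsample_to: tuple[int, int] | None = None) -> list[CAMap]:
    """One activation map per registered stage, upsampled and normalized.

    The returned maps' ``values`` hold the min-max normalized, bilinearly
    upsampled grids at input resolution.  ``method="cam"`` requires a GAP
    head whose channel count matches the probed stage, which restricts it
    to the final stage; use a gradient-based method for stage-wise maps.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    size = (model.input_size, model.input_size) if upsample_to is None else upsample_to
    maps = []
    for stage in model.stages:
        a = model.activations_at(stage, image)
        if method == "cam":
            w_fn = getattr(model, "head_weights", None)
            if w_fn is None:
                raise ValueError("cam requires a model with a GAP head")
            w = w_fn(class_index)
            if w.shape != (a.shape[0],):
                raise ValueError(
                    f"cam is defined at the GAP-head stage only; stage {stage!r} "
                    f"has {a.shape[0]} channels but the head has {w.shape[0]}")
            m = cam(a, w, stage=stage, class_index=class_index)
        else:
            g = model.gradients_at(stage, image, class_index)
            fn = grad_cam if method == "grad_cam" else layer_cam
            m = fn(a, g, stage=stage, class_index=class_index)
        up = _sk_resize(m.normalized, (size[1], size[0]), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
        maps.append(CAMap(up, method, stage, class_index))
    return maps


def overlay(camap: CAMap, image: np.ndarray, alpha: float = 0.5,
            cmap: str = "jet") -> np.ndarray:
    """Alpha-blend the colormapped normalized map over the input image."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=-1)
    norm = camap.normalized
    if norm.shape != img.shape[:2]:
        norm = _sk_resize(norm, img.shape[:2], order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
    heat = colormaps[cmap](norm)[..., :3]
    return np.clip((1.0 - alpha) * img + alpha * heat, 0.0, 1.0)


@dataclass
class AttentionMetrics:
    """Where a map's mass lies relative to the face geometry."""

    overlap: dict[str, float]  # fraction of total map mass inside each feature box
    centroid: tuple[float, float]  # map-weighted mean (x, y)
    left_right_asymmetry: float  # (left-half mass - right-half mass) / total
    defined: bool = True


def attention_metrics(camap: CAMap | np.ndarray,
                      layout: dict[str, Rect]) -> AttentionMetrics:
    """Quantify a map's spatial allocation over the feature layout.

    The map and layout must live on the same pixel grid.  An all-zero map
    has no defined allocation and is returned flagged.
    """
    m = camap.values if isinstance(camap, CAMap) else np.asarray(camap, dtype=float)
    if np.any(m < 0):
        raise ValueError("attention metrics expect a non-negative map")
    total = float(m.sum())
    if total <= 0.0:
        return AttentionMetrics({k: np.nan for k in layout}, (np.nan, np.nan),
                                np.nan, defined=False)
    h, w = m.shape
    overlap = {}
    for name, rect in layout.items():
        rs, cs = rect.clip((w, h)).slices
        overlap[name] = float(m[rs, cs].sum()) / total
    yy, xx = np.mgrid[0:h, 0:w]
    cx = float((m * xx).sum()) / total
    cy = float((m * yy).sum()) / total
    half = w / 2.0
    left = float(m[:, xx[0] < half].sum())
    right = float(m[:, xx[0] >= half].sum())
    # a pixel column straddling an odd width's center belongs to the right half
    return AttentionMetrics(overlap, (cx, cy), (left - right) / total)


def dominant_feature(metrics: AttentionMetrics) -> str:
    """Name the feature group holding the most map mass.

    The two eye boxes are pooled into ``both_eyes`` so the answer matches
    the occlusion battery's condition names.
    """
    if not metrics.defined:
        raise ValueError("attention metrics are undefined (all-zero map)")
    pooled: dict[str, float] = {}
    for name, frac in metrics.overlap.items():
        group = "both_eyes" if name in ("left_eye", "right_eye") else name
        pooled[group] = pooled.get(group, 0.0) + frac
    return max(pooled, key=pooled.get)
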