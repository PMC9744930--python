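"""Disrupted-input stimulus conditions: grayscale, luminance equalization,
feature occlusion, feature-only visibility, and resolution rescaling.

Every transform here is deterministic.  Occlusion boxes are specified on a
reference canvas (562 x 762 by default) and are rescaled proportionally when
applied to images on a smaller canvas, so geometry is consistent across
working resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .faces import DEFAULT_CANVAS, MorphContinuum
from .geometry import Rect

#: ITU-R BT.601 luma weights used for every RGB -> luminance reduction.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Occlusion box sizes (width, height) on the reference canvas.
BOX_SIZES = {"small": (90, 35), "default": (162, 63), "large": (216, 84)}

#: Feature groups addressable by occlusion / visibility specs.
MASKABLE_FEATURES = ("both_eyes", "left_eye", "right_eye", "nose", "mouth")
VISIBLE_GROUPS = ("eyes", "nose", "mouth")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to BT.601 luminance, replicated per channel.

    Single-channel input is returned unchanged (idempotent); RGB input keeps
    its 3-channel shape with all channels equal.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image.copy()
    if image.ndim == 3 and image.shape[-1] == 3:
        if (image[..., 0] == image[..., 1]).all() and (
                image[..., 0] == image[..., 2]).all():
            return image.copy()  # already gray: exact idempotence
        lum = image @ LUMA_WEIGHTS
        return np.repeat(lum[..., None], 3, axis=-1)
    raise ValueError(f"expected (H, W) or (H, W, 3) image, got {image.shape}")


def luminance(image: np.ndarray) -> np.ndarray:
    """Scalar luminance plane of a 2-D or RGB image."""
    image = np.asarray(image, dtype=float)
    return image if image.ndim == 2 else image @ LUMA_WEIGHTS


@dataclass
class EqualizeResult:
    images: list[np.ndarray]
    target_mean: float
    target_sd: float
    n_clipped: int
    flat_flags: list[bool]  # inputs with zero luminance variance


def equalize_luminance(images: list[np.ndarray]) -> EqualizeResult:
    """Match the first two luminance moments across a stimulus set.

    Every image is affinely rescaled so its luminance mean and SD equal the
    across-set averages of the inputs' statistics.  The transform is applied
    channel-wise, which (luminance being linear in the channels) transfers
    exactly to the luminance plane while preserving within-image rank order.
    Outputs are clipped to [0, 1]; the number of clipped pixels is reported.
    A zero-variance input cannot be rescaled and is set to the target mean,
    with its flag raised.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images to equalize")
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ValueError("all images must share one shape")
    lums = [luminance(im) for im in images]
    means = np.array([l.mean() for l in lums])
    sds = np.array([l.std() for l in lums])
    t_mean, t_sd = float(means.mean()), float(sds.mean())

    out, flags, n_clipped = [], [], 0
    for im, m, s in zip(images, means, sds):
        if s < 1e-12:
            eq = np.full_like(np.asarray(im, dtype=float), t_mean)
            flags.append(True)
        else:
            eq = (np.asarray(im, dtype=float) - m) * (t_sd / s) + t_mean
            flags.append(False)
        n_clipped += int(np.sum((eq < 0.0) | (eq > 1.0)))
        out.append(np.clip(eq, 0.0, 1.0))
    return EqualizeResult(out, t_mean, t_sd, n_clipped, flags)


@dataclass(frozen=True)
class OcclusionSpec:
    """A named-feature box battery: what to hide (or exclusively show).

    ``box_size`` is expressed on ``canvas_size`` (the reference canvas) and
    is rescaled proportionally when the spec is applied to an image of a
    different size.
    """

    mode: str  # "mask" | "visible_only"
    features: tuple[str, ...]
    box_size: tuple[int, int] = BOX_SIZES["default"]
    canvas_size: tuple[int, int] = DEFAULT_CANVAS
    merge_overlapping: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("mask", "visible_only"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not self.features:
            raise ValueError("features must be nonempty")
        allowed = set(MASKABLE_FEATURES) | set(VISIBLE_GROUPS)
        for f in self.features:
            if f not in allowed:
                raise ValueError(f"unknown feature {f!r}")
        if self.box_size[0] <= 0 or self.box_size[1] <= 0:
            raise ValueError("box dimensions must be positive")


def place_feature_boxes(
    layout: dict[str, Rect],
    features: tuple[str, ...] | list[str],
    box_size: tuple[int, int],
    canvas_size: tuple[int, int],
    merge_overlapping: bool = False,
) -> list[Rect]:
    """Center one box of ``box_size`` on each requested feature.

    ``both_eyes`` (alias ``eyes``) places one box per eye; overlapping eye
    boxes are merged into their bounding box only when requested.  Every box
    is clipped to the canvas.
    """
    if not features:
        raise ValueError("features must be nonempty")
    bw, bh = box_size
    centers: list[tuple[float, float]] = []
    for f in features:
        if f in ("both_eyes", "eyes"):
            centers.append(layout["left_eye"].center)
            centers.append(layout["right_eye"].center)
        elif f in layout:
            centers.append(layout[f].center)
        else:
            raise ValueError(f"unknown feature {f!r}")
    boxes = [Rect.from_center(cx, cy, bw, bh).clip(canvas_size) for cx, cy in centers]
    if merge_overlapping and len(boxes) == 2:
        a, b = boxes
        if a.x1 > b.x0 and b.x1 > a.x0 and a.y1 > b.y0 and b.y1 > a.y0:
            boxes = [Rect(min(a.x0, b.x0), min(a.y0, b.y0),
                          max(a.x1, b.x1), max(a.y1, b.y1))]
    return boxes


def boxes_for_image(
    image: np.ndarray, layout: dict[str, Rect], spec: OcclusionSpec
) -> list[Rect]:
    """Place the spec's boxes on an image, rescaling the reference box size
    if the image canvas differs from the spec's reference canvas."""
    h, w = image.shape[:2]
    fx, fy = w / spec.canvas_size[0], h / spec.canvas_size[1]
    bw, bh = spec.box_size
    return place_feature_boxes(layout, spec.features, (bw * fx, bh * fy), (w, h),
                               merge_overlapping=spec.merge_overlapping)


def apply_occlusion(
    image: np.ndarray, layout: dict[str, Rect], spec: OcclusionSpec
) -> np.ndarray:
    """Black out the spec's boxes; every other pixel is bit-identical."""
    out = np.asarray(image, dtype=float).copy()
    for box in boxes_for_image(image, layout, spec):
        rs, cs = box.slices
        out[rs, cs] = 0.0
    return out


def apply_visibility(
    image: np.ndarray, layout: dict[str, Rect], spec: OcclusionSpec
) -> np.ndarray:
    """Keep only the spec's boxes visible; everything else is blacked out."""
    img = np.asarray(image, dtype=float)
    out = np.zeros_like(img)
    for box in boxes_for_image(image, layout, spec):
        rs, cs = box.slices
        out[rs, cs] = img[rs, cs]
    return out


def resize_with_masks(
    image: np.ndarray,
    layout: dict[str, Rect],
    target_size: tuple[int, int] = (224, 224),
) -> tuple[np.ndarray, dict[str, Rect]]:
    """Bilinearly resample an image and rescale its layout consistently.

    Rectangle sizes and centers are scaled by ``target / source``
    independently per axis and rounded to the nearest pixel.
    """
    tw, th = target_size
    if tw < 8 or th < 8:
        raise ValueError("target size must be at least 8x8")
    h, w = image.shape[:2]
    if (tw, th) == (w, h):
        return np.asarray(image, dtype=float).copy(), dict(layout)
    shape = (th, tw) if image.ndim == 2 else (th, tw, image.shape[2])
    resized = _sk_resize(np.asarray(image, dtype=float), shape, order=1,
                         mode="edge", anti_aliasing=False, preserve_range=True)
    fx, fy = tw / w, th / h
    return resized, {name: r.scale(fx, fy) for name, r in layout.items()}


@dataclass
class StimulusSet:
    """One disruption condition applied across a whole morph continuum."""

    condition: str
    levels: np.ndarray
    images: list[np.ndarray]
    feature_layout: dict[str, Rect]
    canvas_size: tuple[int, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.levels):
            raise ValueError("exactly one image per morph level required")


def continuum_set(continuum: MorphContinuum, condition: str = "original",
                  grayscale: bool = False) -> StimulusSet:
    """Wrap a continuum (optionally grayscaled) as an undisrupted set."""
    images = [to_grayscale(im) if grayscale else im.copy() for im in continuum.images]
    return StimulusSet(condition, continuum.levels.copy(), images,
                       continuum.feature_layout, continuum.canvas_size,
                       provenance={"grayscale": grayscale})


def occlusion_battery(
    continuum: MorphContinuum,
    box_size: tuple[int, int] = BOX_SIZES["default"],
    reference_canvas: tuple[int, int] = DEFAULT_CANVAS,
) -> list[StimulusSet]:
    """The masked-feature battery: original plus one set per masked feature.

    Produces 6 stimulus sets (original, both_eyes, left_eye, right_eye,
    nose, mouth), each with one image per morph level.
    """
    sets = [continuum_set(continuum, "original")]
    for feat in MASKABLE_FEATURES:
        spec = OcclusionSpec("mask", (feat,), box_size, reference_canvas)
        images = [apply_occlusion(im, continuum.feature_layout, spec)
                  for im in continuum.images]
        sets.append(StimulusSet(feat, continuum.levels.copy(), images,
                                continuum.feature_layout, continuum.canvas_size,
                                provenance={"mode": "mask", "box_size": box_size}))
    return sets


def visibility_battery(
    continuum: MorphContinuum,
    box_sizes: dict[str, tuple[int, int]] | None = None,
    reference_canvas: tuple[int, int] = DEFAULT_CANVAS,
) -> list[StimulusSet]:
    """The feature-only battery: {eyes, nose, mouth} x {small, default, large}.

    Nine stimulus sets, each showing exactly one feature group through boxes
    of one size, everything else black.
    """
    box_sizes = BOX_SIZES if box_sizes is None else box_sizes
    sets = []
    for size_name, box in box_sizes.items():
        for group in VISIBLE_GROUPS:
            spec = OcclusionSpec("visible_only", (group,), box, reference_canvas)
            images = [apply_visibility(im, continuum.feature_layout, spec)
                      for im in continuum.images]
            sets.append(StimulusSet(
                f"{group}_visible_{size_name}", continuum.levels.copy(), images,
                continuum.feature_layout, continuum.canvas_size,
                provenance={"mode": "visible_only", "box_size": box,
                            "size_name": size_name}))
    return sets
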