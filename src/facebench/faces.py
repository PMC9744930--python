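"""Synthetic face stimuli: prototype pairs, morph continua, training corpora,
and simulated observers.

The generator produces schematic luminance "faces": a head ellipse with
localized eye / nose / mouth features drawn at known rectangles, so every
downstream computation (occlusion, activation mapping, attention metrics)
has exact ground-truth geometry.  The two prototype classes differ mainly in
the appearance of the eye region (amplitude and aspect of the eye blobs),
with a weak nose cue and a near-zero mouth cue — the class-diagnostic signal
is deliberately concentrated where human observers concentrate when judging
face ethnicity.  Morphing between the prototypes is pixel-wise linear, so a
morph coordinate ``t`` in [0, 1] indexes a continuum whose endpoints are the
prototypes themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Rect

#: Default reference canvas (width, height) in pixels.
DEFAULT_CANVAS: tuple[int, int] = (562, 762)

#: Names of the localized features every face carries.
FEATURE_NAMES = ("left_eye", "right_eye", "nose", "mouth")

CLASS_NAMES = ("caucasian", "asian")


def default_layout(canvas_size: tuple[int, int] = DEFAULT_CANVAS) -> dict[str, Rect]:
    """Feature rectangles at canonical fractional positions of the canvas.

    Positions scale with the canvas, so a quarter-scale canvas carries a
    quarter-scale layout.
    """
    w, h = canvas_size
    return {
        "left_eye": Rect.from_center(0.345 * w, 0.40 * h, 0.18 * w, 0.066 * h),
        "right_eye": Rect.from_center(0.655 * w, 0.40 * h, 0.18 * w, 0.066 * h),
        "nose": Rect.from_center(0.50 * w, 0.565 * h, 0.13 * w, 0.075 * h),
        "mouth": Rect.from_center(0.50 * w, 0.715 * h, 0.22 * w, 0.07 * h),
    }


@dataclass
class PrototypeFace:
    """A schematic face image with its ground-truth feature geometry."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    canvas_size: tuple[int, int]  # (width, height)
    feature_layout: dict[str, Rect]

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        if (w, h) != tuple(self.canvas_size):
            raise ValueError("image shape does not match canvas_size")


@dataclass
class MorphContinuum:
    """Ordered morph sequence between two prototypes.

    ``levels[i]`` is the morph coordinate of ``images[i]``; level 0 is
    prototype A (Caucasian-like end) and level 1 prototype B (Asian-like
    end).
    """

    levels: np.ndarray
    images: list[np.ndarray]
    feature_layout: dict[str, Rect]
    canvas_size: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.images) != len(self.levels):
            raise ValueError("one image per level required")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")


@dataclass
class ObserverSample:
    """Simulated human observers, each summarized by a PSE."""

    n: int
    pse_values: np.ndarray
    benchmark_mean: float
    benchmark_sem: float


@dataclass
class TrainingCorpus:
    """Balanced two-class image corpus with train/validation splits."""

    images: np.ndarray  # (N, H, W, 3)
    labels: np.ndarray  # (N,) int, 0 = class A, 1 = class B
    split: np.ndarray  # (N,) str, "train" | "val"
    class_names: tuple[str, str] = CLASS_NAMES
    feature_layout: dict[str, Rect] = field(default_factory=dict)

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == split
        return self.images[m], self.labels[m]


def _gauss2d(xx: np.ndarray, yy: np.ndarray, cx: float, cy: float,
             sx: float, sy: float) -> np.ndarray:
    return np.exp(-0.5 * (((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2))


def _draw_face(canvas_size: tuple[int, int], layout: dict[str, Rect],
               params: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    """Render one schematic face as an (H, W, 3) image in [0, 1]."""
    w, h = canvas_size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # head: soft-edged ellipse over a dark background, mild vertical shading
    cx, cy = 0.5 * w, 0.52 * h
    rx, ry = 0.38 * w, 0.42 * h
    d = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2
    head = 1.0 / (1.0 + np.exp((d - 1.0) * 40.0))
    lum = 0.08 + head * (0.60 - 0.06 * (yy / h - 0.5))

    def blob(rect: Rect, amp: float, aspect_x: float, aspect_y: float) -> np.ndarray:
        bx, by = rect.center
        return amp * _gauss2d(xx, yy, bx, by, aspect_x * rect.width,
                              aspect_y * rect.height)

    # eyes: dark horizontal bars; amplitude/aspect carry the class signal
    for eye in ("left_eye", "right_eye"):
        lum -= blob(layout[eye], params["eye_amp"], params["eye_sx"], params["eye_sy"])
        # shared brow line just above each eye, identical across classes
        r = layout[eye]
        lum -= 0.10 * _gauss2d(xx, yy, r.center[0], r.y0 - 0.6 * r.height,
                               0.40 * r.width, 0.18 * r.height)
    # nose: bright vertical ridge (weak class cue)
    lum += blob(layout["nose"], params["nose_amp"], 0.18, 0.45)
    # mouth: dark horizontal bar (near-zero class cue)
    lum -= blob(layout["mouth"], params["mouth_amp"], 0.38, 0.30)

    # fine seeded texture so prototypes from different seeds differ everywhere
    lum += 0.01 * rng.standard_normal((h, w))
    lum = np.clip(lum, 0.0, 1.0)

    img = np.stack([lum, lum, lum], axis=-1)
    # mild skin tint inside the head region
    img[..., 0] += 0.05 * head
    img[..., 2] -= 0.04 * head
    # class-dependent iris tint inside the eye rectangles
    for eye in ("left_eye", "right_eye"):
        rs, cs = layout[eye].slices
        img[rs, cs, 2] += params["eye_tint_b"]
    return np.clip(img, 0.0, 1.0)


def make_prototype_pair(
    seed: int, canvas_size: tuple[int, int] = DEFAULT_CANVAS
) -> tuple[PrototypeFace, PrototypeFace]:
    """Generate the two class prototypes sharing one feature layout.

    Prototype A (morph coordinate 0) carries wide, high-contrast eye bars;
    prototype B (coordinate 1) carries narrower, fainter ones plus a slightly
    stronger nose ridge.  Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If the canvas is smaller than 32 px on either side.
    """
    w, h = canvas_size
    if w < 32 or h < 32:
        raise ValueError(f"canvas {canvas_size} too small; need at least 32x32")
    layout = default_layout(canvas_size)
    for name, r in layout.items():
        if r.clip(canvas_size) != r:
            raise ValueError(f"feature {name} does not fit on canvas {canvas_size}")

    rng = np.random.default_rng(seed)
    jit = lambda: 1.0 + 0.06 * rng.uniform(-1, 1)  # noqa: E731 - per-seed wobble
    params_a = {
        "eye_amp": 0.55 * jit(), "eye_sx": 0.50, "eye_sy": 0.42,
        "nose_amp": 0.06 * jit(), "mouth_amp": 0.20 * jit(), "eye_tint_b": 0.05,
    }
    params_b = {
        "eye_amp": 0.10 * jit(), "eye_sx": 0.30, "eye_sy": 0.38,
        "nose_amp": 0.11 * jit(), "mouth_amp": 0.21 * jit(), "eye_tint_b": -0.04,
    }
    face_a = _draw_face(canvas_size, layout, params_a, np.random.default_rng(seed * 2 + 1))
    face_b = _draw_face(canvas_size, layout, params_b, np.random.default_rng(seed * 2 + 2))
    return (
        PrototypeFace(face_a, canvas_size, layout),
        PrototypeFace(face_b, canvas_size, dict(layout)),
    )


def make_morph_continuum(
    proto_a: PrototypeFace, proto_b: PrototypeFace, n_levels: int = 21
) -> MorphContinuum:
    """Linear pixel-wise morph: image at level ``t`` is ``(1-t)*A + t*B``."""
    if proto_a.canvas_size != proto_b.canvas_size:
        raise ValueError("prototypes must share a canvas size")
    if proto_a.image.shape != proto_b.image.shape:
        raise ValueError("prototype image shapes differ")
    if n_levels < 2:
        raise ValueError("need at least 2 levels")
    levels = np.linspace(0.0, 1.0, n_levels)
    images = [(1.0 - t) * proto_a.image + t * proto_b.image for t in levels]
    return MorphContinuum(levels, images, proto_a.feature_layout, proto_a.canvas_size)


@dataclass
class Jitter:
    """Augmentation noise applied when building a training corpus."""

    translate_px: int = 3
    noise_sd: float = 0.05
    scale_range: tuple[float, float] = (0.97, 1.03)

    @property
    def is_zero(self) -> bool:
        return (self.translate_px == 0 and self.noise_sd == 0.0
                and self.scale_range == (1.0, 1.0))


def _jitter_image(img: np.ndarray, jitter: Jitter, rng: np.random.Generator) -> np.ndarray:
    out = img
    lo, hi = jitter.scale_range
    if (lo, hi) != (1.0, 1.0):
        from skimage.transform import rescale

        s = rng.uniform(lo, hi)
        scaled = rescale(out, (s, s, 1.0), order=1, mode="edge", anti_aliasing=False)
        h, w = img.shape[:2]
        sh, sw = scaled.shape[:2]
        if sh >= h:  # center crop
            y0, x0 = (sh - h) // 2, (sw - w) // 2
            out = scaled[y0:y0 + h, x0:x0 + w]
        else:  # pad with background
            out = np.full_like(img, 0.08)
            y0, x0 = (h - sh) // 2, (w - sw) // 2
            out[y0:y0 + sh, x0:x0 + sw] = scaled
    if jitter.translate_px > 0:
        dx = int(rng.integers(-jitter.translate_px, jitter.translate_px + 1))
        dy = int(rng.integers(-jitter.translate_px, jitter.translate_px + 1))
        out = np.roll(np.roll(out, dy, axis=0), dx, axis=1)
    if jitter.noise_sd > 0:
        out = out + rng.normal(0.0, jitter.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def make_training_corpus(
    proto_a: PrototypeFace,
    proto_b: PrototypeFace,
    n_per_class: int,
    jitter: Jitter | None = None,
    seed: int = 0,
    val_fraction: float = 0.2,
) -> TrainingCorpus:
    """Balanced corpus of jittered prototype instances.

    Each example is one prototype with a seeded random translation, geometric
    rescale, and additive Gaussian noise, clipped to [0, 1].  Class counts
    are equal by construction within both the train and validation splits.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError("val_fraction must be in [0, 1)")
    jitter = Jitter() if jitter is None else jitter
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for label, proto in ((0, proto_a), (1, proto_b)):
        for _ in range(n_per_class):
            img = proto.image.copy() if jitter.is_zero else _jitter_image(
                proto.image, jitter, rng)
            images.append(img)
            labels.append(label)
    images = np.asarray(images)
    labels = np.asarray(labels)
    # per-class round-robin split keeps both splits balanced
    n_val = int(round(val_fraction * n_per_class))
    split = np.empty(2 * n_per_class, dtype=object)
    for label in (0, 1):
        idx = np.where(labels == label)[0]
        split[idx[: n_per_class - n_val]] = "train"
        split[idx[n_per_class - n_val:]] = "val"
    return TrainingCorpus(images, labels, split.astype(str),
                          feature_layout=proto_a.feature_layout)


def sample_human_observers(
    n: int = 30, mean: float = 0.362, sem: float = 0.012, seed: int = 0
) -> ObserverSample:
    """Draw simulated observers whose PSEs match a published group benchmark.

    Individual PSEs are normal with the stated mean and standard deviation
    ``sem * sqrt(n)``, so the sample's expected standard error equals the
    benchmark SEM.
    """
    if n < 2:
        raise ValueError("need at least 2 observers")
    if sem < 0:
        raise ValueError("sem must be non-negative")
    rng = np.random.default_rng(seed)
    values = mean + sem * np.sqrt(n) * rng.standard_normal(n)
    return ObserverSample(n=n, pse_values=values, benchmark_mean=mean, benchmark_sem=sem)


def simulate_2afc_trials(
    observer_pse: float,
    slope: float,
    levels: np.ndarray,
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-alternative forced-choice session.

    Response 1 ("Asian") is drawn per trial with probability given by a
    logistic psychometric curve centered at ``observer_pse``:
    ``P(1 | t) = 1 / (1 + exp(-slope * (t - observer_pse)))``.

    Returns a tidy trial table with one row per trial and columns
    ``level`` and ``response``; row count is ``len(levels) * reps``.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    from scipy.special import expit

    levels = np.asarray(levels, dtype=float)
    rng = np.random.default_rng(seed)
    p = expit(slope * (levels - observer_pse))
    level_col = np.repeat(levels, reps)
    resp = rng.random((len(levels), reps)) < p[:, None]
    return pd.DataFrame({"level": level_col, "response": resp.ravel().astype(int)})
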