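"""The classifier contract and a desk-scale reference CNN.

The rest of the pipeline talks to a classifier only through this contract:

* ``class_names`` — two entries, index 0 Caucasian-like, index 1 Asian-like;
* ``forward`` — class scores (pre-softmax logits) for an image;
* ``stages`` — ordered named probe points;
* ``activations_at(stage, image)`` — the (K, H, W) feature stack at a probe;
* ``gradients_at(stage, image, c)`` — d(score_c)/d(activations), same shape;
* ``head_weights(c)`` — per-channel class weights of a GAP head, if any.

``TinyCNN`` is a small trainable reference implementation: ``n_stages``
blocks of (3x3 conv, ReLU, 2x2 max-pool) whose pool outputs are the probe
points, followed by global average pooling and a 2-way linear head.  The GAP
head makes the classical class-activation-map construction applicable at
the final stage.

The training protocol mirrors common practice for this kind of benchmark:
softmax cross-entropy, Adam, random-crop + horizontal-flip augmentation, and
checkpointing at the best validation accuracy (ties broken toward the
earlier epoch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import nn
from .faces import CLASS_NAMES, TrainingCorpus


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults are the full-scale protocol (batch 32, learning rate 5e-5,
    60 epochs); `desk_config` returns the reduced configuration used for
    the CPU-scale reference runs.
    """

    batch_size: int = 32
    learning_rate: float = 5e-5
    epochs: int = 60
    seed: int = 0
    augment_crop: bool = True
    augment_flip: bool = True
    checkpoint: str = "best_val"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")


def desk_config(seed: int = 0, epochs: int = 5) -> TrainConfig:
    """Reduced configuration for single-CPU runs on the synthetic corpus."""
    return TrainConfig(batch_size=16, learning_rate=1e-2, epochs=epochs, seed=seed)


class TinyCNN:
    """Minimal staged convolutional classifier satisfying the model contract."""

    class_names = CLASS_NAMES

    def __init__(self, seed: int = 0, input_size: int = 48, n_stages: int = 5,
                 channels: tuple[int, ...] | None = None):
        if input_size < 32:
            raise ValueError("input_size must be at least 32")
        if input_size < 2 ** n_stages:
            raise ValueError(
                f"input_size {input_size} too small for {n_stages} pooling stages")
        if channels is None:
            channels = tuple(min(16, 8 + 4 * i) for i in range(n_stages))
        if len(channels) != n_stages:
            raise ValueError("one channel width per stage required")
        self.input_size = input_size
        self.n_stages = n_stages
        self.channels = channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.blocks: list[list] = []
        c_in = 3
        for c_out in channels:
            self.blocks.append([nn.Conv3x3(c_in, c_out, rng), nn.ReLU(), nn.MaxPool2()])
            c_in = c_out
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Linear(c_in, 2, rng)

    # -- contract surface ---------------------------------------------------

    @property
    def stages(self) -> list[str]:
        return [f"stage{i + 1}" for i in range(self.n_stages)]

    def _stage_index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise KeyError(f"unknown stage {stage!r}; have {self.stages}") from None

    def _to_batch(self, images: np.ndarray) -> np.ndarray:
        """Channel-last [0,1] image(s) -> (N, 3, H, W); grayscale replicated."""
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = np.repeat(x[..., None], 3, axis=-1)
        if x.ndim == 3:
            x = x[None]
        if x.shape[-1] != 3:
            raise ValueError("expected channel-last RGB or 2-D grayscale input")
        if x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"input is {x.shape[1]}x{x.shape[2]}, model expects "
                f"{self.input_size}x{self.input_size}; resize first")
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward_batch(self, x: np.ndarray) -> np.ndarray:
        """(N, 3, H, W) -> (N, 2) logits, caching activations for backward.

        Inputs in [0, 1] are centered to [-1, 1] before the first block.
        """
        x = (x - 0.5) * 2.0
        self._stage_acts = []
        for conv, relu, pool in self.blocks:
            x = pool.forward(relu.forward(conv.forward(x)))
            self._stage_acts.append(x)
        return self.head.forward(self.gap.forward(x))

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Class scores y^c for one channel-last image; shape (2,)."""
        logits = self.forward_batch(self._to_batch(image))[0]
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite class scores")
        return logits

    def activations_at(self, stage: str, image: np.ndarray) -> np.ndarray:
        """(K, H, W) feature stack at a probe point."""
        k = self._stage_index(stage)
        self.forward_batch(self._to_batch(image))
        return self._stage_acts[k][0].copy()

    def gradients_at(self, stage: str, image: np.ndarray, class_index: int) -> np.ndarray:
        """d(score of class c)/d(activations at stage); shape (K, H, W)."""
        k = self._stage_index(stage)
        self.forward_batch(self._to_batch(image))
        d = np.zeros((1, 2))
        d[0, class_index] = 1.0
        d = self.gap.backward(self.head.backward(d))
        for conv, relu, pool in reversed(self.blocks[k + 1:]):
            d = conv.backward(relu.backward(pool.backward(d)))
        return d[0].copy()

    def forward_from(self, stage: str, activations: np.ndarray) -> np.ndarray:
        """Run the network tail from a probe point's activations; (2,) logits."""
        k = self._stage_index(stage)
        x = np.asarray(activations, dtype=float)[None]
        for conv, relu, pool in self.blocks[k + 1:]:
            x = pool.forward(relu.forward(conv.forward(x)))
        return self.head.forward(self.gap.forward(x))[0]

    def head_weights(self, class_index: int) -> np.ndarray:
        """Per-channel GAP-head weights w^c_k for the final stage."""
        return self.head.W[class_index].copy()

    # -- parameters ---------------------------------------------------------

    @property
    def layers(self) -> list:
        out = [layer for block in self.blocks for layer in block]
        return out + [self.gap, self.head]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params.values()]

    def set_state(self, state: list[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for k in layer.params:
                layer.params[k][...] = state[i]
                i += 1

    def save(self, path: str) -> None:
        meta = np.array([self.seed, self.input_size, self.n_stages], dtype=np.int64)
        np.savez(path, meta=meta, channels=np.array(self.channels),
                 *self.get_state())

    @classmethod
    def load(cls, path: str) -> "TinyCNN":
        with np.load(path) as z:
            meta = z["meta"]
            model = cls(seed=int(meta[0]), input_size=int(meta[1]),
                        n_stages=int(meta[2]), channels=tuple(z["channels"]))
            model.set_state([z[f"arr_{i}"] for i in range(len(z.files) - 2)])
        return model


def build_tiny_cnn(seed: int = 0, input_size: int = 48, n_stages: int = 5) -> TinyCNN:
    """Construct the reference CNN with kaiming-normal initialization."""
    return TinyCNN(seed=seed, input_size=input_size, n_stages=n_stages)


def augment(image: np.ndarray, seed: int | None = None,
            rng: np.random.Generator | None = None,
            crop: bool = True, flip: bool | None = None,
            crop_frac_range: tuple[float, float] = (0.9, 1.0)) -> np.ndarray:
    """Random-crop (resized back) and horizontal-flip augmentation.

    ``flip=None`` draws a fair coin; passing True/False forces the outcome.
    With ``crop=False`` and ``flip=False`` the image is returned unchanged.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    out = np.asarray(image, dtype=float)
    if crop:
        h, w = out.shape[:2]
        frac = rng.uniform(*crop_frac_range)
        ch, cw = max(1, int(round(frac * h))), max(1, int(round(frac * w)))
        y0 = int(rng.integers(0, h - ch + 1))
        x0 = int(rng.integers(0, w - cw + 1))
        cropped = out[y0:y0 + ch, x0:x0 + cw]
        out = _sk_resize(cropped, out.shape, order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    if flip is None:
        flip = bool(rng.random() < 0.5)
    if flip:
        out = out[:, ::-1].copy()
    return np.asarray(out, dtype=float).copy() if out is image else out


@dataclass
class TrainResult:
    model: TinyCNN
    log: pd.DataFrame
    checkpoint_epoch: int
    best_val_acc: float


def _resize_batch(images: np.ndarray, size: int) -> np.ndarray:
    if images.shape[1] == size and images.shape[2] == size:
        return np.asarray(images, dtype=float)
    return np.stack([
        _sk_resize(im, (size, size, images.shape[3]), order=1, mode="edge",
                   anti_aliasing=False, preserve_range=True)
        for im in images
    ])


def _accuracy(model: TinyCNN, images: np.ndarray, labels: np.ndarray,
              batch: int = 64) -> float:
    hits = 0
    for i in range(0, len(images), batch):
        x = np.ascontiguousarray(images[i:i + batch].transpose(0, 3, 1, 2))
        hits += int((model.forward_batch(x).argmax(axis=1) == labels[i:i + batch]).sum())
    return hits / len(images)


def train_classifier(model: TinyCNN, corpus: TrainingCorpus,
                     config: TrainConfig) -> TrainResult:
    """Cross-entropy training with best-validation checkpointing.

    Returns the model restored to the checkpoint with maximal validation
    accuracy (ties toward the earlier epoch) plus a per-epoch log with
    columns epoch, loss, train_acc, val_acc.
    """
    for split in ("train", "val"):
        imgs, labels = corpus.subset(split)
        if len(imgs) == 0:
            raise ValueError(f"corpus is missing the {split!r} split")
        if len(np.unique(labels)) < 2:
            raise ValueError(f"{split!r} split must contain both classes")

    x_train, y_train = corpus.subset("train")
    x_val, y_val = corpus.subset("val")
    x_train = _resize_batch(x_train, model.input_size)
    x_val = _resize_batch(x_val, model.input_size)

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.layers, lr=config.learning_rate)
    best_state, best_acc, best_epoch = model.get_state(), -1.0, 0
    rows = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_train))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            batch = x_train[idx]
            if config.augment_crop or config.augment_flip:
                batch = np.stack([
                    augment(im, rng=rng, crop=config.augment_crop,
                            flip=None if config.augment_flip else False)
                    for im in batch
                ])
            x = np.ascontiguousarray(batch.transpose(0, 3, 1, 2))
            logits = model.forward_batch(x)
            loss, dlogits = nn.cross_entropy_grad(logits, y_train[idx])
            d = model.gap.backward(model.head.backward(dlogits))
            for conv, relu, pool in reversed(model.blocks):
                d = conv.backward(relu.backward(pool.backward(d)))
            opt.step()
            losses.append(loss)
        train_acc = _accuracy(model, x_train, y_train)
        val_acc = _accuracy(model, x_val, y_val)
        rows.append({"epoch": epoch, "loss": float(np.mean(losses)),
                     "train_acc": train_acc, "val_acc": val_acc})
        if val_acc > best_acc:  # strict: ties keep the earlier epoch
            best_acc, best_epoch = val_acc, epoch
            best_state = model.get_state()
    if config.checkpoint == "best_val":
        model.set_state(best_state)
    return TrainResult(model, pd.DataFrame(rows), best_epoch, best_acc)


def predict_proba(model: TinyCNN, image: np.ndarray) -> np.ndarray:
    """Softmax class probabilities for one image; sums to 1."""
    logits = model.forward(image)
    return nn.softmax(logits[None], axis=1)[0]


# Stage-registration metadata for the published large architectures.  These
# are bookkeeping entries only (which layer of each network serves as each
# probe point when user-supplied weights are adapted); no weights ship with
# the package and nothing in the test surface depends on them.
PUBLISHED_STAGE_REGISTRY: dict[str, dict] = {
    "alexnet": {"stages": ["maxpool1", "maxpool2", "relu8", "relu10", "maxpool5"]},
    "vgg11": {"stages": [f"block{i}_pool" for i in range(1, 6)]},
    "vgg13": {"stages": [f"block{i}_pool" for i in range(1, 6)]},
    "vgg16": {"stages": [f"block{i}_pool" for i in range(1, 6)]},
    "densenet201": {"stages": ["maxpool1", "transition1", "transition2",
                               "transition3", "final_bn"]},
    # the source material is internally inconsistent about the exact
    # MobileNetV3 / EfficientNet variants; the -Large / V2-S readings are used
    "mobilenet_v3_large": {"stages": ["conv1", "invres4", "invres8", "invres12",
                                      "conv_last"]},
    "efficientnet_v2_s": {"stages": ["fused_mbconv2", "fused_mbconv10",
                                     "mbconv6", "mbconv15", "mbconv30"]},
}
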