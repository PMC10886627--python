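"""Tile classifier: VGG19-style CNN, flip augmentation, class-weighted loss.

The reference architecture is the 16-convolution VGG19 feature stack
(randomly initialized, no pretraining) followed by the head used for
this task: flatten -> dense 1000 -> dropout 0.5 -> dense 100 -> 6-way
softmax.  Reference training hyperparameters: 100 epochs, batch size
100, learning rate 1e-4 (Adam), with tiles randomly flipped
horizontally and vertically and the loss weighted inversely to class
frequency.  That configuration is GPU-scale; for CPU work the
``small_cnn`` backbone (four thin conv/pool blocks, the same head)
accepts reduced tile sizes such as 64x64 and trains in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .annotation import N_CLASSES, TissueClass

__all__ = [
    "ModelConfig",
    "ClassWeights",
    "TrainedModel",
    "compute_class_weights",
    "augment_tile",
    "build_model",
    "train",
    "predict_tiles",
]

#: Conv widths of VGG19's five blocks (conv layers per block: 2,2,4,4,4).
_VGG19_BLOCKS = [(64, 2), (128, 2), (256, 4), (512, 4), (512, 4)]
#: Thin desk-profile backbone: one conv per block.
_SMALL_BLOCKS = [(8, 1), (16, 1), (32, 1), (32, 1)]


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference configuration (250x250x3 input tiles,
    batch 100, learning rate 1e-4, 100 epochs, dropout 0.5 between the
    1000- and 100-unit dense layers).  ``small_cnn`` with a smaller
    ``input_size`` is the practical CPU profile.
    """

    input_size: tuple[int, int, int] = (250, 250, 3)
    n_classes: int = N_CLASSES
    backbone: str = "vgg19_full"  # or "small_cnn"
    dense_units: tuple[int, int] = (1000, 100)
    dropout: float = 0.5
    learning_rate: float = 1e-4
    batch_size: int = 100
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in ("vgg19_full", "small_cnn"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        for name in ("learning_rate", "batch_size", "epochs", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["dense_units"] = list(self.dense_units)
        return d


@dataclass
class ClassWeights:
    """Per-class loss weights, expectation 1 under the source distribution."""

    weights: dict[TissueClass, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all class weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.weights[tc] for tc in TissueClass], dtype=np.float64)

    @classmethod
    def uniform(cls) -> "ClassWeights":
        return cls({tc: 1.0 for tc in TissueClass})


def compute_class_weights(distribution) -> ClassWeights:
    """Inverse-frequency weights ``w_c = 1 / (K * p_c)``.

    Normalized so that the expected weight under the training
    distribution is exactly 1 (``sum_c p_c w_c = 1``); a uniform
    distribution therefore yields unit weights, leaving the loss scale
    unchanged.  Every class must have positive frequency.
    """
    p = np.asarray(distribution, dtype=np.float64)
    k = p.size
    if np.any(p <= 0):
        raise ValueError("class weights undefined: a class has zero frequency")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("distribution must sum to 1")
    w = 1.0 / (k * p)
    return ClassWeights({tc: float(w[tc.index]) for tc in TissueClass})


def augment_tile(tile: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal and vertical flips, each with probability 1/2.

    Labels are flip-invariant for tissue texture, so this augments
    without relabeling; the pixel-value multiset is untouched.
    """
    out = tile
    if rng.random() < 0.5:
        out = out[:, ::-1, :]
    if rng.random() < 0.5:
        out = out[::-1, :, :]
    return np.ascontiguousarray(out)


def _augment_batch(batch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.stack([augment_tile(t, rng) for t in batch])


def build_model(cfg: ModelConfig) -> nn.Sequential:
    """Assemble the backbone + head and seed-initialize all weights."""
    h, w, c = cfg.input_size
    blocks = _VGG19_BLOCKS if cfg.backbone == "vgg19_full" else _SMALL_BLOCKS
    factor = 2 ** len(blocks)
    if h % factor or w % factor or h < factor or w < factor:
        raise ValueError(
            f"input size {h}x{w} incompatible with {cfg.backbone}: "
            f"spatial dims must be positive multiples of {factor}"
        )
    layers: list[nn.Layer] = [nn.InputCenter(0.5)]
    in_ch = c
    for width, reps in blocks:
        for _ in range(reps):
            layers.append(nn.Conv2D(in_ch, width))
            layers.append(nn.ReLU())
            in_ch = width
        layers.append(nn.MaxPool2())
    flat = (h // factor) * (w // factor) * in_ch
    d1, d2 = cfg.dense_units
    layers += [
        nn.Flatten(),
        nn.Dense(flat, d1),
        nn.ReLU(),
        nn.Dropout(cfg.dropout),
        nn.Dense(d1, d2),
        nn.ReLU(),
        nn.Dense(d2, cfg.n_classes),
    ]
    model = nn.Sequential(layers)
    model.init(np.random.default_rng(cfg.seed))
    return model


@dataclass
class TrainedModel:
    """A fitted classifier with its training history and provenance."""

    model: nn.Sequential
    config: ModelConfig
    history: list[dict] = field(default_factory=list)
    class_weights: ClassWeights | None = None
    seed: int = 0

    def save(self, path_prefix: str) -> None:
        """Write weights to ``<prefix>.npz`` and metadata to ``<prefix>.json``."""
        import json

        np.savez(f"{path_prefix}.npz", **self.model.state_dict())
        meta = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "class_order": [tc.value for tc in TissueClass],
            "class_weights": (
                {tc.value: w for tc, w in self.class_weights.weights.items()}
                if self.class_weights
                else None
            ),
            "history": self.history,
        }
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path_prefix: str) -> "TrainedModel":
        import json

        with open(f"{path_prefix}.json") as fh:
            meta = json.load(fh)
        cfg_d = dict(meta["config"])
        cfg_d["input_size"] = tuple(cfg_d["input_size"])
        cfg_d["dense_units"] = tuple(cfg_d["dense_units"])
        cfg = ModelConfig(**cfg_d)
        model = build_model(cfg)
        with np.load(f"{path_prefix}.npz") as data:
            model.load_state_dict({k: data[k] for k in data.files})
        cw = meta.get("class_weights")
        return cls(
            model=model,
            config=cfg,
            history=meta.get("history", []),
            class_weights=ClassWeights({TissueClass(k): v for k, v in cw.items()}) if cw else None,
            seed=meta.get("seed", 0),
        )


def _check_tiles(x: np.ndarray, cfg: ModelConfig, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 4 or x.shape[1:] != tuple(cfg.input_size):
        raise ValueError(
            f"{what} tiles must have shape (n, {cfg.input_size[0]}, "
            f"{cfg.input_size[1]}, {cfg.input_size[2]}), got {x.shape}"
        )
    return x


def train(
    model: nn.Sequential,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray | None,
    val_y: np.ndarray | None,
    weights: ClassWeights,
    cfg: ModelConfig,
    augment: bool = True,
) -> TrainedModel:
    """Fit with Adam on class-weighted cross-entropy.

    Tiles are expected normalized to [0, 1] (the difference plane
    rescaled likewise).  Every class must appear in the training labels.
    Per-epoch training loss/accuracy and, when a validation set is
    given, validation loss/accuracy are recorded in the history.  The
    final-epoch weights are kept (no early stopping); dropout and flip
    augmentation are active only during training.
    """
    train_x = _check_tiles(train_x, cfg, "training")
    train_y = np.asarray(train_y, dtype=np.int64)
    present = np.unique(train_y)
    missing = [tc.value for tc in TissueClass if tc.index not in present]
    if missing:
        raise ValueError(f"classes missing from the training set: {missing}")
    w_arr = weights.as_array()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    opt = nn.Adam(model, lr=cfg.learning_rate)
    history: list[dict] = []
    n = train_x.shape[0]
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = train_x[idx]
            if augment:
                xb = _augment_batch(xb, rng)
            yb = train_y[idx]
            logits = model.forward(xb, training=True, rng=rng)
            loss, dlogits = nn.weighted_cross_entropy(logits, yb, w_arr[yb])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "check input normalization and learning rate"
                )
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        rec = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / n,
        }
        if val_x is not None and len(val_x):
            val_probs = _forward_batched(model, _check_tiles(val_x, cfg, "validation"), cfg)
            val_yy = np.asarray(val_y, dtype=np.int64)
            vl, _ = nn.weighted_cross_entropy(
                np.log(np.maximum(val_probs, 1e-12)), val_yy, w_arr[val_yy]
            )
            rec["val_loss"] = float(vl)
            rec["val_acc"] = float((val_probs.argmax(axis=1) == val_yy).mean())
        history.append(rec)
    return TrainedModel(model=model, config=cfg, history=history,
                        class_weights=weights, seed=cfg.seed)


def _forward_batched(model: nn.Sequential, x: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    probs = []
    for start in range(0, x.shape[0], cfg.batch_size):
        logits = model.forward(x[start : start + cfg.batch_size], training=False)
        probs.append(nn.softmax(logits.astype(np.float64)))
    return np.concatenate(probs, axis=0)


def predict_tiles(trained: TrainedModel, tiles: np.ndarray):
    """Class probabilities and argmax labels for a batch of tiles.

    Inference is deterministic (dropout off, no augmentation); argmax
    ties break toward the lowest class index.
    """
    x = _check_tiles(tiles, trained.config, "prediction")
    probs = _forward_batched(trained.model, x, trained.config)
    return probs, probs.argmax(axis=1)
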