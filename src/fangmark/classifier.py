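"""CNN building blocks and a seeded training/prediction harness.

The convolution and pooling primitives are pure-numpy implementations of the
standard CNN calculus (valid cross-correlation at stride 1; max pooling with
floor-division output shapes). The trainable "tiny" backbone — two conv
blocks, max pooling, and a fully-connected head producing two class scores —
runs offline on a single CPU. The named transfer-learning backbones (vgg16,
vgg19, resnet101) are accepted as configuration but require pretrained
weights that are unavailable offline, so building them raises a labelled
error rather than crashing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthetic_data import COBRA, LabeledImage

# Class order of the score vector; the cobra probability is column 0.
CLASS_INDEX = {"cobra": 0, "other": 1}
INDEX_CLASS = {v: k for k, v in CLASS_INDEX.items()}

TINY_BACKBONE = "tiny"
PRETRAINED_BACKBONES = ("vgg16", "vgg19", "resnet101")
BACKBONES = (TINY_BACKBONE,) + PRETRAINED_BACKBONES


class ClassifierError(ValueError):
    pass


class BackboneWeightsUnavailable(ClassifierError):
    """Pretrained weights for a named backbone cannot be fetched offline."""


# ---------------------------------------------------------------------------
# Layer specs and the CNN calculus
# ---------------------------------------------------------------------------

_ACTIVATIONS = {
    "linear": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
}


@dataclass
class ConvLayerSpec:
    """A convolution layer: kernels (m_out, m_in, kh, kw), one bias per
    output map, and an elementwise activation."""

    kernels: np.ndarray
    biases: np.ndarray
    activation: str = "linear"

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=np.float64)
        self.biases = np.asarray(self.biases, dtype=np.float64)
        if self.kernels.ndim != 4:
            raise ClassifierError("kernels must be (m_out, m_in, kh, kw)")
        if self.biases.shape != (self.kernels.shape[0],):
            raise ClassifierError("need exactly one bias per output map")
        if min(self.kernels.shape[2:]) < 1:
            raise ClassifierError("kernel spatial dims must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ClassifierError(
                f"unknown activation {self.activation!r}; "
                f"options: {sorted(_ACTIVATIONS)}")


@dataclass(frozen=True)
class PoolLayerSpec:
    filter_size: int
    stride: int
    mode: str = "max"

    def __post_init__(self) -> None:
        if self.filter_size < 1 or self.stride < 1:
            raise ClassifierError("pool filter size and stride must be >= 1")
        if self.mode != "max":
            raise ClassifierError("only max pooling is supported")


def conv_forward(input_maps: np.ndarray, spec: ConvLayerSpec) -> np.ndarray:
    """Y_i = f(B_i + sum_j K_ij * Y_j), valid cross-correlation at stride 1.

    ``input_maps`` is (m_in, H, W); output is (m_out, H - kh + 1, W - kw + 1).
    """
    x = np.asarray(input_maps, dtype=np.float64)
    if x.ndim != 3:
        raise ClassifierError("input_maps must be (m_in, H, W)")
    m_out, m_in, kh, kw = spec.kernels.shape
    if x.shape[0] != m_in:
        raise ClassifierError(
            f"spec expects {m_in} input maps, got {x.shape[0]}")
    if kh > x.shape[1] or kw > x.shape[2]:
        raise ClassifierError("kernel larger than input")
    # (m_in, oh, ow, kh, kw) windows -> flatten to an im2col matrix
    windows = sliding_window_view(x, (kh, kw), axis=(1, 2))
    oh, ow = windows.shape[1], windows.shape[2]
    cols = windows.transpose(1, 2, 0, 3, 4).reshape(oh * ow, m_in * kh * kw)
    weights = spec.kernels.reshape(m_out, m_in * kh * kw)
    out = cols @ weights.T + spec.biases
    out = out.reshape(oh, ow, m_out).transpose(2, 0, 1)
    return _ACTIVATIONS[spec.activation](out)


def pool_output_shape(in_dims: tuple[int, int, int], filter_size: int,
                      stride: int) -> tuple[int, int, int]:
    """(m1, m2, m3) -> (m1, (m2-F)//S + 1, (m3-F)//S + 1)."""
    m1, m2, m3 = in_dims
    if filter_size > m2 or filter_size > m3:
        raise ClassifierError(
            f"pool filter {filter_size} exceeds spatial dims ({m2}, {m3})")
    return (m1,
            (m2 - filter_size) // stride + 1,
            (m3 - filter_size) // stride + 1)


def max_pool(feature_map: np.ndarray, filter_size: int, stride: int) -> np.ndarray:
    """Max over F x F windows at the given stride; accepts (H, W) or (C, H, W)."""
    x = np.asarray(feature_map, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    if x.ndim != 3:
        raise ClassifierError("feature map must be (H, W) or (C, H, W)")
    pool_output_shape(x.shape, filter_size, stride)  # validates dims
    windows = sliding_window_view(x, (filter_size, filter_size), axis=(1, 2))
    out = windows[:, ::stride, ::stride].max(axis=(3, 4))
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# Trainable tiny backbone (batched, with backprop)
# ---------------------------------------------------------------------------


def _batched_im2col(x: np.ndarray, kh: int, kw: int) -> tuple[np.ndarray, int, int]:
    n, c, h, w = x.shape
    windows = sliding_window_view(x, (kh, kw), axis=(2, 3))
    oh, ow = windows.shape[2], windows.shape[3]
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    return cols, oh, ow


def _col2im(dcols: np.ndarray, x_shape: tuple, kh: int, kw: int,
            oh: int, ow: int) -> np.ndarray:
    n, c, h, w = x_shape
    dx = np.zeros(x_shape)
    dcols = dcols.reshape(n, oh, ow, c, kh, kw)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + oh, j:j + ow] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2)
    return dx


class TinyCNN:
    """Two conv blocks (ReLU + 2x2 max pool) and a fully-connected 2-class head.

    Weights live in ``params``; Adam state in ``opt_state``. All randomness
    (init, batching) is seeded.
    """

    def __init__(self, input_side: int = 64, seed: int = 0,
                 n_filters: tuple[int, int] = (8, 16), kernel: int = 3,
                 n_classes: int = 2) -> None:
        self.input_side = int(input_side)
        self.seed = int(seed)
        self.n_filters = tuple(int(f) for f in n_filters)
        self.kernel = int(kernel)
        self.n_classes = int(n_classes)
        self.trained = False
        rng = np.random.default_rng(seed)
        k, (f1, f2) = self.kernel, self.n_filters

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        s1 = self.input_side - k + 1
        p1 = (s1 - 2) // 2 + 1
        s2 = p1 - k + 1
        p2 = (s2 - 2) // 2 + 1
        self._shapes = (s1, p1, s2, p2)
        flat = f2 * p2 * p2
        self.params = {
            "W1": he((f1, 3, k, k), 3 * k * k),
            "b1": np.zeros(f1),
            "W2": he((f2, f1, k, k), f1 * k * k),
            "b2": np.zeros(f2),
            "W3": he((flat, self.n_classes), flat),
            "b3": np.zeros(self.n_classes),
        }
        self.opt_state: dict[str, dict[str, np.ndarray]] = {}
        self._opt_t = 0

    # -- forward / backward -------------------------------------------------

    def _conv_layer(self, x, W, b):
        cols, oh, ow = _batched_im2col(x, W.shape[2], W.shape[3])
        out = cols @ W.reshape(W.shape[0], -1).T + b
        out = out.reshape(x.shape[0], oh, ow, W.shape[0]).transpose(0, 3, 1, 2)
        return out, cols, (oh, ow)

    def _pool2(self, x):
        n, c, h, w = x.shape
        he, we = h - h % 2, w - w % 2
        xr = x[:, :, :he, :we].reshape(n, c, he // 2, 2, we // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, he // 2, we // 2, 4)
        idx = flat.argmax(axis=4)
        return flat.max(axis=4), (idx, x.shape)

    def _pool2_backward(self, dout, cache):
        idx, x_shape = cache
        n, c, h, w = x_shape
        oh, ow = dout.shape[2], dout.shape[3]
        dflat = np.zeros((n, c, oh, ow, 4))
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=4)
        dxr = dflat.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(x_shape)
        dx[:, :, :oh * 2, :ow * 2] = dxr.reshape(n, c, oh * 2, ow * 2)
        return dx

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, dict]:
        """x: (N, 3, side, side) -> logits (N, n_classes), plus a cache."""
        p = self.params
        z1, cols1, _ = self._conv_layer(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        pool1, pc1 = self._pool2(a1)
        z2, cols2, _ = self._conv_layer(pool1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        pool2, pc2 = self._pool2(a2)
        flat = pool2.reshape(x.shape[0], -1)
        logits = flat @ p["W3"] + p["b3"]
        cache = {"x": x, "z1": z1, "cols1": cols1, "pc1": pc1,
                 "pool1": pool1, "z2": z2, "cols2": cols2, "pc2": pc2,
                 "pool2": pool2, "flat": flat}
        return logits, cache

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p, grads = self.params, {}
        grads["W3"] = cache["flat"].T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["W3"].T
        dpool2 = dflat.reshape(cache["pool2"].shape)
        da2 = self._pool2_backward(dpool2, cache["pc2"])
        dz2 = da2 * (cache["z2"] > 0)
        grads["W2"], grads["b2"], dpool1 = self._conv_backward(
            dz2, cache["cols2"], cache["pool1"].shape, p["W2"])
        da1 = self._pool2_backward(dpool1, cache["pc1"])
        dz1 = da1 * (cache["z1"] > 0)
        grads["W1"], grads["b1"], _ = self._conv_backward(
            dz1, cache["cols1"], cache["x"].shape, p["W1"])
        return grads

    def _conv_backward(self, dz, cols, x_shape, W):
        n, m_out, oh, ow = dz.shape
        dz2d = dz.transpose(0, 2, 3, 1).reshape(n, oh * ow, m_out)
        dW = np.einsum("npm,npk->mk", dz2d, cols).reshape(W.shape)
        db = dz2d.sum(axis=(0, 1))
        dcols = dz2d @ W.reshape(m_out, -1)
        dx = _col2im(dcols, x_shape, W.shape[2], W.shape[3], oh, ow)
        return dW, db, dx

    # -- optimizer ----------------------------------------------------------

    def adam_step(self, grads: dict, lr: float, eps: float,
                  beta1: float = 0.9, beta2: float = 0.999) -> None:
        self._opt_t += 1
        t = self._opt_t
        for name, g in grads.items():
            state = self.opt_state.setdefault(
                name, {"m": np.zeros_like(g), "v": np.zeros_like(g)})
            state["m"] = beta1 * state["m"] + (1 - beta1) * g
            state["v"] = beta2 * state["v"] + (1 - beta2) * g * g
            m_hat = state["m"] / (1 - beta1 ** t)
            v_hat = state["v"] / (1 - beta2 ** t)
            self.params[name] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # -- inference ----------------------------------------------------------

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(batch)
        logits = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        return ex / ex.sum(axis=1, keepdims=True)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = np.array([self.input_side, self.seed, self.n_filters[0],
                         self.n_filters[1], self.kernel, self.n_classes,
                         int(self.trained)])
        np.savez(path, _meta=meta, **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "TinyCNN":
        data = np.load(path)
        meta = data["_meta"]
        model = cls(input_side=int(meta[0]), seed=int(meta[1]),
                    n_filters=(int(meta[2]), int(meta[3])),
                    kernel=int(meta[4]), n_classes=int(meta[5]))
        model.trained = bool(meta[6])
        for name in model.params:
            model.params[name] = data[name]
        return model


# ---------------------------------------------------------------------------
# Training harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters. Defaults: 100 epochs, lr 0.001,
    epsilon 1e-10, batch size 64."""

    epochs: int = 100
    learning_rate: float = 0.001
    epsilon: float = 1e-10
    batch_size: int = 64
    backbone: str = TINY_BACKBONE
    seed: int = 0
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    input_side: int = 64

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ClassifierError("epochs must be >= 1")
        if not (0.0 < self.learning_rate < 1.0):
            raise ClassifierError("learning rate must lie in (0, 1)")
        if self.batch_size < 1:
            raise ClassifierError("batch size must be >= 1")
        if self.backbone not in BACKBONES:
            raise ClassifierError(
                f"unknown backbone {self.backbone!r}; options: {BACKBONES}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ClassifierError("split fractions must sum to 1")
        if self.input_side < 8:
            raise ClassifierError("input side must be >= 8")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_acc: float
    val_acc: float


@dataclass
class TrainResult:
    model: TinyCNN
    history: list[EpochRecord]
    splits: dict[str, list[int]] = field(default_factory=dict)


def build_model(config: TrainConfig) -> TinyCNN:
    """Build the configured backbone; pretrained backbones need weight files
    that cannot be fetched offline and raise a labelled error."""
    if config.backbone == TINY_BACKBONE:
        return TinyCNN(input_side=config.input_side, seed=config.seed)
    if config.backbone in PRETRAINED_BACKBONES:
        raise BackboneWeightsUnavailable(
            f"pretrained weights for {config.backbone!r} are unavailable "
            "offline; use the 'tiny' backbone or provide a weights file")
    raise ClassifierError(
        f"unknown backbone {config.backbone!r}; options: {BACKBONES}")


def images_to_batch(images: list[LabeledImage] | list[np.ndarray],
                    side: int) -> np.ndarray:
    """Stack images into an (N, 3, side, side) float batch, resizing as needed."""
    from .preprocess import resize_to_canonical

    arrays = []
    for im in images:
        px = im.pixels if isinstance(im, LabeledImage) else np.asarray(im)
        if px.ndim == 2:
            px = np.repeat(px[:, :, None], 3, axis=2)
        if px.shape[:2] != (side, side):
            px = resize_to_canonical(px, side)
        arrays.append(px.transpose(2, 0, 1))
    if not arrays:
        return np.zeros((0, 3, side, side))
    return np.stack(arrays)


def labels_to_indices(labels: list[str]) -> np.ndarray:
    return np.array([CLASS_INDEX[lab] for lab in labels], dtype=np.int64)


def split_dataset(n: int, fractions: tuple[float, float, float],
                  seed: int) -> dict[str, list[int]]:
    """Seeded train/val/test index split."""
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return {"train": order[:n_train].tolist(),
            "val": order[n_train:n_train + n_val].tolist(),
            "test": order[n_train + n_val:].tolist()}


def _accuracy(model: TinyCNN, batch: np.ndarray, y: np.ndarray,
              chunk: int = 256) -> float:
    if len(y) == 0:
        return float("nan")
    hits = 0
    for i in range(0, len(y), chunk):
        probs = model.predict_proba(batch[i:i + chunk])
        hits += int((probs.argmax(axis=1) == y[i:i + chunk]).sum())
    return hits / len(y)


def train(model: TinyCNN, dataset: list[LabeledImage], config: TrainConfig,
          splits: dict[str, list[int]] | None = None) -> TrainResult:
    """Mini-batch cross-entropy training, fully seeded.

    ``history`` records one (train loss, train acc, val acc) triple per
    epoch; train/val accuracy are measured with the end-of-epoch weights.
    Passing ``splits`` reuses a precomputed index split (used by the
    feedback-retraining loop to keep its held-out set fixed).
    """
    if not dataset:
        raise ClassifierError("cannot train on an empty dataset")
    if splits is None:
        splits = split_dataset(len(dataset), config.split, config.seed)
    train_idx = splits["train"]
    train_labels = {dataset[i].label for i in train_idx}
    if len(train_labels) < 2:
        raise ClassifierError(
            "training split must contain both classes, got only "
            f"{sorted(train_labels)}")

    side = model.input_side
    x_train = images_to_batch([dataset[i] for i in train_idx], side)
    y_train = labels_to_indices([dataset[i].label for i in train_idx])
    x_val = images_to_batch([dataset[i] for i in splits["val"]], side)
    y_val = labels_to_indices([dataset[i].label for i in splits["val"]])

    rng = np.random.default_rng(config.seed + 1)
    history: list[EpochRecord] = []
    n = len(train_idx)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            xb, yb = x_train[batch_idx], y_train[batch_idx]
            logits, cache = model.forward(xb)
            shifted = logits - logits.max(axis=1, keepdims=True)
            log_probs = shifted - np.log(
                np.exp(shifted).sum(axis=1, keepdims=True))
            losses.append(-log_probs[np.arange(len(yb)), yb].mean())
            probs = np.exp(log_probs)
            dlogits = probs
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            grads = model.backward(dlogits, cache)
            model.adam_step(grads, config.learning_rate, config.epsilon)
        history.append(EpochRecord(
            epoch=epoch,
            train_loss=float(np.mean(losses)),
            train_acc=_accuracy(model, x_train, y_train),
            val_acc=_accuracy(model, x_val, y_val)))
    model.trained = True
    return TrainResult(model=model, history=history, splits=splits)


def predict(model: TinyCNN, images: list[LabeledImage] | list[np.ndarray],
            chunk: int = 256) -> tuple[list[str], np.ndarray]:
    """Classify images; returns labels and per-image cobra probabilities."""
    if len(images) == 0:
        return [], np.zeros(0)
    batch = images_to_batch(images, model.input_side)
    labels: list[str] = []
    scores = np.empty(len(images))
    for i in range(0, len(images), chunk):
        probs = model.predict_proba(batch[i:i + chunk])
        preds = probs.argmax(axis=1)
        labels.extend(INDEX_CLASS[int(p)] for p in preds)
        scores[i:i + len(probs)] = probs[:, CLASS_INDEX[COBRA]]
    return labels, scores
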