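"""F-Net: a compact CNN for PCOS vs normal classification of whole images.

The network is deliberately small and unusual: all seven convolution
layers use 1x1 kernels at stride 1, arranged in two blocks of three
(each block closed by batch normalization and a stride-1 2x2 max pool)
plus a final widening conv, then one global average pooling and three
fully-connected layers ending in a 2-way softmax.  Because 1x1 kernels
carry no spatial extent, the model classifies images through per-pixel
nonlinear channel mixing pooled over the frame — with the stride-1 max
pools providing the only (local) spatial coupling.  That suits the task:
PCOS and normal frames differ in how much of the field is covered by dark
follicle fluid, a property of the pooled intensity statistics rather than
of precise geometry.

Implemented directly on numpy with hand-written backpropagation; training
uses stochastic gradient descent (constant learning rate 0.001, heavy-ball
momentum 0.9, 10 epochs by default) on softmax cross-entropy.  Everything
is float32 and seeded, so a run is reproducible bit-for-bit on a fixed
BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .phantom import LabeledImage
from .preprocess import GrayImage

__all__ = [
    "FNetConfig",
    "TrainConfig",
    "TrainHistory",
    "FNet",
    "build_fnet",
    "train_fnet",
    "fnet_predict",
]

CLASSES = ("PCOS", "normal")


@dataclass
class FNetConfig:
    """Architecture hyperparameters.

    ``conv_widths`` must list exactly 7 output widths; ``fc_widths``
    exactly 3, the last being 2 (the class count).  ``pool_stride`` of 1
    keeps the feature map size constant (same-padded 2x2 windows); 2 gives
    the conventional halving behaviour.
    """

    input_size: int = 224
    in_channels: int = 3
    conv_widths: tuple[int, ...] = (16, 16, 16, 32, 32, 32, 64)
    fc_widths: tuple[int, ...] = (64, 32, 2)
    pool_stride: int = 1

    def __post_init__(self) -> None:
        if len(self.conv_widths) != 7:
            raise ValueError("F-Net requires exactly 7 convolution layers")
        if len(self.fc_widths) != 3 or self.fc_widths[-1] != 2:
            raise ValueError("F-Net requires 3 FC layers ending in width 2")
        if self.pool_stride not in (1, 2):
            raise ValueError("pool_stride must be 1 or 2")
        if self.input_size < 4:
            raise ValueError("input_size too small")


@dataclass
class TrainConfig:
    """Training hyperparameters: constant-rate momentum SGD on cross-entropy.

    Batch size and momentum matter at this scale: with a few dozen training
    images and only ten epochs, batch 4 gives proportionally more parameter
    updates at the fixed 0.001 learning rate, and heavy-ball momentum 0.9
    consolidates them — without it the decision oscillates near the
    boundary instead of settling within the epoch budget.
    """

    lr: float = 0.001
    momentum: float = 0.9
    epochs: int = 10
    batch_size: int = 4
    val_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr > 0:
            raise ValueError("learning rate must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


# --------------------------------------------------------------------------
# layers (NHWC layout, float32, manual backprop)
# --------------------------------------------------------------------------


class _Momentum:
    """Heavy-ball parameter update shared by all weighted layers."""

    def _step(self, name: str, param: np.ndarray, grad: np.ndarray, lr: float, momentum: float) -> None:
        if momentum > 0:
            buf = getattr(self, "_vel", None)
            if buf is None:
                buf = self._vel = {}
            v = buf.get(name)
            if v is None:
                v = buf[name] = np.zeros_like(param)
            v *= momentum
            v += lr * grad
            param -= v
        else:
            param -= lr * grad


class _Conv1x1(_Momentum):
    kind = "conv"

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray, lr: float, momentum: float = 0.0) -> np.ndarray:
        x2 = self._x.reshape(-1, self.w.shape[0])
        g2 = g.reshape(-1, self.w.shape[1])
        gw = x2.T @ g2
        gb = g2.sum(axis=0)
        gx = g @ self.w.T
        self._step("w", self.w, gw, lr, momentum)
        self._step("b", self.b, gb, lr, momentum)
        return gx


class _ReLU:
    kind = "relu"
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._m = x > 0
        return x * self._m

    def backward(self, g: np.ndarray, lr: float, momentum: float = 0.0) -> np.ndarray:
        return g * self._m


class _BatchNorm(_Momentum):
    kind = "bn"

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.run_mean = np.zeros(channels, dtype=np.float32)
        self.run_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv
        self._n = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, g: np.ndarray, lr: float, momentum: float = 0.0) -> np.ndarray:
        axes = tuple(range(g.ndim - 1))
        ggamma = (g * self._xhat).sum(axis=axes)
        gbeta = g.sum(axis=axes)
        n = self._n
        gx = (self.gamma * self._inv / n) * (
            n * g - gbeta - self._xhat * ggamma
        )
        self._step("gamma", self.gamma, ggamma, lr, momentum)
        self._step("beta", self.beta, gbeta, lr, momentum)
        return gx.astype(np.float32)


class _MaxPool2x2:
    """2x2 max pooling; stride 1 keeps the map size (same padding)."""

    kind = "maxpool"
    n_params = 0

    def __init__(self, stride: int = 1):
        self.stride = stride

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        pad = np.full((n, h + 1, w + 1, c), -np.inf, dtype=x.dtype)
        pad[:, :h, :w] = x
        if self.stride == 1:
            windows = np.stack(
                [pad[:, :h, :w], pad[:, :h, 1 : w + 1], pad[:, 1 : h + 1, :w], pad[:, 1 : h + 1, 1 : w + 1]]
            )
        else:
            ho, wo = h // 2, w // 2
            windows = np.stack(
                [
                    pad[:, 0 : 2 * ho : 2, 0 : 2 * wo : 2],
                    pad[:, 0 : 2 * ho : 2, 1 : 2 * wo : 2],
                    pad[:, 1 : 2 * ho : 2, 0 : 2 * wo : 2],
                    pad[:, 1 : 2 * ho : 2, 1 : 2 * wo : 2],
                ]
            )
        self._arg = windows.argmax(axis=0)
        self._in_shape = x.shape
        return windows.max(axis=0)

    def backward(self, g: np.ndarray, lr: float, momentum: float = 0.0) -> np.ndarray:
        n, h, w, c = self._in_shape
        gx = np.zeros((n, h + 1, w + 1, c), dtype=g.dtype)
        offsets = ((0, 0), (0, 1), (1, 0), (1, 1))
        for k, (dr, dc) in enumerate(offsets):
            m = (self._arg == k) * g
            if self.stride == 1:
                gx[:, dr : h + dr, dc : w + dc] += m
            else:
                ho, wo = g.shape[1], g.shape[2]
                gx[:, dr : 2 * ho : 2, dc : 2 * wo : 2] += m
        return gx[:, :h, :w]


class _GlobalAvgPool:
    kind = "avgpool"
    n_params = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g: np.ndarray, lr: float, momentum: float = 0.0) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :] / (h * w), self._shape).astype(g.dtype)


class _Dense(_Momentum):
    kind = "fc"

    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((din, dout)) * np.sqrt(2.0 / din)).astype(np.float32)
        self.b = np.zeros(dout, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, g: np.ndarray, lr: float, momentum: float = 0.0) -> np.ndarray:
        gw = self._x.T @ g
        gb = g.sum(axis=0)
        gx = g @ self.w.T
        self._step("w", self.w, gw, lr, momentum)
        self._step("b", self.b, gb, lr, momentum)
        return gx


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------


class FNet:
    """The assembled network; see the module docstring for the layout."""

    def __init__(self, config: FNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cw = config.conv_widths
        cin = config.in_channels
        layers: list = []
        widths = [cin, *cw]
        for k in range(7):
            layers.append(_Conv1x1(widths[k], widths[k + 1], rng))
            # BN + max pool close each block of three convs
            if k in (2, 5):
                layers.append(_BatchNorm(widths[k + 1]))
                layers.append(_ReLU())
                layers.append(_MaxPool2x2(config.pool_stride))
            else:
                layers.append(_ReLU())
        layers.append(_GlobalAvgPool())
        d_in = cw[-1]
        for i, d_out in enumerate(config.fc_widths):
            layers.append(_Dense(d_in, d_out, rng))
            if i < len(config.fc_widths) - 1:
                layers.append(_ReLU())
            d_in = d_out
        self.layers = layers

    # -- structural introspection -------------------------------------
    def layer_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for lay in self.layers:
            census[lay.kind] = census.get(lay.kind, 0) + 1
        return census

    def n_parameters(self) -> int:
        return sum(lay.n_params for lay in self.layers)

    # -- forward / loss -------------------------------------------------
    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x
        for lay in self.layers:
            out = lay.forward(out, train)
        return out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.logits(x, train=False))

    def _train_step(
        self, x: np.ndarray, y_idx: np.ndarray, lr: float, momentum: float = 0.0
    ) -> tuple[float, int]:
        logits = self.logits(x, train=True)
        probs = _softmax(logits)
        n = len(x)
        loss = float(-np.log(np.maximum(probs[np.arange(n), y_idx], 1e-12)).mean())
        correct = int((probs.argmax(axis=1) == y_idx).sum())
        g = probs.copy()
        g[np.arange(n), y_idx] -= 1.0
        g /= n
        for lay in reversed(self.layers):
            g = lay.backward(g.astype(np.float32), lr, momentum)
        return loss, correct


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def build_fnet(config: FNetConfig | None = None, seed: int = 0) -> FNet:
    """Construct an (untrained) F-Net from its config."""
    return FNet(config or FNetConfig(), seed=seed)


# --------------------------------------------------------------------------
# data plumbing and training
# --------------------------------------------------------------------------


def images_to_tensor(
    images: list[GrayImage | np.ndarray], input_size: int, in_channels: int = 3
) -> np.ndarray:
    """Stack grayscale images into an (N, S, S, C) float tensor in [0, 1].

    Images are resized to ``input_size`` when needed and the single gray
    channel is replicated across the channel axis.
    """
    out = np.empty((len(images), input_size, input_size, in_channels), dtype=np.float32)
    for k, im in enumerate(images):
        px = im.pixels if isinstance(im, GrayImage) else np.asarray(im, dtype=float)
        px = px / 255.0
        if px.shape != (input_size, input_size):
            px = resize(px, (input_size, input_size), anti_aliasing=True)
        out[k] = px[..., None]
    return out


def _labels_to_idx(labels) -> np.ndarray:
    idx = {c: i for i, c in enumerate(CLASSES)}
    try:
        return np.array([idx[str(lab)] for lab in labels])
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from exc


def _eval(model: FNet, x: np.ndarray, y_idx: np.ndarray, batch: int) -> tuple[float, float]:
    losses, correct = [], 0
    for k in range(0, len(x), batch):
        probs = model.predict_proba(x[k : k + batch])
        yi = y_idx[k : k + batch]
        losses.append(-np.log(np.maximum(probs[np.arange(len(yi)), yi], 1e-12)).sum())
        correct += int((probs.argmax(axis=1) == yi).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train_fnet(
    model: FNet,
    dataset: list[LabeledImage] | tuple[np.ndarray, np.ndarray],
    config: TrainConfig | None = None,
) -> TrainHistory:
    """Train in place on a labeled image set; returns the epoch history.

    The dataset is split 70/30 (stratified, seeded) into training and
    validation; optimization is plain SGD on softmax cross-entropy.
    """
    cfg = config or TrainConfig()
    if isinstance(dataset, tuple):
        x_all, y_all = dataset
        y_idx = _labels_to_idx(y_all)
    else:
        x_all = images_to_tensor(
            [d.image for d in dataset], model.config.input_size, model.config.in_channels
        )
        y_idx = _labels_to_idx([d.label for d in dataset])
    if len(set(y_idx.tolist())) < 2:
        raise ValueError("training requires both classes present")

    rng = np.random.default_rng(cfg.seed)
    # stratified split
    tr_idx, va_idx = [], []
    for cls in np.unique(y_idx):
        members = np.where(y_idx == cls)[0]
        members = members[rng.permutation(len(members))]
        n_val = int(round(cfg.val_fraction * len(members)))
        va_idx.extend(members[:n_val])
        tr_idx.extend(members[n_val:])
    tr = np.array(sorted(tr_idx))
    va = np.array(sorted(va_idx))

    history = TrainHistory()
    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(tr))
        for k in range(0, len(tr), cfg.batch_size):
            sel = tr[order[k : k + cfg.batch_size]]
            model._train_step(x_all[sel], y_idx[sel], cfg.lr, cfg.momentum)
        # history reports end-of-epoch evaluation of the current weights,
        # not the running average over the evolving weights within the epoch
        tl, tacc = _eval(model, x_all[tr], y_idx[tr], cfg.batch_size)
        history.train_loss.append(tl)
        history.train_accuracy.append(tacc)
        if len(va):
            vl, vacc = _eval(model, x_all[va], y_idx[va], cfg.batch_size)
            history.val_loss.append(vl)
            history.val_accuracy.append(vacc)
    return history


def fnet_predict(
    model: FNet, images: list[GrayImage | np.ndarray] | np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Per-image class labels and (N, 2) class probabilities."""
    if isinstance(images, np.ndarray) and images.ndim == 4:
        x = images.astype(np.float32)
    else:
        x = images_to_tensor(list(images), model.config.input_size, model.config.in_channels)
    probs = np.concatenate(
        [model.predict_proba(x[k : k + 16]) for k in range(0, len(x), 16)]
    )
    labels = [CLASSES[i] for i in probs.argmax(axis=1)]
    return labels, probs
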