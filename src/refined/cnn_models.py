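"""CNN architectures and training for feature-image regression/classification.

A small, self-contained numpy CNN engine: valid-padding strided convolution
(im2col), batch normalization, ReLU, dropout (inverted, with a *retain*
probability), dense layers, and the Adam optimizer, with early stopping on
validation loss and best-weight restoration.  Inference uses batch-norm
running statistics and disables dropout, so predictions are independent of
batch size.

Three reference architectures are provided as declarative specs:

* sequential regressor  — two conv layers of 64 7x7 kernels, stride 2, valid
  padding, each with batch norm + ReLU; dense 256 and 64 (BN + ReLU);
  dropout retain 0.7 before a linear output,
* sequential classifier — conv 16 7x7, 32 7x7, 64 3x3 (BN + ReLU each),
  dense 256 and 64, dropout, sigmoid output,
* two-arm hybrid        — separate conv arms for cell-line and drug images
  (60 5x5 stride 1, 72 6x6 stride 2, then 72 5x5 with stride 2 on the cell
  arm and stride 1 on the drug arm), concatenated into dense 305 and 175,
  dropout retain 0.7, linear output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .data import ValidationError

__all__ = [
    "ConvLayerSpec",
    "ArchitectureSpec",
    "TrainConfig",
    "Network",
    "conv_output_size",
    "build_regressor_spec",
    "build_classifier_spec",
    "build_hybrid_spec",
    "train_model",
    "predict",
]


# ---------------------------------------------------------------------------
# architecture specs


@dataclass
class ConvLayerSpec:
    n_kernels: int
    kernel: tuple  # (h, w)
    stride: int = 1
    padding: str = "valid"
    batch_norm: bool = True
    activation: str = "relu"

    def __post_init__(self):
        if self.n_kernels < 1 or self.kernel[0] < 1 or self.kernel[1] < 1 or self.stride < 1:
            raise ValidationError("conv layer sizes must be >= 1")
        if self.padding != "valid":
            raise ValidationError("only valid padding is supported")


@dataclass
class ArchitectureSpec:
    input_shapes: list  # one or two (rows, cols)
    conv_stacks: list  # one list of ConvLayerSpec per input arm
    dense_sizes: list
    dropout_keep: float = 0.7
    head: str = "regression"  # or binary_classification

    def __post_init__(self):
        if not 0 < self.dropout_keep <= 1:
            raise ValidationError("dropout_keep must be in (0, 1]")
        if not self.dense_sizes:
            raise ValidationError("dense_sizes must be nonempty")
        if len(self.input_shapes) != len(self.conv_stacks):
            raise ValidationError("one conv stack per input arm required")
        if self.head not in ("regression", "binary_classification"):
            raise ValidationError(f"unknown head {self.head!r}")


def conv_output_size(in_size: int, kernel: int, stride: int, padding: str = "valid") -> int:
    """floor((in - kernel) / stride) + 1 for valid padding."""
    if padding != "valid":
        raise ValidationError("only valid padding is supported")
    if kernel > in_size:
        raise ValidationError(f"kernel {kernel} larger than input {in_size}")
    return (in_size - kernel) // stride + 1


def _check_stack(shape, stack, arm_name: str):
    h, w = shape
    for li, spec in enumerate(stack):
        kh, kw = spec.kernel
        if kh > h or kw > w:
            raise ValidationError(
                f"{arm_name} conv layer {li}: kernel {kh}x{kw} does not fit input {h}x{w}"
            )
        h = conv_output_size(h, kh, spec.stride)
        w = conv_output_size(w, kw, spec.stride)
    return h, w


def build_regressor_spec(input_shape) -> ArchitectureSpec:
    """Sequential CNN regressor: 2x conv(64, 7x7, stride 2), dense 256/64."""
    conv = [
        ConvLayerSpec(64, (7, 7), stride=2),
        ConvLayerSpec(64, (7, 7), stride=2),
    ]
    _check_stack(input_shape, conv, "regressor")
    return ArchitectureSpec(
        input_shapes=[tuple(input_shape)],
        conv_stacks=[conv],
        dense_sizes=[256, 64],
        dropout_keep=0.7,
        head="regression",
    )


def build_classifier_spec(input_shape) -> ArchitectureSpec:
    """Sequential CNN classifier: conv 16 7x7, 32 7x7, 64 3x3; dense 256/64."""
    conv = [
        ConvLayerSpec(16, (7, 7), stride=1),
        ConvLayerSpec(32, (7, 7), stride=1),
        ConvLayerSpec(64, (3, 3), stride=1),
    ]
    _check_stack(input_shape, conv, "classifier")
    return ArchitectureSpec(
        input_shapes=[tuple(input_shape)],
        conv_stacks=[conv],
        dense_sizes=[256, 64],
        dropout_keep=0.7,
        head="binary_classification",
    )


def build_hybrid_spec(input_shape_cell, input_shape_drug) -> ArchitectureSpec:
    """Two-arm CNN: cell arm last conv stride 2, drug arm stride 1; dense 305/175."""
    cell_arm = [
        ConvLayerSpec(60, (5, 5), stride=1),
        ConvLayerSpec(72, (6, 6), stride=2),
        ConvLayerSpec(72, (5, 5), stride=2),
    ]
    drug_arm = [
        ConvLayerSpec(60, (5, 5), stride=1),
        ConvLayerSpec(72, (6, 6), stride=2),
        ConvLayerSpec(72, (5, 5), stride=1),
    ]
    _check_stack(input_shape_cell, cell_arm, "cell arm")
    _check_stack(input_shape_drug, drug_arm, "drug arm")
    return ArchitectureSpec(
        input_shapes=[tuple(input_shape_cell), tuple(input_shape_drug)],
        conv_stacks=[cell_arm, drug_arm],
        dense_sizes=[305, 175],
        dropout_keep=0.7,
        head="regression",
    )


# ---------------------------------------------------------------------------
# layers


def _im2col(x, kh, kw, stride):
    b, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(b, ho, wo, c, kh, kw),
        strides=(s0, s2 * stride, s3 * stride, s1, s2, s3),
    )
    return np.ascontiguousarray(cols).reshape(b, ho, wo, c * kh * kw), ho, wo


class _Conv2D:
    def __init__(self, in_ch, spec: ConvLayerSpec, rng):
        kh, kw = spec.kernel
        fan_in = in_ch * kh * kw
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(spec.n_kernels, in_ch, kh, kw))
        self.b = np.zeros(spec.n_kernels)
        self.stride = spec.stride
        self.kernel = (kh, kw)
        self.params = ["w", "b"]

    def forward(self, x, train):
        self.x_shape = x.shape
        kh, kw = self.kernel
        cols, ho, wo = _im2col(x, kh, kw, self.stride)
        self.cols = cols
        f = self.w.shape[0]
        out = cols @ self.w.reshape(f, -1).T + self.b
        return out.transpose(0, 3, 1, 2)  # (B, F, Ho, Wo)

    def backward(self, grad):
        b, f, ho, wo = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, f)
        cols = self.cols.reshape(-1, self.cols.shape[-1])
        self.gw = (g.T @ cols).reshape(self.w.shape)
        self.gb = g.sum(axis=0)
        dcols = (g @ self.w.reshape(f, -1)).reshape(b, ho, wo, -1)
        _, c, h, w = self.x_shape
        kh, kw = self.kernel
        dcols = dcols.reshape(b, ho, wo, c, kh, kw)
        dx = np.zeros(self.x_shape)
        s = self.stride
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dx


class _BatchNorm:
    """Batch norm over the batch (and spatial dims for conv inputs)."""

    def __init__(self, n_features, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.params = ["gamma", "beta"]

    def _flatten(self, x):
        if x.ndim == 4:  # (B, C, H, W) -> (B*H*W, C)
            self.conv_shape = x.shape
            return x.transpose(0, 2, 3, 1).reshape(-1, x.shape[1])
        self.conv_shape = None
        return x

    def _unflatten(self, x):
        if self.conv_shape is None:
            return x
        b, c, h, w = self.conv_shape
        return x.reshape(b, h, w, c).transpose(0, 3, 1, 2)

    def forward(self, x, train):
        flat = self._flatten(x)
        if train:
            mean = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self.std = np.sqrt(var + self.eps)
        self.xhat = (flat - mean) / self.std
        self.m = flat.shape[0]
        return self._unflatten(self.gamma * self.xhat + self.beta)

    def backward(self, grad):
        g = self._flatten(grad)
        self.ggamma = (g * self.xhat).sum(axis=0)
        self.gbeta = g.sum(axis=0)
        dxhat = g * self.gamma
        m = self.m
        dx = (dxhat - dxhat.mean(axis=0) - self.xhat * (dxhat * self.xhat).mean(axis=0)) / self.std
        return self._unflatten(dx)

    @property
    def gw(self):
        return self.ggamma

    @property
    def gb(self):
        return self.gbeta


class _ReLU:
    params: list = []

    def forward(self, x, train):
        self.mask = x > 0
        return x * self.mask

    def backward(self, grad):
        return grad * self.mask


class _Flatten:
    params: list = []

    def forward(self, x, train):
        self.shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self.shape)


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = ["w", "b"]

    def forward(self, x, train):
        self.x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self.x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T


class _Dropout:
    """Inverted dropout parameterized by the retain probability."""

    params: list = []

    def __init__(self, keep, rng):
        self.keep = keep
        self.rng = rng

    def forward(self, x, train):
        if not train or self.keep >= 1.0:
            self.mask = None
            return x
        self.mask = (self.rng.uniform(size=x.shape) < self.keep) / self.keep
        return x * self.mask

    def backward(self, grad):
        return grad if self.mask is None else grad * self.mask


class _Adam:
    def __init__(self, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict = {}

    def step(self, layers):
        self.t += 1
        for li, layer in enumerate(layers):
            grads = {"w": "gw", "b": "gb", "gamma": "ggamma", "beta": "gbeta"}
            for pname in getattr(layer, "params", []):
                key = (li, pname)
                param = getattr(layer, pname)
                grad = getattr(layer, grads[pname])
                if key not in self.state:
                    self.state[key] = (np.zeros_like(param), np.zeros_like(param))
                m, v = self.state[key]
                m = self.beta1 * m + (1 - self.beta1) * grad
                v = self.beta2 * v + (1 - self.beta2) * grad**2
                self.state[key] = (m, v)
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                setattr(layer, pname, param - self.lr * mhat / (np.sqrt(vhat) + self.eps))


# ---------------------------------------------------------------------------
# network


class Network:
    """A spec-built network with one or two convolutional arms."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.arms = []
        flat_total = 0
        for shape, stack in zip(spec.input_shapes, spec.conv_stacks):
            layers = []
            in_ch = 1
            h, w = shape
            for li, cspec in enumerate(stack):
                kh, kw = cspec.kernel
                if kh > h or kw > w:
                    raise ValidationError(
                        f"conv layer {li}: kernel {kh}x{kw} does not fit {h}x{w}"
                    )
                layers.append(_Conv2D(in_ch, cspec, rng))
                h = conv_output_size(h, kh, cspec.stride)
                w = conv_output_size(w, kw, cspec.stride)
                if cspec.batch_norm:
                    layers.append(_BatchNorm(cspec.n_kernels))
                layers.append(_ReLU())
                in_ch = cspec.n_kernels
            layers.append(_Flatten())
            self.arms.append(layers)
            flat_total += in_ch * h * w

        self.trunk = []
        n_in = flat_total
        for size in spec.dense_sizes:
            self.trunk.append(_Dense(n_in, size, rng))
            self.trunk.append(_BatchNorm(size))
            self.trunk.append(_ReLU())
            n_in = size
        self.trunk.append(_Dropout(spec.dropout_keep, rng))
        self.trunk.append(_Dense(n_in, 1, rng))

    @property
    def all_layers(self):
        return [layer for arm in self.arms for layer in arm] + self.trunk

    def n_parameters(self) -> int:
        total = 0
        for layer in self.all_layers:
            for pname in getattr(layer, "params", []):
                total += getattr(layer, pname).size
        return total

    def _as_batches(self, inputs):
        if len(self.arms) == 1 and not isinstance(inputs, (list, tuple)):
            inputs = [inputs]
        if len(inputs) != len(self.arms):
            raise ValidationError(f"expected {len(self.arms)} input sets, got {len(inputs)}")
        out = []
        for x, shape in zip(inputs, self.spec.input_shapes):
            x = np.asarray(x, dtype=float)
            if x.ndim == 3:
                x = x[:, None, :, :]
            if x.shape[2:] != tuple(shape):
                raise ValidationError(f"image shape {x.shape[2:]} != spec {tuple(shape)}")
            out.append(x)
        return out

    def forward(self, inputs, train=False):
        xs = self._as_batches(inputs)
        flats = []
        self._arm_widths = []
        for layers, x in zip(self.arms, xs):
            for layer in layers:
                x = layer.forward(x, train)
            flats.append(x)
            self._arm_widths.append(x.shape[1])
        z = np.concatenate(flats, axis=1)
        for layer in self.trunk:
            z = layer.forward(z, train)
        z = z[:, 0]
        if self.spec.head == "binary_classification":
            self._logits = z
            return 1.0 / (1.0 + np.exp(-z))
        return z

    def backward(self, grad_out):
        g = grad_out[:, None]
        for layer in reversed(self.trunk):
            g = layer.backward(g)
        offset = 0
        for layers, width in zip(self.arms, self._arm_widths):
            ga = g[:, offset : offset + width]
            offset += width
            for layer in reversed(layers):
                ga = layer.backward(ga)

    def loss_and_grad(self, inputs, y):
        """Mean loss and the gradient w.r.t. the pre-head output."""
        y = np.asarray(y, dtype=float)
        pred = self.forward(inputs, train=True)
        n = y.size
        if self.spec.head == "binary_classification":
            p = np.clip(pred, 1e-12, 1 - 1e-12)
            loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
            grad = (pred - y) / n  # gradient w.r.t. the logit
        else:
            loss = float(np.mean((pred - y) ** 2))
            grad = 2.0 * (pred - y) / n
        return loss, grad

    def evaluate_loss(self, inputs, y, batch_size=256):
        y = np.asarray(y, dtype=float)
        preds = self.predict(inputs, batch_size=batch_size)
        if self.spec.head == "binary_classification":
            p = np.clip(preds, 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return float(np.mean((preds - y) ** 2))

    def predict(self, inputs, batch_size=256):
        xs = self._as_batches(inputs)
        n = xs[0].shape[0]
        out = np.empty(n)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            out[sl] = self.forward([x[sl] for x in xs], train=False)
        return out

    def get_weights(self):
        return copy.deepcopy(
            [
                {p: getattr(layer, p) for p in getattr(layer, "params", [])}
                | (
                    {"running_mean": layer.running_mean, "running_var": layer.running_var}
                    if isinstance(layer, _BatchNorm)
                    else {}
                )
                for layer in self.all_layers
            ]
        )

    def set_weights(self, weights):
        for layer, wdict in zip(self.all_layers, weights):
            for name, value in wdict.items():
                setattr(layer, name, value.copy())


@dataclass
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 128
    seed: int = 0
    early_stop_patience: int = 20


def train_model(spec: ArchitectureSpec, images, targets, split, train_cfg: TrainConfig):
    """Train a network built from a spec; returns (network, history DataFrame).

    ``images`` is one array (n, rows, cols) or a list of two for the hybrid
    architecture; ``split`` is (train_indices, val_indices).  The best
    validation-loss weights are restored at the end.
    """
    import pandas as pd

    if not isinstance(images, (list, tuple)):
        images = [images]
    if len(images) != len(spec.input_shapes):
        raise ValidationError(
            f"architecture expects {len(spec.input_shapes)} image sets, got {len(images)}"
        )
    images = [np.asarray(x, dtype=float) for x in images]
    targets = np.asarray(targets, dtype=float)
    train_idx, val_idx = (np.asarray(ix) for ix in split)
    if np.intersect1d(train_idx, val_idx).size:
        raise ValidationError("train/validation indices overlap")

    net = Network(spec, seed=train_cfg.seed)
    opt = _Adam(lr=train_cfg.lr)
    rng = np.random.default_rng(train_cfg.seed + 1)

    x_train = [x[train_idx] for x in images]
    y_train = targets[train_idx]
    x_val = [x[val_idx] for x in images]
    y_val = targets[val_idx]

    history = {"epoch": [], "train_loss": [], "val_loss": []}
    best_val = np.inf
    best_weights = net.get_weights()
    patience_left = train_cfg.early_stop_patience
    n = y_train.size
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start : start + train_cfg.batch_size]
            if idx.size < 2:
                continue  # batch norm needs at least 2 samples
            loss, grad = net.loss_and_grad([x[idx] for x in x_train], y_train[idx])
            net.backward(grad)
            opt.step(net.all_layers)
            epoch_loss += loss
            n_batches += 1
        val_loss = net.evaluate_loss(x_val, y_val) if y_val.size else np.nan
        history["epoch"].append(epoch)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        if not np.isfinite(history["train_loss"][-1]):
            raise ValidationError(f"non-finite training loss at epoch {epoch}")
        if y_val.size and val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = net.get_weights()
            patience_left = train_cfg.early_stop_patience
        elif y_val.size:
            patience_left -= 1
            if patience_left <= 0:
                break
    if y_val.size:
        net.set_weights(best_weights)
    return net, pd.DataFrame(history)


def predict(model: Network, images, batch_size: int = 256) -> np.ndarray:
    """One prediction per sample; classifier outputs are probabilities in [0, 1]."""
    if not isinstance(images, (list, tuple)):
        images = [images]
    return model.predict([np.asarray(x, dtype=float) for x in images], batch_size=batch_size)
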