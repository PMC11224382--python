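"""The residual-network classifier for fused pod data and its training loop.

Architecture (defaults): a conv1 stage (kernel 3, stride 1, padding 1, 4->64
channels, batch norm, ReLU), then Layer1 = two plain residual modules and
Layer2-4 = one downsampling convolutional module plus one plain residual
module each — 8 modules in total — followed by global average pooling and a
linear head to the 4 freshness classes.

Every module computes ``activation(h(x) + F(x, w))`` where the branch F is
conv -> batchnorm -> ReLU -> conv -> batchnorm.  In plain residual modules
the direct mapping h is the identity; in downsampling modules the branch's
first convolution has stride 2 and h is a kernel-1 convolution (stride 2,
batch-normed) so the two paths keep matching shapes.  Channel widths double
at each downsampling stage (64/128/256/512 at full width).

Training uses Adam on softmax cross-entropy with a stratified 70/30 split.
By default the final-epoch weights are reported; best-epoch retention (by
training loss) is available behind ``keep_best``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import DegenerateInputError, ShapeError
from .fusion import FusedSample
from .nnet import (
    Adam,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    ReLU,
    softmax_cross_entropy,
)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Structural parameters of the classifier."""

    in_channels: int = 4
    n_classes: int = 4
    base_channels: int = 64

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.n_classes < 2:
            raise ShapeError("need in_channels >= 1 and n_classes >= 2")


def residual_forward(x: np.ndarray, branch, shortcut=None, activation: str | None = "relu"):
    """Functional residual computation ``activation(h(x) + F(x))``.

    ``branch`` and ``shortcut`` are callables on arrays; ``shortcut=None``
    means the identity direct mapping.  ``activation=None`` returns the raw
    pre-activation sum (useful for checking the telescoped sum identity
    x_L = x_l + sum_i F(x_i)).
    """
    fx = branch(x)
    hx = x if shortcut is None else shortcut(x)
    if fx.shape != hx.shape:
        raise ShapeError(f"branch {fx.shape} and shortcut {hx.shape} shapes differ")
    y = hx + fx
    if activation is None:
        return y
    if activation != "relu":
        raise ShapeError(f"unknown activation {activation!r}")
    return np.maximum(y, 0.0)


class _Branch:
    """conv -> bn -> relu -> conv -> bn residual mapping."""

    def __init__(self, in_c: int, out_c: int, stride: int, rng: np.random.Generator):
        self.layers: list[Layer] = [
            Conv2d(in_c, out_c, 3, stride=stride, pad=1, rng=rng),
            BatchNorm2d(out_c),
            ReLU(),
            Conv2d(out_c, out_c, 3, stride=1, pad=1, rng=rng),
            BatchNorm2d(out_c),
        ]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()


class ResidualModule:
    """Plain residual module: identity shortcut, relu(x + F(x))."""

    kind = "residual"

    def __init__(self, channels: int, rng: np.random.Generator):
        self.branch = _Branch(channels, channels, stride=1, rng=rng)
        self.relu = ReLU()

    def forward(self, x, train=True):
        self._x_shape = x.shape
        return self.relu.forward(x + self.branch.forward(x, train), train)

    def backward(self, dout):
        dsum = self.relu.backward(dout)
        return dsum + self.branch.backward(dsum)

    def parameters(self):
        yield from self.branch.parameters()


class DownsampleModule:
    """Downsampling convolutional module: stride-2 branch, kernel-1 shortcut."""

    kind = "downsample"

    def __init__(self, in_c: int, out_c: int, rng: np.random.Generator):
        self.branch = _Branch(in_c, out_c, stride=2, rng=rng)
        self.short_conv = Conv2d(in_c, out_c, 1, stride=2, pad=0, rng=rng)
        self.short_bn = BatchNorm2d(out_c)
        self.relu = ReLU()

    def forward(self, x, train=True):
        hx = self.short_bn.forward(self.short_conv.forward(x, train), train)
        return self.relu.forward(hx + self.branch.forward(x, train), train)

    def backward(self, dout):
        dsum = self.relu.backward(dout)
        dshort = self.short_conv.backward(self.short_bn.backward(dsum))
        return dshort + self.branch.backward(dsum)

    def parameters(self):
        yield from self.branch.parameters()
        yield from self.short_conv.parameters()
        yield from self.short_bn.parameters()


class ResNetRH:
    """conv1 + Layer1-4 (8 modules) + global average pool + linear head.

    External input contract is channels-last ``(n, rows, cols, channels)``;
    arrays are transposed to NCHW internally.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        c = spec.base_channels
        self.conv1 = Conv2d(spec.in_channels, c, 3, stride=1, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(c)
        self.relu1 = ReLU()
        self.modules = [
            ResidualModule(c, rng),
            ResidualModule(c, rng),
            DownsampleModule(c, 2 * c, rng),
            ResidualModule(2 * c, rng),
            DownsampleModule(2 * c, 4 * c, rng),
            ResidualModule(4 * c, rng),
            DownsampleModule(4 * c, 8 * c, rng),
            ResidualModule(8 * c, rng),
        ]
        self.pool = GlobalAvgPool()
        self.fc = Linear(8 * c, spec.n_classes, rng=rng)

    def parameters(self):
        yield from self.conv1.parameters()
        yield from self.bn1.parameters()
        for m in self.modules:
            yield from m.parameters()
        yield from self.fc.parameters()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits for a channels-last batch (n, rows, cols, in_channels)."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[3] != self.spec.in_channels:
            raise ShapeError(
                f"expected (n, rows, cols, {self.spec.in_channels}) input, got {x.shape}"
            )
        h = x.transpose(0, 3, 1, 2)
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(h, train), train), train)
        for m in self.modules:
            h = m.forward(h, train)
        return self.fc.forward(self.pool.forward(h, train), train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.pool.backward(self.fc.backward(dlogits))
        for m in reversed(self.modules):
            d = m.backward(d)
        self.conv1.backward(self.bn1.backward(self.relu1.backward(d)))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.parameters(), weights, strict=True):
            p[...] = w


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> ResNetRH:
    """Construct the classifier (optionally RGB-only/spectral-only via in_channels)."""
    return ResNetRH(spec or ArchitectureSpec(), seed=seed)


def audit(model: ResNetRH) -> dict:
    """Structural report: input channels, classes, module count and kinds."""
    return {
        "in_channels": model.spec.in_channels,
        "n_classes": model.spec.n_classes,
        "n_modules": len(model.modules),
        "module_kinds": [m.kind for m in model.modules],
        "n_parameters": int(sum(p.size for p, _ in model.parameters())),
    }


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    train_fraction: float = 0.70
    keep_best: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ShapeError("train fraction must lie in (0, 1)")
        if self.epochs < 1:
            raise ShapeError("need at least one epoch")
        if self.optimizer != "adam":
            raise ShapeError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainResult:
    model: ResNetRH
    history: pd.DataFrame
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None


def _to_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        return np.asarray(dataset[0], dtype=float), np.asarray(dataset[1], dtype=int)
    if len(dataset) and isinstance(dataset[0], FusedSample):
        return (
            np.stack([s.tensor for s in dataset]),
            np.array([s.label for s in dataset], dtype=int),
        )
    raise ShapeError("dataset must be (X, y) arrays or a list of fused samples")


def stratified_split(
    labels: np.ndarray, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split; the test share is rounded up (416 -> 125 test)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise DegenerateInputError("stratified split needs at least two classes")
    idx = np.arange(labels.size)
    # integer test count with an exact ceiling (0.30 of 416 -> 125), immune
    # to binary-fraction rounding of the fraction itself
    n_test = int(np.ceil(np.round(labels.size * (1.0 - train_fraction), 9)))
    train_idx, test_idx = train_test_split(
        idx, test_size=n_test, random_state=seed, stratify=labels
    )
    return np.sort(train_idx), np.sort(test_idx)


def fit(
    model: ResNetRH,
    x_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
) -> pd.DataFrame:
    """Train on a prepared split; returns the per-epoch loss/accuracy history."""
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise DegenerateInputError("training split contains fewer than two classes")
    rng = np.random.default_rng(config.seed)
    opt = Adam(list(model.parameters()), lr=config.learning_rate)
    records = []
    best_loss, best_weights = np.inf, None
    n = y_train.size
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            logits = model.forward(x_train[sel], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_train[sel])
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * sel.size
            correct += int((logits.argmax(axis=1) == y_train[sel]).sum())
        mean_loss = epoch_loss / n
        records.append(
            {"epoch": epoch, "loss": mean_loss, "accuracy": correct / n}
        )
        if config.keep_best and mean_loss < best_loss:
            best_loss, best_weights = mean_loss, model.get_weights()
    if config.keep_best and best_weights is not None:
        model.set_weights(best_weights)
    return pd.DataFrame.from_records(records)


def train(model: ResNetRH, dataset, config: TrainConfig) -> TrainResult:
    """Stratified 70/30 split by seed, then fit on the training portion."""
    x, y = _to_arrays(dataset)
    train_idx, test_idx = stratified_split(y, config.train_fraction, config.seed)
    history = fit(model, x[train_idx], y[train_idx], config)
    return TrainResult(model=model, history=history, train_idx=train_idx, test_idx=test_idx)


def predict(model: ResNetRH, samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class codes (argmax, lowest index on ties) and raw scores, eval mode."""
    x = np.asarray(samples, dtype=float)
    if x.ndim == 3:
        x = x[None]
    scores = model.forward(x, train=False)
    return scores.argmax(axis=1), scores
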