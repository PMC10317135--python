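"""The four chop-classifier architectures and their training.

AlexNet (8 weight layers), VGG-16 (16), ResNet-50 (50) and SqueezeNet
(18) are built at their canonical channel configurations; a
``width_multiplier`` in (0, 1] scales all channel counts down for
CPU-scale training runs without changing the layer audit.  Grayscale
chops are replicated to three channels so the canonical stem shapes
(and therefore the published parameter counts) are preserved.

Depth accounting follows the usual convention: a weight layer is a
convolutional or fully connected layer; parallel branches at the same
depth (fire-module expands, residual shortcuts) count once.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from . import nn
from .nn import core
from .nn.core import Tensor
from .nn.layers import (
    AdaptiveAvgPool2d,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Flatten,
    Linear,
    MaxPool2d,
    Module,
    ModuleList,
    ReLU,
    Sequential,
)

ARCH_NAMES = ("alexnet", "vgg16", "resnet50", "squeezenet")


@dataclass(frozen=True)
class ArchSpec:
    """Which network to build and at what scale."""

    name: str
    num_classes: int
    input_size: int = 256
    width_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ARCH_NAMES:
            raise ValueError(f"unknown architecture {self.name!r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if not 0.0 < self.width_multiplier <= 1.0:
            raise ValueError("width_multiplier must be in (0, 1]")


def _scaled(channels: int, width: float) -> int:
    return max(1, round(channels * width))


class Fire(Module):
    """SqueezeNet fire module: 1x1 squeeze feeding parallel 1x1/3x3 expands.

    Depth 2: the squeeze stage plus the expand stage (the two expand
    convolutions sit in parallel and count once).
    """

    def __init__(self, in_c: int, squeeze: int, expand1: int, expand3: int, rng):
        super().__init__()
        self.squeeze = Conv2d(in_c, squeeze, 1, rng=rng)
        self.expand1 = Conv2d(squeeze, expand1, 1, rng=rng)
        self.expand3 = Conv2d(squeeze, expand3, 3, padding=1, rng=rng)

    def weight_depth(self) -> int:
        return self.squeeze.weight_depth() + max(
            self.expand1.weight_depth(), self.expand3.weight_depth()
        )

    def forward(self, x: Tensor) -> Tensor:
        s = core.relu(self.squeeze(x))
        return core.relu(core.concat([self.expand1(s), self.expand3(s)], axis=1))


class Bottleneck(Module):
    """ResNet bottleneck block (1x1 - 3x3 - 1x1) with identity shortcut.

    Depth 3: the shortcut (identity or 1x1 projection) runs in parallel
    with the three-convolution main branch and counts once, i.e. as the
    deeper of the two branches.
    """

    expansion = 4

    def __init__(self, in_c: int, planes: int, stride: int, rng):
        super().__init__()
        out_c = planes * self.expansion
        self.conv1 = Conv2d(in_c, planes, 1, rng=rng)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, stride=stride, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(planes, out_c, 1, rng=rng)
        self.bn3 = BatchNorm2d(out_c)
        self.has_projection = stride != 1 or in_c != out_c
        if self.has_projection:
            self.proj = Conv2d(in_c, out_c, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm2d(out_c)

    def weight_depth(self) -> int:
        main = (
            self.conv1.weight_depth()
            + self.conv2.weight_depth()
            + self.conv3.weight_depth()
        )
        shortcut = self.proj.weight_depth() if self.has_projection else 0
        return max(main, shortcut)

    def forward(self, x: Tensor) -> Tensor:
        out = core.relu(self.bn1(self.conv1(x)))
        out = core.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        short = self.proj_bn(self.proj(x)) if self.has_projection else x
        return core.relu(core.add(out, short))


class _Classifier(Module):
    """Common wrapper: features -> head -> logits (N, num_classes)."""

    def __init__(self, spec: ArchSpec):
        super().__init__()
        self.spec = spec

    def forward(self, x: Tensor) -> Tensor:
        raise NotImplementedError


class _SequentialClassifier(_Classifier):
    def __init__(self, spec: ArchSpec, body: Sequential):
        super().__init__(spec)
        self.body = body

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


def _build_alexnet(spec: ArchSpec, rng) -> _Classifier:
    w = spec.width_multiplier
    s = lambda c: _scaled(c, w)
    body = Sequential(
        Conv2d(3, s(64), 11, stride=4, padding=2, rng=rng), ReLU(),
        MaxPool2d(3, 2),
        Conv2d(s(64), s(192), 5, padding=2, rng=rng), ReLU(),
        MaxPool2d(3, 2),
        Conv2d(s(192), s(384), 3, padding=1, rng=rng), ReLU(),
        Conv2d(s(384), s(256), 3, padding=1, rng=rng), ReLU(),
        Conv2d(s(256), s(256), 3, padding=1, rng=rng), ReLU(),
        MaxPool2d(3, 2),
        AdaptiveAvgPool2d(6, 6),
        Flatten(),
        Dropout(0.5),
        Linear(s(256) * 36, s(4096), rng=rng), ReLU(),
        Dropout(0.5),
        Linear(s(4096), s(4096), rng=rng), ReLU(),
        Linear(s(4096), spec.num_classes, rng=rng),
    )
    return _SequentialClassifier(spec, body)


_VGG16_CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M")


def _build_vgg16(spec: ArchSpec, rng) -> _Classifier:
    w = spec.width_multiplier
    s = lambda c: _scaled(c, w)
    layers: list[Module] = []
    in_c = 3
    for item in _VGG16_CFG:
        if item == "M":
            layers.append(MaxPool2d(2, 2))
        else:
            layers += [Conv2d(in_c, s(item), 3, padding=1, rng=rng), ReLU()]
            in_c = s(item)
    layers += [
        AdaptiveAvgPool2d(7, 7),
        Flatten(),
        Linear(s(512) * 49, s(4096), rng=rng), ReLU(), Dropout(0.5),
        Linear(s(4096), s(4096), rng=rng), ReLU(), Dropout(0.5),
        Linear(s(4096), spec.num_classes, rng=rng),
    ]
    return _SequentialClassifier(spec, Sequential(*layers))


def _build_resnet50(spec: ArchSpec, rng) -> _Classifier:
    w = spec.width_multiplier
    s = lambda c: _scaled(c, w)
    blocks: list[Module] = [
        Conv2d(3, s(64), 7, stride=2, padding=3, rng=rng),
        BatchNorm2d(s(64)), ReLU(),
        MaxPool2d(3, 2, padding=1),
    ]
    in_c = s(64)
    for planes, count, first_stride in (
        (64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)
    ):
        for i in range(count):
            blocks.append(
                Bottleneck(in_c, s(planes), first_stride if i == 0 else 1, rng)
            )
            in_c = s(planes) * Bottleneck.expansion
    blocks += [
        AdaptiveAvgPool2d(1, 1), Flatten(),
        Linear(in_c, spec.num_classes, rng=rng),
    ]
    return _SequentialClassifier(spec, Sequential(*blocks))


def _build_squeezenet(spec: ArchSpec, rng) -> _Classifier:
    w = spec.width_multiplier
    s = lambda c: _scaled(c, w)
    fire = lambda i, sq, e: Fire(s(i), s(sq), s(e), s(e), rng)
    body = Sequential(
        Conv2d(3, s(96), 7, stride=2, rng=rng), ReLU(),
        MaxPool2d(3, 2),
        fire(96, 16, 64),
        fire(128, 16, 64),
        fire(128, 32, 128),
        MaxPool2d(3, 2),
        fire(256, 32, 128),
        fire(256, 48, 192),
        fire(384, 48, 192),
        fire(384, 64, 256),
        MaxPool2d(3, 2),
        fire(512, 64, 256),
        Dropout(0.5),
        Conv2d(s(512), spec.num_classes, 1, rng=rng), ReLU(),
        AdaptiveAvgPool2d(1, 1),
        Flatten(),
    )
    return _SequentialClassifier(spec, body)


_BUILDERS = {
    "alexnet": _build_alexnet,
    "vgg16": _build_vgg16,
    "resnet50": _build_resnet50,
    "squeezenet": _build_squeezenet,
}


def build_architecture(spec: ArchSpec, seed: int = 0) -> _Classifier:
    """Construct one of the four classifier architectures."""
    rng = np.random.default_rng(seed)
    model = _BUILDERS[spec.name](spec, rng)
    model.eval()
    return model


def count_weight_layers(model: Module) -> int:
    """Serial depth in weight layers (convolutional + fully connected)."""
    return model.weight_depth()


def count_parameters(model: Module) -> int:
    """Exact number of trainable weights and biases."""
    return sum(p.data.size for p in model.parameters())


# ---------------------------------------------------------------------
# preprocessing and prediction
# ---------------------------------------------------------------------

#: fixed input standardization (mid-gray mean, plate-image spread);
#: applied identically at train and predict time
_INPUT_MEAN = 0.5
_INPUT_SD = 0.25


def prepare_chops(chops: np.ndarray, input_size: int) -> np.ndarray:
    """(N, H, W) grayscale chops in [0, 1] -> (N, 3, S, S) network input.

    Chops are resized (anti-aliased) when their size differs from the
    network input size, standardized with fixed constants, and
    replicated across three channels.
    """
    chops = np.asarray(chops, dtype=np.float64)
    if chops.ndim == 2:
        chops = chops[None]
    n, h, w = chops.shape
    if (h, w) != (input_size, input_size):
        out = np.empty((n, input_size, input_size))
        for i in range(n):
            out[i] = resize(chops[i], (input_size, input_size), anti_aliasing=h > input_size)
        chops = out
    chops = (chops - _INPUT_MEAN) / _INPUT_SD
    return np.repeat(chops[:, None], 3, axis=1)


def predict_proba(model: _Classifier, chops: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class probabilities for a stack of grayscale chops."""
    x = prepare_chops(chops, model.spec.input_size).astype(model.dtype)
    model.eval()
    out = []
    for i in range(0, len(x), batch_size):
        logits = model(Tensor(x[i : i + batch_size]))
        out.append(core.softmax(logits.data))
    return np.concatenate(out, axis=0)


def predict_chop(model: _Classifier, chop: np.ndarray) -> np.ndarray:
    """Probability vector for a single chop."""
    return predict_proba(model, chop[None])[0]


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Stepwise-LR training configuration.

    The learning rate starts at ``initial_lr`` and is divided by
    ``lr_drop_factor`` whenever the validation loss stagnates for
    ``plateau_patience`` epochs, flooring at ``final_lr``.
    """

    initial_lr: float = 1e-2
    final_lr: float = 1e-5
    lr_drop_factor: float = 10.0
    plateau_patience: int = 3
    epochs: int = 20
    batch_size: int = 32
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.initial_lr > self.final_lr > 0:
            raise ValueError("need initial_lr > final_lr > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainReport:
    """Per-epoch accounting: accuracy/top-5/loss for train and validation."""

    train_acc: list[float] = field(default_factory=list)
    train_top5: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    val_top5: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    epoch_seconds: list[float] = field(default_factory=list)


def _topk_hits(logits: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    k = min(k, logits.shape[1])
    topk = np.argpartition(-logits, k - 1, axis=1)[:, :k]
    return (topk == labels[:, None]).any(axis=1)


def evaluate(model: _Classifier, x: np.ndarray, labels: np.ndarray,
             batch_size: int = 64) -> tuple[float, float, float]:
    """(accuracy %, top-5 accuracy %, mean loss) on prepared input x."""
    model.eval()
    losses, hit1, hit5 = [], [], []
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], labels[i : i + batch_size]
        logits = model(Tensor(xb)).data
        lsm = core.log_softmax(logits)
        losses.append(-lsm[np.arange(len(yb)), yb].sum())
        hit1.append(_topk_hits(logits, yb, 1).sum())
        hit5.append(_topk_hits(logits, yb, 5).sum())
    n = len(labels)
    return (
        100.0 * sum(hit1) / n,
        100.0 * sum(hit5) / n,
        float(sum(losses) / n),
    )


def train_classifier(
    model: _Classifier,
    train_chops: np.ndarray,
    train_labels: np.ndarray,
    val_chops: np.ndarray,
    val_labels: np.ndarray,
    config: TrainConfig,
) -> tuple[_Classifier, TrainReport]:
    """SGD-with-momentum training under the plateau LR schedule.

    Deterministic for a fixed seed on one machine.  Labels must be
    integer indices in ``[0, num_classes)``.
    """
    k = model.spec.num_classes
    for arr in (train_labels, val_labels):
        if len(arr) == 0:
            raise ValueError("empty training or validation set")
        if arr.min() < 0 or arr.max() >= k:
            raise ValueError(f"labels outside [0, {k})")
    # single precision: halves CPU time, still deterministic per seed
    model.astype(np.float32)
    xtr = prepare_chops(train_chops, model.spec.input_size).astype(np.float32)
    xva = prepare_chops(val_chops, model.spec.input_size).astype(np.float32)
    ytr = np.asarray(train_labels)
    yva = np.asarray(val_labels)

    rng = np.random.default_rng(config.seed)
    model.set_rng(rng)
    opt = nn.SGD(model.parameters(), lr=config.initial_lr, momentum=config.momentum)
    sched = nn.ReduceLROnPlateau(
        opt,
        factor=config.lr_drop_factor,
        patience=config.plateau_patience,
        min_lr=config.final_lr,
    )
    report = TrainReport()
    for _ in range(config.epochs):
        t0 = time.perf_counter()
        model.train()
        order = rng.permutation(len(xtr))
        ep_loss, ep_hit1, ep_hit5 = 0.0, 0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            opt.zero_grad()
            logits = model(Tensor(xb, requires_grad=False))
            loss = core.cross_entropy(logits, yb)
            loss.backward()
            opt.step()
            ep_loss += loss.data.item() * len(idx)
            ep_hit1 += _topk_hits(logits.data, yb, 1).sum()
            ep_hit5 += _topk_hits(logits.data, yb, 5).sum()
        n = len(order)
        va, v5, vl = evaluate(model, xva, yva)
        report.train_acc.append(100.0 * ep_hit1 / n)
        report.train_top5.append(100.0 * ep_hit5 / n)
        report.train_loss.append(ep_loss / n)
        report.val_acc.append(va)
        report.val_top5.append(v5)
        report.val_loss.append(vl)
        report.lr.append(sched.lr)
        report.epoch_seconds.append(time.perf_counter() - t0)
        sched.step(vl)
    model.eval()
    return model, report


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

def save_classifier(path, model: _Classifier) -> None:
    spec = model.spec
    nn.io.save_model(path, model, {
        "kind": "classifier",
        "name": spec.name,
        "num_classes": spec.num_classes,
        "input_size": spec.input_size,
        "width_multiplier": spec.width_multiplier,
    })


def load_classifier(path) -> _Classifier:
    cfg = nn.io.read_config(path)
    if cfg.get("kind") != "classifier":
        raise ValueError(f"{path} is not a classifier checkpoint")
    spec = ArchSpec(
        name=cfg["name"],
        num_classes=cfg["num_classes"],
        input_size=cfg["input_size"],
        width_multiplier=cfg["width_multiplier"],
    )
    model = build_architecture(spec)
    nn.io.load_weights(path, model)
    return model


# ---------------------------------------------------------------------
# estimator front end
# ---------------------------------------------------------------------

from sklearn.base import BaseEstimator, ClassifierMixin  # noqa: E402


class ChopClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style front end over the four architectures.

    ``fit(X, y)`` takes (N, S, S) grayscale chops in [0, 1] and integer
    labels; a validation split drives the plateau LR schedule.
    """

    def __init__(
        self,
        arch: str = "squeezenet",
        width_multiplier: float = 1.0,
        input_size: int = 64,
        epochs: int = 15,
        batch_size: int = 32,
        initial_lr: float = 1e-2,
        final_lr: float = 1e-5,
        lr_drop_factor: float = 10.0,
        plateau_patience: int = 3,
        val_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.arch = arch
        self.width_multiplier = width_multiplier
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.final_lr = final_lr
        self.lr_drop_factor = lr_drop_factor
        self.plateau_patience = plateau_patience
        self.val_fraction = val_fraction
        self.seed = seed

    def _config(self) -> TrainConfig:
        return TrainConfig(
            initial_lr=self.initial_lr,
            final_lr=self.final_lr,
            lr_drop_factor=self.lr_drop_factor,
            plateau_patience=self.plateau_patience,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
        )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ChopClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([index[v] for v in y])
        spec = ArchSpec(
            name=self.arch,
            num_classes=len(self.classes_),
            input_size=self.input_size,
            width_multiplier=self.width_multiplier,
        )
        model = build_architecture(spec, seed=self.seed)
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(X))
        n_val = max(1, int(len(X) * self.val_fraction))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        self.model_, self.report_ = train_classifier(
            model, X[tr_idx], yi[tr_idx], X[val_idx], yi[val_idx], self._config()
        )
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self.model_, np.asarray(X, dtype=np.float64))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def save(self, path) -> None:
        save_classifier(path, self.model_)

    @classmethod
    def from_file(cls, path, **kwargs) -> "ChopClassifier":
        model = load_classifier(path)
        est = cls(
            arch=model.spec.name,
            width_multiplier=model.spec.width_multiplier,
            input_size=model.spec.input_size,
            **kwargs,
        )
        est.model_ = model
        est.classes_ = np.arange(model.spec.num_classes)
        return est
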