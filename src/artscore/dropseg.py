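"""Droplet localization with a small U-Net.

The well image is much larger than the droplet; before chopping, the
droplet is found by semantic segmentation: an encoder of repeated
convolution + ReLU + max-pooling stages, mirrored by a decoder of
up-convolutions with skip concatenations from the encoder, ending in a
per-pixel foreground probability.  The largest connected component of
the thresholded probability map gives the droplet region, whose
bounding box (padded to at least one chop) is used to crop the image.

Training masks come from the synthetic generator, which knows its exact
droplet geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from . import nn
from .nn import core
from .nn.core import Tensor
from .nn.layers import Conv2d, ConvTranspose2d, MaxPool2d, Module, ModuleList, Sequential, ReLU
from .tiling import Window


@dataclass(frozen=True)
class UNetSpec:
    """Mirror-symmetric encoder/decoder; each level halves resolution."""

    depth: int = 4
    base_filters: int = 16
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class DropletRegion:
    """Located droplet: tight bbox of the largest component, its mask,
    and the mean foreground probability inside the bbox."""

    bbox: Window
    mask: np.ndarray
    confidence: float


class _DoubleConv(Module):
    def __init__(self, in_c: int, out_c: int, rng):
        super().__init__()
        self.block = Sequential(
            Conv2d(in_c, out_c, 3, padding=1, rng=rng), ReLU(),
            Conv2d(out_c, out_c, 3, padding=1, rng=rng), ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class UNet(Module):
    """Contracting path doubles filters per level; the expansive path
    restores resolution and concatenates the skip features."""

    def __init__(self, spec: UNetSpec, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        f = spec.base_filters
        enc, ch = [], spec.in_channels
        self.encoder_channels = []
        for level in range(spec.depth):
            out = f * 2**level
            enc.append(_DoubleConv(ch, out, rng))
            self.encoder_channels.append(out)
            ch = out
        self.encoders = ModuleList(enc)
        self.pool = MaxPool2d(2, 2)
        self.bottom = _DoubleConv(ch, ch * 2, rng)
        ups, decs = [], []
        ch *= 2
        for level in reversed(range(spec.depth)):
            skip = f * 2**level
            ups.append(ConvTranspose2d(ch, skip, 2, 2, rng=rng))
            decs.append(_DoubleConv(skip * 2, skip, rng))
            ch = skip
        self.ups = ModuleList(ups)
        self.decoders = ModuleList(decs)
        self.head = Conv2d(ch, spec.out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.data.shape[2:]
        div = 2**self.spec.depth
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {div}"
            )
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottom(x)
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            x = up(x)
            x = dec(core.concat([skip, x], axis=1))
        return core.sigmoid(self.head(x))


def build_unet(spec: UNetSpec, seed: int = 0) -> UNet:
    """Build the segmentation model (probability map in [0,1] per pixel)."""
    model = UNet(spec, np.random.default_rng(seed))
    model.eval()
    return model


def segment_proba(model, image: np.ndarray) -> np.ndarray:
    """Per-pixel droplet probability; accepts a UNet or any callable."""
    if callable(model) and not isinstance(model, Module):
        return np.asarray(model(image), dtype=float)
    model.eval()
    x = Tensor(np.asarray(image, dtype=model.dtype)[None, None])
    return np.asarray(model(x).data[0, 0], dtype=float)


def train_unet(
    model: UNet,
    images: np.ndarray,
    masks: np.ndarray,
    epochs: int = 30,
    seed: int = 0,
    lr: float = 1e-3,
    batch_size: int = 4,
) -> tuple[UNet, list[float]]:
    """Adam + pixelwise binary cross-entropy; deterministic per seed."""
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks, dtype=np.float32)
    if len(images) == 0:
        raise ValueError("empty training set")
    if images.shape != masks.shape:
        raise ValueError("images and masks must share shapes")
    model.astype(np.float32)  # single precision for CPU speed
    rng = np.random.default_rng(seed)
    model.set_rng(rng)
    opt = nn.Adam(model.parameters(), lr=lr)
    losses: list[float] = []
    for _ in range(epochs):
        model.train()
        order = rng.permutation(len(images))
        total = 0.0
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            opt.zero_grad()
            probs = model(Tensor(images[idx][:, None]))
            loss = core.bce_loss(probs, masks[idx][:, None])
            loss.backward()
            opt.step()
            total += loss.data.item() * len(idx)
        losses.append(total / len(images))
    model.eval()
    return model, losses


def locate_droplet(
    model,
    image: np.ndarray,
    prob_threshold: float = 0.5,
    min_bbox: int | None = None,
) -> DropletRegion | None:
    """Threshold the probability map, keep the largest component.

    Returns ``None`` when nothing exceeds the threshold (a valid
    outcome: no droplet found).  The bbox is padded to at least
    ``min_bbox`` pixels per side (clipped to the image) so it can hold
    at least one chop.
    """
    probs = segment_proba(model, image)
    fg = probs >= prob_threshold
    if not fg.any():
        return None
    labeled, n = ndimage.label(fg)
    largest = np.argmax(ndimage.sum_labels(fg, labeled, range(1, n + 1))) + 1
    mask = labeled == largest
    ys, xs = np.nonzero(mask)
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    h, w = image.shape
    if min_bbox:
        y0, y1 = _pad_span(y0, y1, min_bbox, h)
        x0, x1 = _pad_span(x0, x1, min_bbox, w)
    bbox = Window(x0=x0, y0=y0, width=x1 - x0, height=y1 - y0)
    conf = float(probs[y0:y1, x0:x1].mean())
    return DropletRegion(bbox=bbox, mask=mask, confidence=conf)


def _pad_span(a: int, b: int, min_len: int, limit: int) -> tuple[int, int]:
    if b - a >= min_len:
        return a, b
    need = min_len - (b - a)
    a = max(0, a - need // 2)
    b = min(limit, a + min_len)
    a = max(0, b - min_len)
    return a, b


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two boolean masks."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

def save_unet(path, model: UNet) -> None:
    s = model.spec
    nn.io.save_model(path, model, {
        "kind": "unet",
        "depth": s.depth,
        "base_filters": s.base_filters,
        "in_channels": s.in_channels,
        "out_channels": s.out_channels,
    })


def load_unet(path) -> UNet:
    cfg = nn.io.read_config(path)
    if cfg.get("kind") != "unet":
        raise ValueError(f"{path} is not a U-Net checkpoint")
    spec = UNetSpec(
        depth=cfg["depth"],
        base_filters=cfg["base_filters"],
        in_channels=cfg["in_channels"],
        out_channels=cfg["out_channels"],
    )
    model = build_unet(spec)
    nn.io.load_weights(path, model)
    return model


# ---------------------------------------------------------------------
# estimator front end
# ---------------------------------------------------------------------

class DropletSegmenter(BaseEstimator):
    """Sklearn-style wrapper around the U-Net segmentation stage.

    ``fit(images, masks)`` trains on (N, H, W) grayscale wells with
    boolean masks; ``predict`` returns thresholded masks and
    ``locate`` the droplet region of a single well.
    """

    def __init__(
        self,
        depth: int = 3,
        base_filters: int = 8,
        epochs: int = 30,
        lr: float = 1e-3,
        batch_size: int = 4,
        prob_threshold: float = 0.5,
        min_bbox: int | None = None,
        seed: int = 0,
    ):
        self.depth = depth
        self.base_filters = base_filters
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.prob_threshold = prob_threshold
        self.min_bbox = min_bbox
        self.seed = seed

    def fit(self, images: np.ndarray, masks: np.ndarray) -> "DropletSegmenter":
        spec = UNetSpec(depth=self.depth, base_filters=self.base_filters)
        model = build_unet(spec, seed=self.seed)
        self.model_, self.loss_history_ = train_unet(
            model, images, masks,
            epochs=self.epochs, seed=self.seed,
            lr=self.lr, batch_size=self.batch_size,
        )
        return self

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return np.stack([segment_proba(self.model_, im) for im in images])

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.predict_proba(images) >= self.prob_threshold

    def locate(self, image: np.ndarray) -> DropletRegion | None:
        return locate_droplet(
            self.model_, image,
            prob_threshold=self.prob_threshold, min_bbox=self.min_bbox,
        )

    def save(self, path) -> None:
        save_unet(path, self.model_)

    @classmethod
    def from_file(cls, path, **kwargs) -> "DropletSegmenter":
        model = load_unet(path)
        est = cls(
            depth=model.spec.depth, base_filters=model.spec.base_filters, **kwargs
        )
        est.model_ = model
        est.loss_history_ = []
        return est
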