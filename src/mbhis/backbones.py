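"""The three backbone CNNs as global-average-pooling feature extractors.

ResNet-50, DenseNet-201 and MobileNet (v2) are implemented as NumPy
inference networks with their classification head replaced by a
``num_classes`` linear layer. The pooled embedding widths are fixed by the
architectures: 2048, 1920 and 1280 channels respectively, independent of
image content and of the spatial input size (any multiple of 32, minimum
32 px, is accepted; 224 x 224 is the conventional size).

Without a local weight cache the networks are seeded-random (He
initialisation, identity batch-norm statistics). Random deep features are
still useful embeddings — they are a structured multiscale random projection
of the image — and every dimension contract holds regardless of the weights.
``fine_tune`` trains the replaced head with momentum SGD and cross-entropy on
the (frozen) pooled embeddings, i.e. linear probing of the backbone.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import (
    avgpool2d,
    batchnorm,
    conv2d,
    depthwise_conv2d,
    global_avg_pool,
    maxpool2d,
    relu,
    relu6,
    softmax,
)
from .data import LabeledImageSet
from .exceptions import ConfigurationError, DataError
from .features import FeatureMatrix

logger = logging.getLogger(__name__)

FEATURE_DIMS = {"resnet50": 2048, "densenet201": 1920, "mobilenet": 1280}

# standard ImageNet channel statistics used by all three backbones
_PIX_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_PIX_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class BackboneSpec:
    name: str
    pretrained: bool = False
    num_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in FEATURE_DIMS:
            raise ConfigurationError(
                f"unknown backbone {self.name!r}; choose from {sorted(FEATURE_DIMS)}"
            )
        if self.num_classes not in (2, 4):
            raise ConfigurationError("num_classes must be 2 (binary) or 4 (subtypes)")

    @property
    def feature_dim(self) -> int:
        return FEATURE_DIMS[self.name]


@dataclass
class TrainConfig:
    """Head-training recipe: momentum SGD, cross-entropy."""

    epochs: int = 20
    initial_lr: float = 3e-4
    batch_size: int = 4
    momentum: float = 0.9
    optimizer: str = "sgdm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if self.initial_lr <= 0:
            raise ConfigurationError("initial_lr must be > 0")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


def _he(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _bn_params(c: int) -> dict:
    return {
        "gamma": np.ones(c, dtype=np.float32),
        "beta": np.zeros(c, dtype=np.float32),
        "mean": np.zeros(c, dtype=np.float32),
        "var": np.ones(c, dtype=np.float32),
    }


def _bn(x, p):
    return batchnorm(x, p["gamma"], p["beta"], p["mean"], p["var"])


class _Backbone:
    """Common machinery: head, preprocessing, batched GAP extraction."""

    name: str = ""
    feature_dim: int = 0

    def __init__(self, spec: BackboneSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.head_w = np.zeros((spec.num_classes, self.feature_dim), dtype=np.float64)
        self.head_b = np.zeros(spec.num_classes, dtype=np.float64)
        self.loss_history: list[float] = []

    # subclasses implement the convolutional trunk
    def _trunk(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    @staticmethod
    def _preprocess(images: list[np.ndarray]) -> np.ndarray:
        arr = np.stack([im.astype(np.float32) / 255.0 for im in images])
        arr = (arr - _PIX_MEAN) / _PIX_STD
        return arr.transpose(0, 3, 1, 2)

    def gap_features(self, images: list[np.ndarray], batch: int = 8) -> np.ndarray:
        for im in images:
            if im.ndim != 3 or im.shape[2] != 3:
                raise DataError(f"expected H x W x 3 images, got shape {im.shape}")
            h, w = im.shape[:2]
            if h < 32 or w < 32 or h % 32 or w % 32:
                raise DataError(
                    f"backbone input must be a multiple of 32 px per side, got {h}x{w}"
                )
        out = []
        for i in range(0, len(images), batch):
            x = self._preprocess(images[i : i + batch])
            out.append(global_avg_pool(self._trunk(x)).astype(np.float64))
        feats = np.concatenate(out) if out else np.empty((0, self.feature_dim))
        if feats.shape[1] != self.feature_dim:
            raise DataError(
                f"trunk produced width {feats.shape[1]}, expected {self.feature_dim}"
            )
        return feats

    def logits(self, images: list[np.ndarray]) -> np.ndarray:
        return self.gap_features(images) @ self.head_w.T + self.head_b

    def predict_proba(self, images: list[np.ndarray]) -> np.ndarray:
        return softmax(self.logits(images))


class ResNet50(_Backbone):
    """50-layer residual network; bottleneck stages (3, 4, 6, 3) -> 2048."""

    name = "resnet50"
    feature_dim = 2048

    def __init__(self, spec: BackboneSpec):
        super().__init__(spec)
        rng = self.rng
        self.stem_w = _he(rng, (64, 3, 7, 7))
        self.stem_bn = _bn_params(64)
        self.blocks = []
        cin = 64
        for mid, cout, reps, stride in (
            (64, 256, 3, 1),
            (128, 512, 4, 2),
            (256, 1024, 6, 2),
            (512, 2048, 3, 2),
        ):
            for r in range(reps):
                s = stride if r == 0 else 1
                blk = {
                    "w1": _he(rng, (mid, cin, 1, 1)),
                    "bn1": _bn_params(mid),
                    "w2": _he(rng, (mid, mid, 3, 3)),
                    "bn2": _bn_params(mid),
                    "w3": _he(rng, (cout, mid, 1, 1)),
                    "bn3": _bn_params(cout),
                    "stride": s,
                }
                # damp the residual branch at init (cf. zero-gamma residual
                # init) so activation variance stays bounded over 16 blocks
                blk["bn3"]["gamma"] *= 0.25
                if r == 0:
                    blk["wd"] = _he(rng, (cout, cin, 1, 1))
                    blk["bnd"] = _bn_params(cout)
                self.blocks.append(blk)
                cin = cout

    def _trunk(self, x):
        x = relu(_bn(conv2d(x, self.stem_w, stride=2, pad=3), self.stem_bn))
        x = maxpool2d(x, 3, 2, pad=1)
        for blk in self.blocks:
            idn = x
            y = relu(_bn(conv2d(x, blk["w1"]), blk["bn1"]))
            y = relu(_bn(conv2d(y, blk["w2"], stride=blk["stride"], pad=1), blk["bn2"]))
            y = _bn(conv2d(y, blk["w3"]), blk["bn3"])
            if "wd" in blk:
                idn = _bn(conv2d(x, blk["wd"], stride=blk["stride"]), blk["bnd"])
            x = relu(y + idn)
        return x


class DenseNet201(_Backbone):
    """Densely connected network; blocks (6, 12, 48, 32), growth 32 -> 1920."""

    name = "densenet201"
    feature_dim = 1920
    growth = 32

    def __init__(self, spec: BackboneSpec):
        super().__init__(spec)
        rng = self.rng
        self.stem_w = _he(rng, (64, 3, 7, 7))
        self.stem_bn = _bn_params(64)
        self.stages = []
        c = 64
        for bi, reps in enumerate((6, 12, 48, 32)):
            layers = []
            for _ in range(reps):
                layers.append(
                    {
                        "bn1": _bn_params(c),
                        "w1": _he(rng, (4 * self.growth, c, 1, 1)),
                        "bn2": _bn_params(4 * self.growth),
                        "w2": _he(rng, (self.growth, 4 * self.growth, 3, 3)),
                    }
                )
                c += self.growth
            stage = {"layers": layers}
            if bi < 3:  # transition halves channels and spatial size
                stage["tbn"] = _bn_params(c)
                stage["tw"] = _he(rng, (c // 2, c, 1, 1))
                c //= 2
            self.stages.append(stage)
        self.final_bn = _bn_params(c)
        assert c == self.feature_dim

    def _trunk(self, x):
        x = relu(_bn(conv2d(x, self.stem_w, stride=2, pad=3), self.stem_bn))
        x = maxpool2d(x, 3, 2, pad=1)
        for stage in self.stages:
            for ly in stage["layers"]:
                y = relu(_bn(x, ly["bn1"]))
                y = relu(_bn(conv2d(y, ly["w1"]), ly["bn2"]))
                y = conv2d(y, ly["w2"], pad=1)
                x = np.concatenate([x, y], axis=1)
            if "tw" in stage:
                x = conv2d(relu(_bn(x, stage["tbn"])), stage["tw"])
                x = avgpool2d(x, 2, 2)
        return relu(_bn(x, self.final_bn))


class MobileNetV2(_Backbone):
    """Inverted-residual mobile network; final 1x1 conv widens to 1280."""

    name = "mobilenet"
    feature_dim = 1280
    settings = (  # (expansion, channels, repeats, stride)
        (1, 16, 1, 1),
        (6, 24, 2, 2),
        (6, 32, 3, 2),
        (6, 64, 4, 2),
        (6, 96, 3, 1),
        (6, 160, 3, 2),
        (6, 320, 1, 1),
    )

    def __init__(self, spec: BackboneSpec):
        super().__init__(spec)
        rng = self.rng
        self.stem_w = _he(rng, (32, 3, 3, 3))
        self.stem_bn = _bn_params(32)
        self.blocks = []
        cin = 32
        for t, c, n, s in self.settings:
            for r in range(n):
                stride = s if r == 0 else 1
                hidden = cin * t
                blk = {"stride": stride, "residual": stride == 1 and cin == c, "t": t}
                if t != 1:
                    blk["we"] = _he(rng, (hidden, cin, 1, 1))
                    blk["bne"] = _bn_params(hidden)
                blk["wd"] = _he(rng, (hidden, 3, 3))
                blk["bnd"] = _bn_params(hidden)
                blk["wp"] = _he(rng, (c, hidden, 1, 1))
                blk["bnp"] = _bn_params(c)
                self.blocks.append(blk)
                cin = c
        self.last_w = _he(rng, (1280, cin, 1, 1))
        self.last_bn = _bn_params(1280)

    def _trunk(self, x):
        x = relu6(_bn(conv2d(x, self.stem_w, stride=2, pad=1), self.stem_bn))
        for blk in self.blocks:
            y = x
            if blk["t"] != 1:
                y = relu6(_bn(conv2d(y, blk["we"]), blk["bne"]))
            y = relu6(_bn(depthwise_conv2d(y, blk["wd"], stride=blk["stride"], pad=1), blk["bnd"]))
            y = _bn(conv2d(y, blk["wp"]), blk["bnp"])
            x = x + y if blk["residual"] else y
        return relu6(_bn(conv2d(x, self.last_w), self.last_bn))


_ARCHS = {"resnet50": ResNet50, "densenet201": DenseNet201, "mobilenet": MobileNetV2}


def default_weight_cache() -> Path:
    return Path(os.environ.get("MBHIS_WEIGHTS", Path.home() / ".cache" / "mbhis"))


def build_backbone(spec: BackboneSpec, weight_cache: str | Path | None = None) -> _Backbone:
    """Instantiate the named architecture with a ``num_classes`` head.

    ``pretrained=True`` loads weights from a local ``.npz`` cache; without
    one (no network at run time) a configuration error points at
    ``pretrained=False``, which gives seeded He-initialised weights.
    """
    model = _ARCHS[spec.name](spec)
    if spec.pretrained:
        cache = Path(weight_cache) if weight_cache else default_weight_cache()
        path = cache / f"{spec.name}.npz"
        if not path.exists():
            raise ConfigurationError(
                f"pretrained weights for {spec.name!r} not found at {path}; "
                "download them into the cache or use pretrained=False "
                "(seeded random initialisation)"
            )
        _load_weights(model, path)
    return model


def fine_tune(model: _Backbone, train: LabeledImageSet, cfg: TrainConfig) -> _Backbone:
    """Train the replaced linear head with momentum SGD on frozen embeddings.

    ``epochs=0`` returns the model unchanged. Loss history (mean cross-entropy
    per epoch) is recorded on the model.
    """
    if train.n_classes != model.spec.num_classes:
        raise ConfigurationError(
            f"dataset has {train.n_classes} classes, head expects {model.spec.num_classes}"
        )
    if cfg.epochs == 0:
        return model
    feats = model.gap_features(train.images)
    y = train.labels
    n, d = feats.shape
    rng = np.random.default_rng(cfg.seed)
    vel_w = np.zeros_like(model.head_w)
    vel_b = np.zeros_like(model.head_b)
    onehot = np.eye(model.spec.num_classes)[y]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            fb = feats[idx]
            z = fb @ model.head_w.T + model.head_b
            p = softmax(z)
            losses.append(float(-np.log(np.clip(p[np.arange(len(idx)), y[idx]], 1e-12, None)).mean()))
            g = (p - onehot[idx]) / len(idx)
            gw = g.T @ fb
            gb = g.sum(axis=0)
            vel_w = cfg.momentum * vel_w - cfg.initial_lr * gw
            vel_b = cfg.momentum * vel_b - cfg.initial_lr * gb
            model.head_w += vel_w
            model.head_b += vel_b
        model.loss_history.append(float(np.mean(losses)))
    return model


def extract_gap_features(model: _Backbone, data: LabeledImageSet) -> FeatureMatrix:
    """n x feature_dim matrix of pooled trunk activations, rows in data order."""
    feats = model.gap_features(data.images)
    return FeatureMatrix(feats, list(data.sample_ids), "spatial", model.spec.name)


def predict_end_to_end(model: _Backbone, data: LabeledImageSet) -> np.ndarray:
    """Arg-max of the classification head per image."""
    return np.argmax(model.predict_proba(data.images), axis=1)


def _flatten_params(model: _Backbone) -> dict[str, np.ndarray]:
    flat: dict[str, np.ndarray] = {"head_w": model.head_w, "head_b": model.head_b}

    def rec(obj, prefix):
        if isinstance(obj, np.ndarray):
            flat[prefix] = obj
        elif isinstance(obj, dict):
            for k, v in obj.items():
                rec(v, f"{prefix}.{k}")
        elif isinstance(obj, list):
            for i, v in enumerate(obj):
                rec(v, f"{prefix}[{i}]")

    for attr, val in vars(model).items():
        if attr in ("spec", "rng", "loss_history", "head_w", "head_b"):
            continue
        rec(val, attr)
    return {k: v for k, v in flat.items() if isinstance(v, np.ndarray)}


def save_weights(model: _Backbone, path: str | Path) -> None:
    np.savez(path, **_flatten_params(model))


def _load_weights(model: _Backbone, path: Path) -> None:
    stored = np.load(path)
    flat = _flatten_params(model)
    missing = set(flat) - set(stored.files)
    if missing:
        raise ConfigurationError(f"weight file {path} is missing arrays: {sorted(missing)[:5]}")
    for k, arr in flat.items():
        if stored[k].shape != arr.shape:
            raise ConfigurationError(f"weight {k} has shape {stored[k].shape}, expected {arr.shape}")
        arr[...] = stored[k]
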