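"""Synthetic 5-class texture image sets.

Stands in for a normal-plus-four-subtype histopathology dataset so the whole
cascade (embedding, wavelet, fusion, classification) can be exercised offline
and deterministically. Each class has its own texture program driven by
second-order structure rather than mean brightness:

* ``normal`` — smooth low-frequency field,
* ``classic`` — dense field of small blobs,
* ``desmoplastic`` — oriented stripes,
* ``large_cell`` — coarse checkerboard,
* ``nodular`` — concentric rings around a random centre.

All images share the same mean intensity scale; ``signal_strength`` sets the
texture contrast and ``noise_sd`` the additive Gaussian noise, both on the
[0, 1] intensity scale before quantisation to uint8. All randomness flows
from a single generator seeded per call, so identical specs give bit-identical
pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import LabeledImageSet
from .exceptions import ConfigurationError

DEFAULT_CLASSES = ["normal", "classic", "desmoplastic", "large_cell", "nodular"]


@dataclass
class FixtureSpec:
    n_per_class: int = 10
    image_size: tuple[int, int] = (224, 224)
    classes: list[str] = field(default_factory=lambda: list(DEFAULT_CLASSES))
    seed: int = 0
    signal_strength: float = 0.8
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ConfigurationError(f"image_size too small: {self.image_size}")
        if len(set(self.classes)) != len(self.classes):
            raise ConfigurationError("class names must be duplicate-free")
        if not (0.0 < self.signal_strength <= 1.0):
            raise ConfigurationError("signal_strength must be in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _smooth_field(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Low-frequency random surface in [-0.5, 0.5] from a coarse bilinear grid."""
    coarse = rng.normal(size=(4, 4))
    yi = np.linspace(0, 3, h)
    xi = np.linspace(0, 3, w)
    y0 = np.clip(yi.astype(int), 0, 2)
    x0 = np.clip(xi.astype(int), 0, 2)
    fy = (yi - y0)[:, None]
    fx = (xi - x0)[None, :]
    a = coarse[y0][:, x0]
    b = coarse[y0][:, x0 + 1]
    c = coarse[y0 + 1][:, x0]
    d = coarse[y0 + 1][:, x0 + 1]
    f = a * (1 - fy) * (1 - fx) + b * (1 - fy) * fx + c * fy * (1 - fx) + d * fy * fx
    return 0.5 * np.tanh(f)


def _blob_lattice(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Gaussian bumps on a jittered lattice, pitch h/5 (dense nodule field)."""
    pitch = h / 5
    radius = pitch / 3
    yy, xx = np.mgrid[0:h, 0:w]
    f = np.zeros((h, w))
    for gy in np.arange(pitch / 2, h, pitch):
        for gx in np.arange(pitch / 2, w, pitch):
            y0 = gy + rng.normal(0, 0.08 * pitch)
            x0 = gx + rng.normal(0, 0.08 * pitch)
            f += np.exp(-(((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * radius**2)))
    f -= f.mean()
    return np.tanh(f / (f.std() + 1e-12))


def _stripes(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Oriented sinusoid, 4 cycles across, small orientation/phase jitter."""
    period = h / 4
    theta = np.pi / 6 + rng.normal(0, 0.05)
    phase = rng.normal(0, 0.3)
    yy, xx = np.mgrid[0:h, 0:w]
    u = np.cos(theta) * xx + np.sin(theta) * yy
    return np.sin(2 * np.pi * u / period + phase)


def _checker(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Coarse checkerboard, cell h/6, small integer offset jitter."""
    cell = max(2, int(round(h / 6)))
    oy, ox = rng.integers(0, max(1, cell // 3) + 1, size=2)
    yy, xx = np.mgrid[0:h, 0:w]
    f = (((yy + oy) // cell + (xx + ox) // cell) % 2).astype(float)
    return 2 * f - 1


def _rings(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Concentric rings, 4 cycles over the half-diagonal, centre jitter 3%."""
    cy = h / 2 + rng.normal(0, 0.03 * h)
    cx = w / 2 + rng.normal(0, 0.03 * w)
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    return np.cos(2 * np.pi * 4.0 * r / (0.5 * np.hypot(h, w)) + rng.normal(0, 0.3))


_PROGRAMS = {
    "normal": _smooth_field,
    "classic": _blob_lattice,
    "desmoplastic": _stripes,
    "large_cell": _checker,
    "nodular": _rings,
}


def _texture(name: str, rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    # pattern scales are relative to the image size, so class structure
    # survives both CNN embedding and coarse thumbnailing at any resolution
    if name not in _PROGRAMS:
        raise ConfigurationError(f"no texture program for class {name!r}")
    return _PROGRAMS[name](rng, h, w)


# fixed RGB weighting shared by all classes: separability must come from
# texture, not colour or mean intensity
_CHANNEL_GAIN = np.array([1.0, 0.92, 0.96])


def generate_fixture(spec: FixtureSpec) -> LabeledImageSet:
    """Generate ``n_per_class`` images per class as an in-memory labeled set."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    images: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    for ci, cname in enumerate(spec.classes):
        for k in range(spec.n_per_class):
            pattern = _texture(cname, rng, h, w)
            base = 0.5 + 0.45 * spec.signal_strength * pattern
            base = base + rng.normal(scale=spec.noise_sd, size=(h, w))
            rgb = base[:, :, None] * _CHANNEL_GAIN[None, None, :]
            img = np.clip(np.rint(rgb * 255), 0, 255).astype(np.uint8)
            images.append(img)
            labels.append(ci)
            ids.append(f"{cname}/{cname}_{k:03d}")
    return LabeledImageSet(images, np.array(labels), list(spec.classes), "multiclass", ids)


def write_fixture_tree(data: LabeledImageSet, root: str | Path) -> int:
    """Dump a labeled set as a folder-per-class PNG tree; returns file count."""
    root = Path(root)
    n = 0
    for img, lab, sid in zip(data.images, data.labels, data.sample_ids):
        cname = data.class_names[lab]
        out = root / cname / (Path(sid).name + ".png")
        out.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img).save(out)
        n += 1
    return n
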