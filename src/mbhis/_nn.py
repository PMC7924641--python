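"""Minimal NumPy inference layers for the backbone networks.

All tensors are NCHW float32. Convolution is im2col + GEMM; batch
normalisation is inference-mode (running statistics). These layers only need
to support forward passes — the cascade uses the networks as fixed feature
extractors, and head training happens on the pooled embeddings.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """x (N,C,H,W) * w (O,C,kh,kw) -> (N,O,H',W')."""
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    _, _, ho, wo, _, _ = win.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    out = cols @ w.reshape(o, -1).T.astype(np.float32)
    return out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)


def depthwise_conv2d(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
    """x (N,C,H,W) * w (C,kh,kw), one filter per channel."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    kh, kw = w.shape[1:]
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    return np.einsum("nchwij,cij->nchw", win, w.astype(np.float32), optimize=True)


def batchnorm(x: np.ndarray, gamma, beta, mean, var, eps: float = 1e-5) -> np.ndarray:
    shp = (1, -1, 1, 1)
    inv = (gamma / np.sqrt(var + eps)).astype(np.float32)
    return x * inv.reshape(shp) + (beta - mean * inv).astype(np.float32).reshape(shp)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0, out=x)


def relu6(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0, 6, out=x)


def maxpool2d(x: np.ndarray, k: int, stride: int, pad: int = 0) -> np.ndarray:
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    return win.max(axis=(4, 5))


def avgpool2d(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    return win.mean(axis=(4, 5))


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N,C): spatial mean of each channel."""
    return x.mean(axis=(2, 3))


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
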