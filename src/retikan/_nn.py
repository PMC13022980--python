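"""Low-level numpy neural-net primitives shared by the backbone and the head.

Arrays are channels-last: ``(batch, height, width, channels)``.  Convolutions
are implemented by window extraction (``sliding_window_view``) followed by a
tensor contraction, which keeps everything inside BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "pad_same", "conv2d", "depthwise_conv2d", "instance_norm",
    "layer_norm", "relu", "softmax", "multi_head_attention",
]


def pad_same(x: np.ndarray, k: int, stride: int = 1) -> np.ndarray:
    """Zero-pad H and W so that an odd ``k`` kernel with this stride yields
    ceil(H/stride) output pixels (TensorFlow 'same' convention)."""
    h = x.shape[1]
    out = -(-h // stride)
    total = max(0, (out - 1) * stride + k - h)
    lo, hi = total // 2, total - total // 2
    return np.pad(x, ((0, 0), (lo, hi), (lo, hi), (0, 0)))


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, Ho, Wo, C, k, k) view of all k x k patches."""
    w = sliding_window_view(x, (k, k), axis=(1, 2))
    return w[:, ::stride, ::stride]


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
           stride: int = 1, groups: int = 1) -> np.ndarray:
    """'Same'-padded 2-D convolution. ``w`` has shape (k, k, Cin/groups, Cout)."""
    k = w.shape[0]
    cin = x.shape[-1]
    cout = w.shape[-1]
    if cin % groups or cout % groups:
        raise ValueError("channels not divisible by groups")
    xp = pad_same(x, k, stride) if k > 1 or stride > 1 else x
    if k == 1 and stride == 1 and groups == 1:
        out = x @ w[0, 0]
    else:
        win = _windows(xp, k, stride)
        if groups == 1:
            out = np.tensordot(win, w, axes=([3, 4, 5], [2, 0, 1]))
        else:
            gin, gout = cin // groups, cout // groups
            parts = []
            for g in range(groups):
                wg = w[..., g * gout:(g + 1) * gout]
                parts.append(np.tensordot(
                    win[:, :, :, g * gin:(g + 1) * gin],
                    wg, axes=([3, 4, 5], [2, 0, 1])))
            out = np.concatenate(parts, axis=-1)
    if b is not None:
        out = out + b
    return out


def depthwise_conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None = None,
                     stride: int = 1) -> np.ndarray:
    """Depthwise convolution; ``w`` has shape (k, k, C), multiplier 1."""
    k = w.shape[0]
    xp = pad_same(x, k, stride)
    win = _windows(xp, k, stride)          # (B, Ho, Wo, C, k, k)
    out = np.einsum("bhwckl,klc->bhwc", win, w, optimize=True)
    if b is not None:
        out = out + b
    return out


def instance_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Per-sample, per-channel standardization over the spatial axes."""
    mu = x.mean(axis=(1, 2), keepdims=True)
    var = x.var(axis=(1, 2), keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def rms_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Per-sample, per-channel RMS scaling over the spatial axes.

    Unlike mean-subtracting instance normalization this preserves each
    channel's spatial mean (up to scale), so globally pooled statistics —
    e.g. total lesion response — survive a deep stack of frozen layers.
    """
    ms = np.mean(np.square(x), axis=(1, 2), keepdims=True)
    return x / np.sqrt(ms + eps)


def layer_norm(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Standardization over the last axis (token embedding)."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def multi_head_attention(tokens: np.ndarray, wq: np.ndarray, wk: np.ndarray,
                         wv: np.ndarray, wo: np.ndarray, n_heads: int,
                         dropout: float = 0.0,
                         rng: np.random.Generator | None = None,
                         return_weights: bool = False):
    """Multi-head self-attention over ``tokens`` of shape (B, N, d).

    ``dropout`` is applied to the attention weight matrix and only when an
    ``rng`` is supplied (training mode); inference is deterministic.
    """
    b, n, d = tokens.shape
    if d % n_heads:
        raise ValueError("embedding dim must be divisible by n_heads")
    dh = d // n_heads

    def split(x):
        return x.reshape(b, n, n_heads, dh).transpose(0, 2, 1, 3)

    q, k, v = split(tokens @ wq), split(tokens @ wk), split(tokens @ wv)
    scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dh)
    attn = softmax(scores, axis=-1)
    if dropout > 0.0 and rng is not None:
        mask = rng.random(attn.shape) >= dropout
        attn = attn * mask / (1.0 - dropout)
    out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d) @ wo
    if return_weights:
        return out, attn
    return out
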