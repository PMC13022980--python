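"""Hybrid convolutional/attention feature extractor.

A toy-scale ShuffleNet-V2-style stack (stride-2 stem, three stages of shuffle
units with repeats 2/4/2, total stride 16) followed by one LeViT-style
multi-head self-attention block over the 14 x 14 token grid, and a final
projection fixing the output at 256 channels regardless of the width
multiplier.  For a 224-pixel input the feature map is ``(B, 14, 14, 256)``.

The extractor is used in the frozen-weights regime: weights are drawn once
from a seeded He initialization and every activation is RMS-normalized per
channel (scaling without mean subtraction, so globally pooled statistics
survive the stack); only the spline head downstream is trained.  Parameter and FLOP counts are computed analytically from the
same layer plan that builds the weights, with the convention that one
multiply-accumulate counts as 2 FLOPs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .preprocessing import FundusImage

__all__ = [
    "BackboneConfig", "channel_shuffle", "init_backbone_weights",
    "extract_features", "count_params_flops", "conv_flops", "linear_flops",
    "save_checkpoint", "load_checkpoint",
]

_WIDTHS = (0.5, 0.75, 1.0)
_KERNELS = (3, 5)
_EMBEDS = (128, 256, 384)
_HEADS = (4, 8)

#: Output channel count, fixed by a final projection for every configuration.
OUT_CHANNELS = 256


@dataclass(frozen=True)
class BackboneConfig:
    """Searchable architecture hyperparameters of the feature extractor."""

    width_multiplier: float = 1.0
    depthwise_kernel: int = 3
    embed_dim: int = 256
    n_heads: int = 8
    attention_dropout: float = 0.0
    input_size: int = 224

    def __post_init__(self) -> None:
        if self.width_multiplier not in _WIDTHS:
            raise ValueError(f"width_multiplier must be one of {_WIDTHS}")
        if self.depthwise_kernel not in _KERNELS:
            raise ValueError(f"depthwise_kernel must be one of {_KERNELS}")
        if self.embed_dim not in _EMBEDS:
            raise ValueError(f"embed_dim must be one of {_EMBEDS}")
        if self.n_heads not in _HEADS:
            raise ValueError(f"n_heads must be one of {_HEADS}")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not 0.0 <= self.attention_dropout <= 0.3:
            raise ValueError("attention_dropout must be in [0, 0.3]")
        if self.input_size < 16 or self.input_size % 16:
            raise ValueError("input_size must be a positive multiple of 16")

    @property
    def grid(self) -> int:
        """Side of the output token grid (input_size / 16)."""
        return self.input_size // 16


def channel_shuffle(x: np.ndarray, groups: int) -> np.ndarray:
    """Interleave channel groups (reshape-transpose-reshape permutation)."""
    if groups <= 0:
        raise ValueError("groups must be positive")
    c = x.shape[-1]
    if c % groups:
        raise ValueError(f"channels ({c}) not divisible by groups ({groups})")
    shape = x.shape
    return (x.reshape(*shape[:-1], groups, c // groups)
             .swapaxes(-1, -2)
             .reshape(shape))


def _even(x: float, minimum: int = 8) -> int:
    return max(minimum, 2 * int(round(x / 2)))


def _stage_channels(cfg: BackboneConfig) -> tuple[int, int, int, int]:
    wm = cfg.width_multiplier
    return (_even(16 * wm), _even(32 * wm), _even(64 * wm), _even(128 * wm))


def _plan(cfg: BackboneConfig) -> list[dict]:
    """Layer plan: single source of truth for weights, forward, and FLOPs.

    Each entry records the operation, its parameter shapes, and the spatial
    size at which it runs.
    """
    stem_c, c1, c2, c3 = _stage_channels(cfg)
    k = cfg.depthwise_kernel
    s = cfg.input_size
    plan: list[dict] = []

    plan.append({"op": "conv", "name": "stem", "k": 3, "cin": 3,
                 "cout": stem_c, "stride": 2, "hw": s // 2})
    hw = s // 2
    cin = stem_c
    for stage, (cout, repeats) in enumerate(zip((c1, c2, c3), (2, 4, 2))):
        hw //= 2
        # downsample unit: two branches, each emitting cout/2 channels
        plan.append({"op": "down_unit", "name": f"s{stage}_d", "k": k,
                     "cin": cin, "cout": cout, "hw": hw})
        for r in range(1, repeats):
            plan.append({"op": "shuffle_unit", "name": f"s{stage}_u{r}",
                         "k": k, "c": cout, "hw": hw})
        cin = cout
    plan.append({"op": "conv", "name": "embed", "k": 1, "cin": c3,
                 "cout": cfg.embed_dim, "stride": 1, "hw": hw})
    plan.append({"op": "attention", "name": "attn", "d": cfg.embed_dim,
                 "heads": cfg.n_heads, "n": hw * hw})
    plan.append({"op": "ffn", "name": "ffn", "d": cfg.embed_dim,
                 "hidden": 2 * cfg.embed_dim, "n": hw * hw})
    plan.append({"op": "linear", "name": "proj", "cin": cfg.embed_dim,
                 "cout": OUT_CHANNELS, "n": hw * hw})
    return plan


def _he(rng: np.random.Generator, shape: tuple[int, ...],
        fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


def init_backbone_weights(cfg: BackboneConfig, seed: int) -> dict[str, np.ndarray]:
    """Seeded He-initialized weights for every layer in the plan."""
    rng = np.random.default_rng(seed)
    w: dict[str, np.ndarray] = {}
    for layer in _plan(cfg):
        op, name = layer["op"], layer["name"]
        if op == "conv":
            k, cin, cout = layer["k"], layer["cin"], layer["cout"]
            w[name] = _he(rng, (k, k, cin, cout), k * k * cin)
        elif op == "down_unit":
            k, cin, cout = layer["k"], layer["cin"], layer["cout"]
            half = cout // 2
            w[f"{name}_a_dw"] = _he(rng, (k, k, cin), k * k)
            w[f"{name}_a_pw"] = _he(rng, (1, 1, cin, half), cin)
            w[f"{name}_b_pw1"] = _he(rng, (1, 1, cin, half), cin)
            w[f"{name}_b_dw"] = _he(rng, (k, k, half), k * k)
            w[f"{name}_b_pw2"] = _he(rng, (1, 1, half, half), half)
        elif op == "shuffle_unit":
            k, c = layer["k"], layer["c"]
            half = c // 2
            w[f"{name}_pw1"] = _he(rng, (1, 1, half, half), half)
            w[f"{name}_dw"] = _he(rng, (k, k, half), k * k)
            w[f"{name}_pw2"] = _he(rng, (1, 1, half, half), half)
        elif op == "attention":
            d = layer["d"]
            for p in ("wq", "wk", "wv", "wo"):
                w[f"{name}_{p}"] = _he(rng, (d, d), d)
        elif op == "ffn":
            d, hid = layer["d"], layer["hidden"]
            w[f"{name}_w1"] = _he(rng, (d, hid), d)
            w[f"{name}_w2"] = _he(rng, (hid, d), hid)
        elif op == "linear":
            cin, cout = layer["cin"], layer["cout"]
            w[name] = _he(rng, (cin, cout), cin)
    return w


def _stack_batch(images, cfg: BackboneConfig) -> np.ndarray:
    if isinstance(images, np.ndarray):
        batch = images
    else:
        for img in images:
            if isinstance(img, FundusImage) and img.size != cfg.input_size:
                raise ValueError(
                    f"image {img.id!r} has size {img.size}; the backbone "
                    f"expects {cfg.input_size}")
        batch = np.stack([img.pixels if isinstance(img, FundusImage) else img
                          for img in images])
    if batch.ndim != 4 or batch.shape[3] != 3:
        raise ValueError(f"expected (B, H, W, 3) input, got {batch.shape}")
    if batch.shape[1] != cfg.input_size or batch.shape[2] != cfg.input_size:
        raise ValueError(
            f"input spatial size {batch.shape[1]}x{batch.shape[2]} does not "
            f"match the expected {cfg.input_size}x{cfg.input_size}")
    if batch.min() < -1.0 - 1e-6 or batch.max() > 1.0 + 1e-6:
        raise ValueError("backbone input must be normalized to [-1, 1]")
    return batch.astype(np.float32)


def _forward(batch: np.ndarray, cfg: BackboneConfig, w: dict,
             rng: np.random.Generator | None, collect_attn: bool):
    x = batch
    attn_weights = None
    for layer in _plan(cfg):
        op, name = layer["op"], layer["name"]
        if op == "conv":
            x = _nn.rms_norm(_nn.relu(
                _nn.conv2d(x, w[name], stride=layer["stride"])))
        elif op == "down_unit":
            a = _nn.conv2d(
                _nn.depthwise_conv2d(x, w[f"{name}_a_dw"], stride=2),
                w[f"{name}_a_pw"])
            btmp = _nn.relu(_nn.conv2d(x, w[f"{name}_b_pw1"]))
            btmp = _nn.depthwise_conv2d(btmp, w[f"{name}_b_dw"], stride=2)
            btmp = _nn.relu(_nn.conv2d(btmp, w[f"{name}_b_pw2"]))
            x = channel_shuffle(np.concatenate([a, btmp], axis=-1), 2)
            x = _nn.rms_norm(x)
        elif op == "shuffle_unit":
            half = layer["c"] // 2
            keep, branch = x[..., :half], x[..., half:]
            branch = _nn.relu(_nn.conv2d(branch, w[f"{name}_pw1"]))
            branch = _nn.depthwise_conv2d(branch, w[f"{name}_dw"])
            branch = _nn.relu(_nn.conv2d(branch, w[f"{name}_pw2"]))
            x = channel_shuffle(np.concatenate([keep, branch], axis=-1), 2)
            x = _nn.rms_norm(x)
        elif op == "attention":
            b, h, wd, c = x.shape
            tokens = x.reshape(b, h * wd, c)
            normed = _nn.layer_norm(tokens)
            out = _nn.multi_head_attention(
                normed, w[f"{name}_wq"], w[f"{name}_wk"], w[f"{name}_wv"],
                w[f"{name}_wo"], layer["heads"],
                dropout=cfg.attention_dropout, rng=rng,
                return_weights=collect_attn)
            if collect_attn:
                out, attn_weights = out
            tokens = tokens + out
            x = tokens.reshape(b, h, wd, c)
        elif op == "ffn":
            b, h, wd, c = x.shape
            tokens = x.reshape(b, h * wd, c)
            hid = _nn.relu(_nn.layer_norm(tokens) @ w[f"{name}_w1"])
            tokens = tokens + hid @ w[f"{name}_w2"]
            x = tokens.reshape(b, h, wd, c)
        elif op == "linear":
            x = _nn.rms_norm(x @ w[name])
    return x, attn_weights


def extract_features(images, cfg: BackboneConfig, weights: dict[str, np.ndarray],
                     rng: np.random.Generator | None = None,
                     batch_size: int = 16, return_attention: bool = False):
    """Run the backbone over a batch of [-1, 1]-normalized images.

    Returns a feature map of shape ``(B, g, g, 256)`` with ``g = input/16``
    (14 for the default 224 input, matching the head's expected grid).
    Deterministic unless ``rng`` is given and ``attention_dropout > 0``.
    """
    batch = _stack_batch(images, cfg)
    outs, attns = [], []
    for i in range(0, len(batch), batch_size):
        x, attn = _forward(batch[i:i + batch_size], cfg, weights, rng,
                           return_attention)
        outs.append(x)
        if return_attention:
            attns.append(attn)
    feats = np.concatenate(outs) if outs else np.zeros(
        (0, cfg.grid, cfg.grid, OUT_CHANNELS), np.float32)
    if return_attention:
        return feats, np.concatenate(attns)
    return feats


# ---------------------------------------------------------------------------
# analytic parameter / FLOP accounting (1 multiply-accumulate = 2 FLOPs)

def conv_flops(h_out: int, w_out: int, k: int, cin: int, cout: int,
               groups: int = 1) -> int:
    """FLOPs of one convolution: 2 * Hout * Wout * Cout * (k^2 * Cin / groups)."""
    return 2 * h_out * w_out * cout * (k * k * cin // groups)


def linear_flops(n_in: int, n_out: int, n_positions: int = 1) -> int:
    return 2 * n_in * n_out * n_positions


def _attention_flops(n: int, d: int) -> int:
    qkv = 3 * linear_flops(d, d, n)
    scores = 2 * n * n * d   # Q K^T
    mix = 2 * n * n * d      # attn @ V
    proj = linear_flops(d, d, n)
    return qkv + scores + mix + proj


def count_params_flops(cfg: BackboneConfig,
                       head_cfg=None) -> tuple[int, int]:
    """Exact analytic parameter and FLOP counts for one forward pass.

    ``head_cfg`` (a :class:`retikan.ckan.CkanConfig`) optionally adds the
    classification head on the ``grid x grid`` feature map.
    """
    params = 0
    flops = 0
    for layer in _plan(cfg):
        op = layer["op"]
        if op == "conv":
            k, cin, cout, hw = layer["k"], layer["cin"], layer["cout"], layer["hw"]
            params += k * k * cin * cout
            flops += conv_flops(hw, hw, k, cin, cout)
        elif op == "down_unit":
            k, cin, cout, hw = layer["k"], layer["cin"], layer["cout"], layer["hw"]
            half = cout // 2
            params += k * k * cin + cin * half            # branch a
            params += cin * half + k * k * half + half * half  # branch b
            flops += conv_flops(hw, hw, k, cin, cin, groups=cin)
            flops += conv_flops(hw, hw, 1, cin, half)
            flops += conv_flops(2 * hw, 2 * hw, 1, cin, half)
            flops += conv_flops(hw, hw, k, half, half, groups=half)
            flops += conv_flops(hw, hw, 1, half, half)
        elif op == "shuffle_unit":
            k, c, hw = layer["k"], layer["c"], layer["hw"]
            half = c // 2
            params += half * half + k * k * half + half * half
            flops += conv_flops(hw, hw, 1, half, half)
            flops += conv_flops(hw, hw, k, half, half, groups=half)
            flops += conv_flops(hw, hw, 1, half, half)
        elif op == "attention":
            d, n = layer["d"], layer["n"]
            params += 4 * d * d
            flops += _attention_flops(n, d)
        elif op == "ffn":
            d, hid, n = layer["d"], layer["hidden"], layer["n"]
            params += d * hid + hid * d
            flops += linear_flops(d, hid, n) + linear_flops(hid, d, n)
        elif op == "linear":
            cin, cout, n = layer["cin"], layer["cout"], layer["n"]
            params += cin * cout
            flops += linear_flops(cin, cout, n)
    if head_cfg is not None:
        hp, hf = head_cfg.count_params_flops(cfg.grid)
        params += hp
        flops += hf
    return params, flops


# ---------------------------------------------------------------------------
# checkpointing: weights + embedded config in one .npz

def save_checkpoint(path: str | Path, cfg: BackboneConfig,
                    weights: dict[str, np.ndarray]) -> None:
    cfg_json = json.dumps(asdict(cfg))
    np.savez(Path(path), __config__=np.frombuffer(
        cfg_json.encode(), dtype=np.uint8), **weights)


def load_checkpoint(path: str | Path) -> tuple[BackboneConfig, dict[str, np.ndarray]]:
    data = np.load(Path(path))
    cfg = BackboneConfig(**json.loads(bytes(data["__config__"]).decode()))
    weights = {k: data[k] for k in data.files if k != "__config__"}
    return cfg, weights
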