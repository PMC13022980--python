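"""Convolutional Kolmogorov-Arnold classification head.

Five stages operating on the backbone's contextualized feature map
``(B, g, g, 256)``:

1. channel condenser — 1x1 convolution 256 -> 128;
2. univariate function bank — a depthwise convolution followed by a
   learnable clamped cubic B-spline applied elementwise per channel
   (the Kolmogorov-Arnold "inner functions");
3. superposition mixer — 1x1 convolution 128 -> 256 (the "outer" sum);
4. global average pooling over the spatial axes;
5. linear projection to 5 severity classes + softmax.

Inputs to the spline stage are batch-normalized so activations live inside
the spline's knot span ([-2, 2] by default); outside the span the spline
extrapolates by its boundary value.  Training minimizes cross-entropy plus
``lam * (mu1 * L1(coefficients) + mu2 * entropy(coefficients))`` — the usual
KAN sparsity regularizer — with Adam, minibatches, and early stopping on
validation loss.  All gradients are analytic; no autodiff framework is used.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from ._nn import pad_same, softmax

__all__ = [
    "SplineBank", "CkanConfig", "bspline_basis", "spline_apply",
    "init_head_params", "ckan_forward", "ckan_forward_stages",
    "spline_regularizer", "train_head", "head_param_count",
    "dense_head_param_count",
]


# ---------------------------------------------------------------------------
# clamped cubic B-splines

def _clamped_knot_vector(breakpoints: np.ndarray, order: int) -> np.ndarray:
    return np.r_[[breakpoints[0]] * order, breakpoints,
                 [breakpoints[-1]] * order]


def _basis_dense(x: np.ndarray, t: np.ndarray, k: int) -> np.ndarray:
    """Dense B-spline design matrix, shape ``x.shape + (n_basis,)``.

    Cox-de Boor in the triangular "basis functions" form, vectorized over
    ``x``.  ``x`` is assumed already clamped into ``[t[0], t[-1]]``.
    """
    n_basis = len(t) - k - 1
    flat = x.ravel()
    i = np.searchsorted(t, flat, side="right") - 1
    i = np.clip(i, k, len(t) - k - 2)

    n = np.zeros((flat.size, k + 1), dtype=x.dtype)
    n[:, 0] = 1.0
    left = np.empty((flat.size, k + 1), dtype=x.dtype)
    right = np.empty((flat.size, k + 1), dtype=x.dtype)
    for j in range(1, k + 1):
        left[:, j] = flat - t[i + 1 - j]
        right[:, j] = t[i + j] - flat
        saved = np.zeros(flat.size, dtype=x.dtype)
        for r in range(j):
            denom = right[:, r + 1] + left[:, j - r]
            temp = np.where(denom > 0, n[:, r] / np.where(denom > 0, denom, 1.0), 0.0)
            n[:, r] = saved + right[:, r + 1] * temp
            saved = left[:, j - r] * temp
        n[:, j] = saved

    dense = np.zeros((flat.size, n_basis), dtype=x.dtype)
    cols = i[:, None] - k + np.arange(k + 1)
    np.put_along_axis(dense, cols, n, axis=1)
    return dense.reshape(*x.shape, n_basis)


def _basis_and_derivative(x: np.ndarray, t: np.ndarray,
                          k: int) -> tuple[np.ndarray, np.ndarray]:
    """Dense design matrix and its derivative w.r.t. ``x`` (same shape)."""
    dense = _basis_dense(x, t, k)
    lower = _basis_dense(x, t, k - 1)          # n_basis + 1 columns
    n_basis = dense.shape[-1]
    d1 = t[k:k + n_basis] - t[:n_basis]
    d2 = t[k + 1:k + 1 + n_basis] - t[1:1 + n_basis]
    term1 = np.where(d1 > 0, k / np.where(d1 > 0, d1, 1.0), 0.0)
    term2 = np.where(d2 > 0, k / np.where(d2 > 0, d2, 1.0), 0.0)
    deriv = lower[..., :n_basis] * term1 - lower[..., 1:n_basis + 1] * term2
    return dense, deriv


class SplineBank:
    """Per-channel clamped cubic B-spline function bank on a shared knot grid.

    Parameters
    ----------
    n_channels
        Number of univariate functions (one per feature channel).
    n_knots
        Number of distinct breakpoints spanning ``interval`` (default 8).
    interval
        Input span; inputs outside it are clamped, so the spline
        extrapolates by its boundary value.
    coefficients
        Optional ``(n_channels, n_basis)`` initial coefficients; defaults
        to the identity function on the interval (Greville abscissae).
    """

    order = 3

    def __init__(self, n_channels: int, n_knots: int = 8,
                 interval: tuple[float, float] = (-2.0, 2.0),
                 coefficients: np.ndarray | None = None,
                 dtype=np.float64):
        if n_knots < 2:
            raise ValueError("need at least 2 knots")
        breakpoints = np.linspace(interval[0], interval[1], n_knots,
                                  dtype=dtype)
        if not np.all(np.diff(breakpoints) > 0):
            raise ValueError("knots must be strictly increasing")
        self.interval = (float(interval[0]), float(interval[1]))
        self.breakpoints = breakpoints
        self.knots = _clamped_knot_vector(breakpoints, self.order)
        self.n_basis = len(self.knots) - self.order - 1
        if coefficients is None:
            coefficients = np.tile(self.greville(), (n_channels, 1))
        coefficients = np.asarray(coefficients, dtype=dtype)
        if coefficients.shape != (n_channels, self.n_basis):
            raise ValueError(
                f"coefficients must be ({n_channels}, {self.n_basis}), "
                f"got {coefficients.shape}")
        self.coefficients = coefficients

    def greville(self) -> np.ndarray:
        """Coefficients that reproduce the identity function on the span."""
        k, t = self.order, self.knots
        return np.array([t[j + 1:j + 1 + k].mean() for j in range(self.n_basis)])

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.interval[0], self.interval[1])

    def design(self, x: np.ndarray) -> np.ndarray:
        """Dense basis values at (clamped) ``x``; shape ``x.shape + (n_basis,)``."""
        return _basis_dense(self.clamp(x), self.knots, self.order)

    def design_with_derivative(self, x: np.ndarray):
        """Basis and d(basis)/dx; the derivative is zero outside the span."""
        xc = self.clamp(x)
        dense, deriv = _basis_and_derivative(xc, self.knots, self.order)
        inside = ((x >= self.interval[0]) & (x <= self.interval[1]))
        return dense, deriv * inside[..., None]


def bspline_basis(x: float | np.ndarray, bank: SplineBank) -> np.ndarray:
    """Basis-value vector(s) at ``x``: nonnegative, summing to 1 on the span."""
    return bank.design(np.asarray(x, dtype=bank.coefficients.dtype))


def spline_apply(x: np.ndarray, bank: SplineBank) -> np.ndarray:
    """Apply the per-channel splines elementwise to ``(..., C)`` input."""
    dense = bank.design(x)
    return np.einsum("...cn,cn->...c", dense, bank.coefficients)


# ---------------------------------------------------------------------------
# head configuration and parameters

@dataclass(frozen=True)
class CkanConfig:
    """Shape and regularization settings of the cKAN head."""

    in_channels: int = 256
    condensed_channels: int = 128
    out_channels: int = 256
    n_classes: int = 5
    hidden_units: int = 128
    lam: float = 1e-4
    mu1: float = 1.0
    mu2: float = 1.0
    dropout: float = 0.3
    n_knots: int = 8
    spline_interval: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self) -> None:
        for name in ("in_channels", "condensed_channels", "out_channels",
                     "n_classes", "hidden_units", "n_knots"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lam", "mu1", "mu2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def n_basis(self) -> int:
        return self.n_knots + SplineBank.order - 1

    def count_params_flops(self, grid: int = 14) -> tuple[int, int]:
        """Analytic parameter/FLOP count of the head on a grid x grid map."""
        ci, cc, co, k = self.in_channels, self.condensed_channels, \
            self.out_channels, self.n_classes
        params = (ci * cc + cc) + 2 * cc + (9 * cc + cc) \
            + cc * self.n_basis + (cc * co + co) + (co * k + k)
        g2 = grid * grid
        flops = 2 * g2 * cc * ci + 2 * g2 * cc * 9 \
            + 2 * g2 * cc * self.n_basis + 2 * g2 * co * cc + 2 * co * k
        return params, flops


def head_param_count(cfg: CkanConfig) -> int:
    return cfg.count_params_flops()[0]


def dense_head_param_count(cfg: CkanConfig, grid: int = 14) -> int:
    """Parameters of the flatten -> linear baseline head on the same input."""
    return grid * grid * cfg.in_channels * cfg.n_classes + cfg.n_classes


def init_head_params(cfg: CkanConfig, seed: int = 0,
                     dtype=np.float32) -> dict[str, np.ndarray]:
    """Seeded initial parameters.

    The spline starts as the identity function (Greville coefficients), the
    depthwise kernel as a centre-delta, and the linear layers with small
    He-style noise, so the untrained head is a benign near-linear map.
    """
    rng = np.random.default_rng(seed)
    ci, cc, co, k = (cfg.in_channels, cfg.condensed_channels,
                     cfg.out_channels, cfg.n_classes)
    bank = SplineBank(cc, cfg.n_knots, cfg.spline_interval, dtype=dtype)
    dw = np.zeros((3, 3, cc), dtype=dtype)
    dw[1, 1, :] = 1.0
    dw += rng.normal(0.0, 0.02, dw.shape).astype(dtype)
    params = {
        "w1": rng.normal(0.0, np.sqrt(2.0 / ci), (ci, cc)).astype(dtype),
        "b1": np.zeros(cc, dtype=dtype),
        "bn_gamma": np.ones(cc, dtype=dtype),
        "bn_beta": np.zeros(cc, dtype=dtype),
        "dw": dw,
        "dw_b": np.zeros(cc, dtype=dtype),
        "spline_coef": bank.coefficients.astype(dtype),
        "w3": rng.normal(0.0, np.sqrt(2.0 / cc), (cc, co)).astype(dtype),
        "b3": np.zeros(co, dtype=dtype),
        "w5": rng.normal(0.0, 0.01, (co, k)).astype(dtype),
        "b5": np.zeros(k, dtype=dtype),
    }
    # running batchnorm statistics (not trained by gradient)
    params["bn_mean"] = np.zeros(cc, dtype=dtype)
    params["bn_var"] = np.ones(cc, dtype=dtype)
    return params


_TRAINABLE = ("w1", "b1", "bn_gamma", "bn_beta", "dw", "dw_b",
              "spline_coef", "w3", "b3", "w5", "b5")
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _bank_from_params(cfg: CkanConfig, params: dict) -> SplineBank:
    return SplineBank(cfg.condensed_channels, cfg.n_knots,
                      cfg.spline_interval, coefficients=params["spline_coef"],
                      dtype=params["spline_coef"].dtype)


def _check_input(z: np.ndarray, cfg: CkanConfig) -> None:
    if z.ndim != 4:
        raise ValueError(f"stage 0 expects (B, H, W, C) input, got {z.shape}")
    if z.shape[-1] != cfg.in_channels:
        raise ValueError(
            f"stage 1 (channel condenser) expects {cfg.in_channels} input "
            f"channels, got {z.shape[-1]}")


def _dw3_forward(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 'same' depthwise convolution as 9 shifted multiply-adds."""
    h, wd = x.shape[1], x.shape[2]
    xp = pad_same(x, 3)
    out = np.zeros_like(x)
    for k in range(3):
        for l in range(3):
            out += xp[:, k:k + h, l:l + wd, :] * w[k, l]
    return out


def _dw3_weight_grad(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    h, wd = x.shape[1], x.shape[2]
    xp = pad_same(x, 3)
    gw = np.empty((3, 3, x.shape[-1]), dtype=x.dtype)
    for k in range(3):
        for l in range(3):
            gw[k, l] = (xp[:, k:k + h, l:l + wd, :] * g).sum(axis=(0, 1, 2))
    return gw


def ckan_forward_stages(z: np.ndarray, cfg: CkanConfig, params: dict,
                        train: bool = False,
                        rng: np.random.Generator | None = None) -> dict:
    """Forward pass returning every intermediate stage tensor.

    Keys: ``condensed`` (stage 1), ``pre_spline`` (depthwise-conv output
    entering the spline), ``spline`` (stage 2), ``mixed`` (stage 3),
    ``pooled`` (stage 4), ``logits`` and ``probs`` (stage 5).
    """
    _check_input(z, cfg)
    z = z.astype(params["w1"].dtype, copy=False)
    x1 = z @ params["w1"] + params["b1"]

    if train:
        mu = x1.mean(axis=(0, 1, 2))
        var = x1.var(axis=(0, 1, 2))
    else:
        mu, var = params["bn_mean"], params["bn_var"]
    xh = (x1 - mu) / np.sqrt(var + _BN_EPS)
    x2in = params["bn_gamma"] * xh + params["bn_beta"]

    x2d = _dw3_forward(x2in, params["dw"]) + params["dw_b"]
    bank = _bank_from_params(cfg, params)
    u = spline_apply(x2d, bank)

    x3 = u @ params["w3"] + params["b3"]
    pooled = x3.mean(axis=(1, 2))
    drop = pooled
    if train and cfg.dropout > 0.0 and rng is not None:
        mask = rng.random(pooled.shape) >= cfg.dropout
        drop = pooled * mask / (1.0 - cfg.dropout)
    logits = drop @ params["w5"] + params["b5"]
    return {"condensed": x1, "pre_spline": x2d, "spline": u, "mixed": x3,
            "pooled": pooled, "logits": logits, "probs": softmax(logits)}


def ckan_forward(z: np.ndarray, cfg: CkanConfig, params: dict) -> np.ndarray:
    """Class-probability matrix ``(B, n_classes)``; rows sum to 1."""
    return ckan_forward_stages(z, cfg, params, train=False)["probs"]


# ---------------------------------------------------------------------------
# regularizer (L1 + coefficient-entropy, the KAN sparsity penalty)

def spline_regularizer(coefficients: np.ndarray, mu1: float,
                       mu2: float) -> float:
    """``mu1 * mean|c|  +  mu2 * mean_bank entropy(|c| / sum|c|)``.

    Each row of ``coefficients`` is one spline bank; a bank whose mass
    concentrates on a single coefficient has zero entropy, and 0 log 0 = 0.
    """
    if mu1 < 0 or mu2 < 0:
        raise ValueError("mu1 and mu2 must be nonnegative")
    coefficients = np.atleast_2d(coefficients)
    absc = np.abs(coefficients)
    l1 = absc.mean() if absc.size else 0.0
    totals = absc.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    p = absc / safe
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = np.where(totals[:, 0] > 0, -plogp.sum(axis=1), 0.0).mean() \
        if absc.size else 0.0
    return float(mu1 * l1 + mu2 * entropy)


def _regularizer_grad(coefficients: np.ndarray, mu1: float,
                      mu2: float) -> np.ndarray:
    """Analytic (sub)gradient of :func:`spline_regularizer`."""
    absc = np.abs(coefficients)
    sign = np.sign(coefficients)
    n_banks, n_basis = coefficients.shape
    g = mu1 * sign / coefficients.size
    totals = absc.sum(axis=1, keepdims=True)
    nz = totals[:, 0] > 0
    p = np.where(totals > 0, absc / np.where(totals > 0, totals, 1.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
    ent = -np.where(p > 0, p * logp, 0.0).sum(axis=1, keepdims=True)
    # dS/d|c_j| = (-log p_j - S) / total  for p_j > 0
    dent = np.where(p > 0, (-logp - ent) / np.where(totals > 0, totals, 1.0), 0.0)
    g = g + mu2 * nz[:, None] * dent * sign / n_banks
    return g


# ---------------------------------------------------------------------------
# analytic forward/backward and training

def _forward_backward(z: np.ndarray, y: np.ndarray, cfg: CkanConfig,
                      params: dict, rng: np.random.Generator | None):
    """One training step's loss and analytic gradients for a minibatch."""
    dtype = params["w1"].dtype
    z = z.astype(dtype, copy=False)
    b = z.shape[0]
    nhw = b * z.shape[1] * z.shape[2]

    x1 = z @ params["w1"] + params["b1"]
    mu = x1.mean(axis=(0, 1, 2))
    var = x1.var(axis=(0, 1, 2))
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xh = (x1 - mu) * inv
    x2in = params["bn_gamma"] * xh + params["bn_beta"]

    x2d = _dw3_forward(x2in, params["dw"]) + params["dw_b"]
    bank = _bank_from_params(cfg, params)
    dense, deriv = bank.design_with_derivative(x2d)
    u = np.einsum("bhwcn,cn->bhwc", dense, params["spline_coef"],
                  optimize=True)

    x3 = u @ params["w3"] + params["b3"]
    pooled = x3.mean(axis=(1, 2))
    if cfg.dropout > 0.0 and rng is not None:
        mask = (rng.random(pooled.shape) >= cfg.dropout).astype(dtype)
        drop = pooled * mask / (1.0 - cfg.dropout)
    else:
        mask = None
        drop = pooled
    logits = drop @ params["w5"] + params["b5"]
    probs = softmax(logits)
    ce = -np.log(np.maximum(probs[np.arange(b), y], 1e-12)).mean()
    reg = spline_regularizer(params["spline_coef"], cfg.mu1, cfg.mu2)
    loss = ce + cfg.lam * reg

    grads: dict[str, np.ndarray] = {}
    glogits = probs.copy()
    glogits[np.arange(b), y] -= 1.0
    glogits /= b
    grads["w5"] = drop.T @ glogits
    grads["b5"] = glogits.sum(axis=0)
    gdrop = glogits @ params["w5"].T
    gpooled = gdrop * mask / (1.0 - cfg.dropout) if mask is not None else gdrop

    gx3 = np.broadcast_to(
        gpooled[:, None, None, :] / (z.shape[1] * z.shape[2]), x3.shape)
    grads["w3"] = np.einsum("bhwc,bhwo->co", u, gx3, optimize=True)
    grads["b3"] = gx3.sum(axis=(0, 1, 2))
    gu = gx3 @ params["w3"].T

    grads["spline_coef"] = np.einsum("bhwcn,bhwc->cn", dense, gu,
                                     optimize=True)
    grads["spline_coef"] += cfg.lam * _regularizer_grad(
        params["spline_coef"].astype(np.float64), cfg.mu1, cfg.mu2
    ).astype(dtype)
    du_dx = np.einsum("bhwcn,cn->bhwc", deriv, params["spline_coef"],
                      optimize=True)
    gx2d = gu * du_dx

    grads["dw_b"] = gx2d.sum(axis=(0, 1, 2))
    grads["dw"] = _dw3_weight_grad(x2in, gx2d)
    # input gradient of a 'same' depthwise conv = correlation with the
    # spatially flipped kernel
    gx2in = _dw3_forward(gx2d, np.ascontiguousarray(params["dw"][::-1, ::-1]))

    grads["bn_gamma"] = (gx2in * xh).sum(axis=(0, 1, 2))
    grads["bn_beta"] = gx2in.sum(axis=(0, 1, 2))
    gxh = gx2in * params["bn_gamma"]
    gvar = (gxh * (x1 - mu)).sum(axis=(0, 1, 2)) * (-0.5) * inv ** 3
    gmu = -(gxh.sum(axis=(0, 1, 2)) * inv) \
        - 2.0 * gvar * (x1 - mu).mean(axis=(0, 1, 2))
    gx1 = gxh * inv + (2.0 / nhw) * gvar * (x1 - mu) + gmu / nhw

    grads["w1"] = np.einsum("bhwi,bhwo->io", z, gx1, optimize=True)
    grads["b1"] = gx1.sum(axis=(0, 1, 2))

    batch_stats = (mu, var)
    return loss, ce, grads, batch_stats


class _Adam:
    def __init__(self, params: dict, lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(params[k]) for k in _TRAINABLE}
        self.v = {k: np.zeros_like(params[k]) for k in _TRAINABLE}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in _TRAINABLE:
            g = grads[k]
            if self.wd and k.startswith("w"):
                g = g + self.wd * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def evaluate_head(z: np.ndarray, y: np.ndarray, cfg: CkanConfig,
                  params: dict, batch_size: int = 64) -> tuple[float, float]:
    """(cross-entropy loss, top-1 accuracy) in inference mode."""
    losses, correct = [], 0
    for i in range(0, len(z), batch_size):
        probs = ckan_forward(z[i:i + batch_size], cfg, params)
        yy = y[i:i + batch_size]
        losses.append(-np.log(np.maximum(
            probs[np.arange(len(yy)), yy], 1e-12)).sum())
        correct += (probs.argmax(axis=1) == yy).sum()
    return float(np.sum(losses) / len(z)), float(correct / len(z))


def train_head(features: np.ndarray, labels: np.ndarray, cfg: CkanConfig,
               val_features: np.ndarray | None = None,
               val_labels: np.ndarray | None = None,
               epochs: int = 50, lr: float = 1e-3, weight_decay: float = 0.0,
               batch_size: int = 16, patience: int = 10,
               seed: int = 0, dtype=np.float32) -> tuple[dict, dict]:
    """Train the head on frozen backbone features.

    Returns ``(params, history)`` where ``history`` has per-epoch
    ``train_loss`` (objective, including the regularizer), ``train_ce``
    and, when a validation split is given, ``val_loss`` / ``val_accuracy``.
    Early stopping restores the parameters of the best validation epoch.
    Fully reproducible given ``seed``.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    if len(features) == 0:
        raise ValueError("empty training set")
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels must contain at least 2 classes")

    params = init_head_params(cfg, seed=seed, dtype=dtype)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    opt = _Adam(params, lr=lr, weight_decay=weight_decay)
    history: dict[str, list[float]] = {"train_loss": [], "train_ce": []}
    has_val = val_features is not None and val_labels is not None
    if has_val:
        history["val_loss"] = []
        history["val_accuracy"] = []
    best_val = np.inf
    best_params = None
    bad_epochs = 0

    n = len(features)
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss, ep_ce = 0.0, 0.0
        for i in range(0, n, batch_size):
            idx = order[i:i + batch_size]
            loss, ce, grads, (mu, var) = _forward_backward(
                features[idx], labels[idx], cfg, params, rng)
            opt.step(params, grads)
            params["bn_mean"] = ((1 - _BN_MOMENTUM) * params["bn_mean"]
                                 + _BN_MOMENTUM * mu)
            params["bn_var"] = ((1 - _BN_MOMENTUM) * params["bn_var"]
                                + _BN_MOMENTUM * var)
            ep_loss += loss * len(idx)
            ep_ce += ce * len(idx)
        history["train_loss"].append(ep_loss / n)
        history["train_ce"].append(ep_ce / n)
        if has_val:
            vloss, vacc = evaluate_head(val_features, val_labels, cfg, params)
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(vacc)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_params = copy.deepcopy(params)
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > patience:
                    break
    if best_params is not None:
        params = best_params
    return params, history
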