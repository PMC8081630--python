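"""Siamese patch-scoring network and its training on synthetic patch pairs.

The network compares two 16x16 patches and emits a scalar in [0, 1]: values
near 1 mean the salient feature sits in the first patch, near 0 in the
second.  Both branches share one parameter set (three 3x3 stride-1
convolutions with ReLU, then a 2x2/2 max-pool); the head maps the
*difference* of the two branch feature vectors through a bias-free linear
layer and a sigmoid, so

    score(A, B) + score(B, A) == 1        (exactly)
    score(A, A) == 0.5                    (exactly)

hold by construction.  Everything is plain numpy (im2col convolutions,
manual backprop, Adam), deterministic for a fixed seed.

Training data are procedurally textured patches paired with Gaussian-blurred
copies: the label marks which member is sharp.  That sharp-vs-degraded proxy
is what lets the score discriminate which subband locally carries detail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, InputError

__all__ = [
    "CNNConfig",
    "PatchPair",
    "ScoringModel",
    "build_model",
    "make_training_pairs",
    "train_model",
    "score_pair",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CNNConfig:
    patch_size: int = 16
    kernel_size: int = 3
    conv_stride: int = 1
    pool_size: int = 2
    pool_stride: int = 2
    n_conv_layers_per_branch: int = 3
    channels_per_layer: tuple[int, ...] = (16, 32, 64)
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels_per_layer", tuple(self.channels_per_layer))
        if len(self.channels_per_layer) != self.n_conv_layers_per_branch:
            raise ConfigurationError("channels_per_layer length must match layer count")
        if self.kernel_size != 3 or self.conv_stride != 1:
            raise ConfigurationError("only 3x3 stride-1 convolutions are supported")
        if self.pool_size != 2 or self.pool_stride != 2:
            raise ConfigurationError("only 2x2 stride-2 pooling is supported")
        side = self.patch_size - self.n_conv_layers_per_branch * (self.kernel_size - 1)
        if side < self.pool_size or side % self.pool_stride:
            raise ConfigurationError(
                f"patch_size {self.patch_size} incompatible with conv/pool arithmetic"
            )

    @property
    def feature_dim(self) -> int:
        side = self.patch_size - self.n_conv_layers_per_branch * (self.kernel_size - 1)
        return (side // self.pool_stride) ** 2 * self.channels_per_layer[-1]


@dataclass
class PatchPair:
    """A labelled pair of square patches; label 1 means patch_a is the sharp one."""

    patch_a: np.ndarray
    patch_b: np.ndarray
    label: float


@dataclass
class ScoringModel:
    config: CNNConfig
    params: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "ScoringModel":
        return ScoringModel(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------- layers

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (B, C, H, W) -> (B, H-k+1, W-k+1, C*k*k)
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    b, c, ho, wo = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, ho, wo, c * k * k)


def _conv_forward(x, w):
    # w: (C_out, C_in*k*k); valid convolution, stride 1
    cols = _im2col(x, 3)
    out = cols @ w.T
    return out.transpose(0, 3, 1, 2), cols


def _conv_backward(d_out, cols, w, x_shape):
    b, c_in, h, wd = x_shape
    d_flat = d_out.transpose(0, 2, 3, 1)  # (B, Ho, Wo, C_out)
    dw = np.tensordot(d_flat, cols, axes=([0, 1, 2], [0, 1, 2]))
    # gradient wrt input: full correlation of d_out with flipped kernels
    pad = np.pad(d_out, ((0, 0), (0, 0), (2, 2), (2, 2)))
    w_r = w.reshape(-1, c_in, 3, 3)[:, :, ::-1, ::-1]  # (C_out, C_in, 3, 3)
    w_t = w_r.transpose(1, 0, 2, 3).reshape(c_in, -1)  # (C_in, C_out*9)
    cols_p = _im2col(pad, 3)
    dx = (cols_p @ w_t.T).transpose(0, 3, 1, 2)
    return dx, dw


def _pool_forward(x):
    b, c, h, w = x.shape
    r = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        b, c, h // 2, w // 2, 4
    )
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(d_out, idx, x_shape):
    b, c, h, w = x_shape
    dr = np.zeros((b, c, h // 2, w // 2, 4), dtype=d_out.dtype)
    np.put_along_axis(dr, idx[..., None], d_out[..., None], axis=-1)
    return dr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        b, c, h, w
    )


def _branch_forward(model: ScoringModel, x: np.ndarray, keep: bool = False):
    """x: (B, H, W) -> feature matrix (B, feature_dim); optionally keep cache."""
    cache = []
    a = (x[:, None, :, :] - 0.5).astype(np.float32)
    for i in range(model.config.n_conv_layers_per_branch):
        w = model.params[f"conv{i}_w"]
        b = model.params[f"conv{i}_b"]
        pre, cols = _conv_forward(a, w)
        pre = pre + b[None, :, None, None]
        act = np.maximum(pre, 0.0)
        if keep:
            cache.append((a.shape, cols, pre > 0))
        a = act
    pooled, idx = _pool_forward(a)
    if keep:
        cache.append((a.shape, idx))
    return pooled.reshape(len(x), -1), cache


def _branch_backward(model: ScoringModel, d_feat: np.ndarray, cache, grads: dict) -> None:
    pool_shape, idx = cache[-1]
    b = len(d_feat)
    side = pool_shape[2] // 2
    d = d_feat.reshape(b, pool_shape[1], side, side)
    d = _pool_backward(d, idx, pool_shape)
    for i in reversed(range(model.config.n_conv_layers_per_branch)):
        x_shape, cols, relu_mask = cache[i]
        d = d * relu_mask
        w = model.params[f"conv{i}_w"]
        dx, dw = _conv_backward(d, cols, w, x_shape)
        grads[f"conv{i}_w"] += dw
        grads[f"conv{i}_b"] += d.sum(axis=(0, 2, 3))
        d = dx


def _forward_scores(model: ScoringModel, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    fa, _ = _branch_forward(model, a)
    fb, _ = _branch_forward(model, b)
    z = (fa - fb) @ model.params["head_w"]
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------- API

def build_model(config: CNNConfig | None = None) -> ScoringModel:
    """Deterministically initialised siamese scoring model (He-normal weights)."""
    config = config or CNNConfig()
    rng = np.random.default_rng(config.seed)
    params: dict[str, np.ndarray] = {}
    c_in = 1
    for i, c_out in enumerate(config.channels_per_layer):
        fan_in = c_in * config.kernel_size**2
        params[f"conv{i}_w"] = (
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        ).astype(np.float32)
        params[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
        c_in = c_out
    # bias-free head on the branch-feature difference: keeps the score
    # antisymmetric under swapping the two patches
    params["head_w"] = (
        rng.normal(0.0, 1.0 / np.sqrt(config.feature_dim), size=config.feature_dim)
    ).astype(np.float32)
    return ScoringModel(config=config, params=params, metadata={"seed": config.seed})


def make_training_pairs(
    n: int, seed: int, blur_sigma_range: tuple[float, float] = (0.75, 3.0)
) -> list[PatchPair]:
    """Sharp/blurred patch pairs with balanced labels.

    Each base patch is band-limited seeded noise (lightly smoothed white
    noise, rescaled to [0, 1]); its partner is a Gaussian-degraded copy with
    sigma drawn from ``blur_sigma_range``.  Exactly ceil(n/2) pairs put the
    sharp member first (label 1).
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    lo, hi = blur_sigma_range
    if hi <= 0 or hi < lo:
        raise ConfigurationError(f"degenerate blur_sigma_range {blur_sigma_range}")
    lo = max(lo, 1e-3)
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        base = rng.standard_normal((16, 16))
        base = gaussian_filter(base, 0.6, mode="wrap")
        base = (base - base.min()) / (base.max() - base.min() + 1e-12)
        sigma = rng.uniform(lo, hi)
        blurred = gaussian_filter(base, sigma, mode="reflect")
        if i % 2 == 0:
            pairs.append(PatchPair(base.astype(np.float32), blurred.astype(np.float32), 1.0))
        else:
            pairs.append(PatchPair(blurred.astype(np.float32), base.astype(np.float32), 0.0))
    return pairs


def _stack(pairs: list[PatchPair]):
    a = np.stack([p.patch_a for p in pairs]).astype(np.float32)
    b = np.stack([p.patch_b for p in pairs]).astype(np.float32)
    y = np.array([p.label for p in pairs], dtype=np.float32)
    return a, b, y


def train_model(
    model: ScoringModel,
    pairs: list[PatchPair],
    epochs: int = 10,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> ScoringModel:
    """Train with binary cross-entropy + Adam; records held-out accuracy.

    The last ``holdout_fraction`` of a seeded shuffle is held out and scored
    after training; accuracy lands in ``metadata['holdout_accuracy']``.
    Returns a trained copy; the input model is untouched.
    """
    if not pairs:
        raise InputError("empty training set")
    if len(pairs) < 100:
        raise InputError("need at least 100 pairs to train")
    model = model.copy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_hold = max(1, int(round(holdout_fraction * len(pairs))))
    train_idx, hold_idx = order[:-n_hold], order[-n_hold:]
    a, b, y = _stack(pairs)

    cfg = model.config
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    t = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    for _ in range(epochs):
        perm = rng.permutation(train_idx)
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            xa, xb, yb = a[batch], b[batch], y[batch]
            fa, ca = _branch_forward(model, xa, keep=True)
            fb, cb = _branch_forward(model, xb, keep=True)
            z = (fa - fb) @ model.params["head_w"]
            p = 1.0 / (1.0 + np.exp(-z))
            dz = ((p - yb) / len(batch)).astype(np.float32)
            grads = {k: np.zeros_like(v) for k, v in model.params.items()}
            grads["head_w"] = (fa - fb).T @ dz
            d_feat = dz[:, None] * model.params["head_w"][None, :]
            _branch_backward(model, d_feat, ca, grads)
            _branch_backward(model, -d_feat, cb, grads)
            t += 1
            lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for k in model.params:
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * grads[k]
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * grads[k] ** 2
                model.params[k] -= (
                    lr_t * m_state[k] / (np.sqrt(v_state[k]) + eps)
                ).astype(np.float32)

    scores = score_batch(model, a[hold_idx], b[hold_idx])
    acc = float(np.mean((scores > 0.5) == (y[hold_idx] > 0.5)))
    model.metadata.update(
        {"epochs": epochs, "train_seed": seed, "n_pairs": len(pairs), "holdout_accuracy": acc}
    )
    return model


def score_batch(model: ScoringModel, a: np.ndarray, b: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Scores for stacked patch arrays of shape (N, p, p)."""
    p = model.config.patch_size
    if a.shape != b.shape or a.shape[1:] != (p, p):
        raise InputError(f"expected (N, {p}, {p}) patch stacks, got {a.shape} / {b.shape}")
    out = np.empty(len(a))
    for start in range(0, len(a), chunk):
        sl = slice(start, start + chunk)
        out[sl] = _forward_scores(model, a[sl].astype(np.float32), b[sl].astype(np.float32))
    return out


def score_pair(model: ScoringModel, patch_a: np.ndarray, patch_b: np.ndarray) -> float:
    """Scalar in [0, 1]; higher means patch_a carries the salient feature."""
    p = model.config.patch_size
    patch_a = np.asarray(patch_a, dtype=np.float32)
    patch_b = np.asarray(patch_b, dtype=np.float32)
    if patch_a.shape != (p, p) or patch_b.shape != (p, p):
        raise InputError(f"patches must be {p}x{p}, got {patch_a.shape} and {patch_b.shape}")
    return float(score_batch(model, patch_a[None], patch_b[None])[0])


def save_model(model: ScoringModel, path) -> None:
    """Checkpoint: one npz archive of parameter arrays plus JSON metadata."""
    meta = json.dumps({"config": asdict(model.config), "metadata": model.metadata})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **model.params)


def load_model(path) -> ScoringModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["channels_per_layer"] = tuple(cfg_dict["channels_per_layer"])
    return ScoringModel(
        config=CNNConfig(**cfg_dict), params=params, metadata=meta["metadata"]
    )
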