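"""Bounded CNN regressor over stabilogram channel stacks.

Architecture: stacked 64x64 stabilogram channels -> conv(3x3, same) -> ReLU
-> maxpool(2x2) -> conv(3x3, same) -> ReLU -> maxpool(2x2) -> flatten ->
concatenate scalar features -> dense(d1) -> ReLU -> dropout -> dense(d2) ->
ReLU -> dropout -> single linear unit -> smooth bounded output
0.5 + 5 * sigmoid(z), which keeps every prediction strictly inside
(0.5, 5.5) on the 1-5 intensity scale.

Implemented directly on numpy (im2col convolutions, explicit backprop,
Adam); initialization is deterministic given the config seed, dropout is
active only during training, and multi-sensor input is handled purely by
the channel count of the stack.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

CONV_FILTER_GRID = (8, 16, 32)
DENSE_GRID = (8, 16, 32)
DROPOUT_GRID = (0.0, 0.2, 0.5)

LOWER_BOUND = 0.5
UPPER_BOUND = 5.5
_SPAN = UPPER_BOUND - LOWER_BOUND

FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; conv/dense/dropout values come from fixed grids."""

    conv_filters: int = 16
    dense_sizes: tuple = (32, 8)
    dropout_rate: float = 0.2
    n_input_channels: int = 13
    n_scalar_features: int = 8
    grid_size: int = 64
    learning_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.conv_filters not in CONV_FILTER_GRID:
            raise ValueError(f"conv_filters must be in {CONV_FILTER_GRID}")
        if (len(self.dense_sizes) != 2
                or any(d not in DENSE_GRID for d in self.dense_sizes)):
            raise ValueError(f"dense_sizes must be a pair from {DENSE_GRID}")
        if self.dropout_rate not in DROPOUT_GRID:
            raise ValueError(f"dropout_rate must be in {DROPOUT_GRID}")
        if self.n_input_channels < 1:
            raise ValueError("n_input_channels must be >= 1")
        if self.n_scalar_features < 0:
            raise ValueError("n_scalar_features must be >= 0")
        if self.grid_size % 4 != 0:
            raise ValueError("grid_size must be divisible by 4")


def bounded_output(z):
    """Smooth transform mapping pre-activations onto (0.5, 5.5).

    value = 0.5 + 5 * sigmoid(z): strictly increasing, differentiable
    everywhere, attaining the bounds only in the infinite-|z| limit.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("pre-activation must be finite")
    return LOWER_BOUND + _SPAN * expit(z)


def bounded_output_grad(z):
    s = expit(np.asarray(z, dtype=float))
    return _SPAN * s * (1.0 - s)


# ---------------------------------------------------------------------------
# numpy layers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*9) patches for 3x3 same convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # (B, C, H, W, 3, 3) -> (B, H, W, C, 3, 3)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    return np.ascontiguousarray(win).reshape(b * h * w, c * 9)


def _conv_same(x: np.ndarray, weights: np.ndarray,
               bias: np.ndarray | None = None,
               cols: np.ndarray | None = None) -> tuple:
    """3x3 same-padding convolution; returns (output, patch matrix)."""
    b, c, h, w = x.shape
    f = weights.shape[0]
    if cols is None:
        cols = _im2col(x)
    out = cols @ weights.reshape(f, c * 9).T
    if bias is not None:
        out += bias
    return out.reshape(b, h, w, f).transpose(0, 3, 1, 2), cols


def _conv_backward_input(d_out: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Gradient wrt the conv input: correlation with flipped kernels."""
    flipped = weights[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    dx, _ = _conv_same(d_out, np.ascontiguousarray(flipped))
    return dx


def _maxpool(x: np.ndarray) -> tuple:
    """2x2 max pooling with deterministic (first-index) tie-breaking."""
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool_backward(d_out: np.ndarray, idx: np.ndarray,
                      in_shape: tuple) -> np.ndarray:
    b, c, h, w = in_shape
    dxr = np.zeros((b, c, h // 2, w // 2, 4), dtype=d_out.dtype)
    np.put_along_axis(dxr, idx[..., None], d_out[..., None], axis=-1)
    dxr = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dxr.reshape(b, c, h, w)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class BalanceCNN:
    """Bounded stabilogram CNN regressor; built via :func:`build_model`."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.conv_filters
        c = config.n_input_channels
        d1, d2 = config.dense_sizes
        flat = f * (config.grid_size // 4) ** 2
        s = config.n_scalar_features

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in),
                              size=shape).astype(np.float32)

        self.params = {
            "W1": he((f, c, 3, 3), c * 9), "b1": np.zeros(f, np.float32),
            "W2": he((f, f, 3, 3), f * 9), "b2": np.zeros(f, np.float32),
            "W3": he((flat + s, d1), flat + s), "b3": np.zeros(d1, np.float32),
            "W4": he((d1, d2), d1), "b4": np.zeros(d2, np.float32),
            # small output weights + zero bias put the initial mean
            # prediction at the midpoint 3.0 of the bounded scale
            "W5": (0.01 * rng.standard_normal((d2, 1))).astype(np.float32),
            "b5": np.zeros(1, np.float32),
        }

    # -- forward ---------------------------------------------------------

    def forward(self, grids: np.ndarray, scalars: np.ndarray,
                train: bool = False,
                dropout_rng: np.random.Generator | None = None) -> tuple:
        """Forward pass; returns (predictions, cache for backprop)."""
        p = self.params
        x = np.asarray(grids, dtype=np.float32)
        s = np.asarray(scalars, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != self.config.n_input_channels:
            raise ValueError("grids must be (B, C, grid, grid)")

        a1, cols1 = _conv_same(x, p["W1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        p1, idx1 = _maxpool(r1)
        a2, cols2 = _conv_same(p1, p["W2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        p2, idx2 = _maxpool(r2)
        flat = p2.reshape(p2.shape[0], -1)
        h0 = np.concatenate([flat, s], axis=1)

        z1 = h0 @ p["W3"] + p["b3"]
        h1 = np.maximum(z1, 0.0)
        m1 = self._dropout_mask(h1.shape, train, dropout_rng)
        h1d = h1 * m1
        z2 = h1d @ p["W4"] + p["b4"]
        h2 = np.maximum(z2, 0.0)
        m2 = self._dropout_mask(h2.shape, train, dropout_rng)
        h2d = h2 * m2
        z = (h2d @ p["W5"] + p["b5"])[:, 0]
        preds = bounded_output(z)
        cache = dict(cols1=cols1, a1=a1, r1shape=r1.shape, idx1=idx1,
                     p1=p1, cols2=cols2, a2=a2, r2shape=r2.shape, idx2=idx2,
                     p2shape=p2.shape, h0=h0, z1=z1, m1=m1, h1d=h1d,
                     z2=z2, m2=m2, h2d=h2d, z=z)
        return preds, cache

    def predict(self, grids: np.ndarray, scalars: np.ndarray) -> np.ndarray:
        """Inference pass: dropout inactive, bit-reproducible."""
        preds, _ = self.forward(grids, scalars, train=False)
        return preds

    def _dropout_mask(self, shape, train, rng):
        rate = self.config.dropout_rate
        if not train or rate == 0.0:
            return np.ones(shape, dtype=np.float32)
        if rng is None:
            raise ValueError("dropout requires a generator during training")
        return ((rng.random(shape) >= rate) / (1.0 - rate)).astype(np.float32)

    # -- backward --------------------------------------------------------

    def backward(self, cache: dict, d_pred: np.ndarray) -> dict:
        """Gradients of the loss wrt every parameter given dL/dprediction."""
        p = self.params
        f = self.config.conv_filters
        dz = (d_pred * bounded_output_grad(cache["z"])).astype(np.float32)

        grads = {}
        grads["W5"] = cache["h2d"].T @ dz[:, None]
        grads["b5"] = np.array([dz.sum()], dtype=np.float32)
        dh2d = dz[:, None] @ p["W5"].T
        dz2 = dh2d * cache["m2"] * (cache["z2"] > 0)
        grads["W4"] = cache["h1d"].T @ dz2
        grads["b4"] = dz2.sum(axis=0)
        dh1d = dz2 @ p["W4"].T
        dz1 = dh1d * cache["m1"] * (cache["z1"] > 0)
        grads["W3"] = cache["h0"].T @ dz1
        grads["b3"] = dz1.sum(axis=0)
        dh0 = dz1 @ p["W3"].T

        n_flat = int(np.prod(cache["p2shape"][1:]))
        dflat = dh0[:, :n_flat].reshape(cache["p2shape"])
        dr2 = _maxpool_backward(dflat, cache["idx2"], cache["r2shape"])
        da2 = dr2 * (cache["a2"] > 0)
        da2_col = da2.transpose(0, 2, 3, 1).reshape(-1, f)
        grads["W2"] = (cache["cols2"].T @ da2_col).T.reshape(p["W2"].shape)
        grads["b2"] = da2_col.sum(axis=0)
        dp1 = _conv_backward_input(da2, p["W2"])
        dr1 = _maxpool_backward(dp1, cache["idx1"], cache["r1shape"])
        da1 = dr1 * (cache["a1"] > 0)
        da1_col = da1.transpose(0, 2, 3, 1).reshape(-1, f)
        grads["W1"] = (cache["cols1"].T @ da1_col).T.reshape(p["W1"].shape)
        grads["b1"] = da1_col.sum(axis=0)
        return grads

    # -- bookkeeping -----------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy_params(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict) -> None:
        self.params = {k: v.copy() for k, v in params.items()}

    def save(self, path) -> None:
        """Self-describing, versioned snapshot (npz with embedded config)."""
        meta = {"format_version": FORMAT_VERSION,
                "config": {**self.config.__dict__,
                           "dense_sizes": list(self.config.dense_sizes)}}
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "BalanceCNN":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta["format_version"] != FORMAT_VERSION:
                raise ValueError("unknown model format version")
            cfg = meta["config"]
            cfg["dense_sizes"] = tuple(cfg["dense_sizes"])
            model = cls(ModelConfig(**cfg))
            model.params = {k: data[k] for k in model.params}
        return model


def build_model(config: ModelConfig) -> BalanceCNN:
    """Construct the bounded CNN regressor for a config from the search grids."""
    return BalanceCNN(config)


@dataclass
class Adam:
    """Adam optimizer (the standard first/second-moment update)."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)
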