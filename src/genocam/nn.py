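"""A small convolutional network with explicit forward/backward passes.

The architecture is fixed by design: three conv stages sharing one filter
size, each stage ``conv('same', k) -> ReLU -> maxpool(2x2, stride 2)``, with
inverted dropout on the last conv stage's activations, then flatten and a
dense layer into a 2-way softmax. Training is plain minibatch SGD with
momentum, cross-entropy loss and an L2 penalty on all weight matrices.

Everything runs on numpy arrays in channels-last layout (N, H, W, C);
convolutions use im2col so the heavy lifting is a single matrix product.
Writing the backward pass by hand also gives us exact gradients of the class
score with respect to the last conv activations, which is precisely what
Grad-CAM needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dataset import ValidationError

FILTER_SIZES = (3, 5, 7)
LR_BOUNDS = (1e-3, 1.0)
MOMENTUM_BOUNDS = (0.9, 0.98)
L2_BOUNDS = (1e-10, 1e-2)


@dataclass(frozen=True)
class HyperParams:
    """The four tuned hyperparameters and their search box."""

    filter_size: int = 5
    learning_rate: float = 0.01
    momentum: float = 0.9
    l2: float = 1e-6

    def __post_init__(self) -> None:
        if self.filter_size not in FILTER_SIZES:
            raise ValidationError(f"filter_size must be one of {FILTER_SIZES}")
        if not (LR_BOUNDS[0] <= self.learning_rate <= LR_BOUNDS[1]):
            raise ValidationError(f"learning_rate outside {LR_BOUNDS}")
        if not (MOMENTUM_BOUNDS[0] <= self.momentum <= MOMENTUM_BOUNDS[1]):
            raise ValidationError(f"momentum outside {MOMENTUM_BOUNDS}")
        if not (L2_BOUNDS[0] <= self.l2 <= L2_BOUNDS[1]):
            raise ValidationError(f"l2 outside {L2_BOUNDS}")


@dataclass
class ModelConfig:
    """Fixed architecture skeleton and training bookkeeping."""

    input_side: int = 45
    input_channels: int = 3
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    dropout_rate: float = 0.5
    batch_size: int = 128
    max_epochs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_channels not in (1, 3):
            raise ValidationError("input_channels must be 1 or 3")
        if len(self.conv_filters) != 3:
            raise ValidationError("exactly three conv stages are supported")
        if self.input_side < 8:
            raise ValidationError(
                f"input_side {self.input_side} too small to survive three "
                "stride-2 poolings (need >= 8)"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must be in [0, 1)")


# ---- layer primitives ---------------------------------------------------


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, k*k*C) patches under 'same' zero padding."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, H, W, C, k, k)
    n, h, w = x.shape[:3]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, -1)


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """'same' stride-1 convolution. w: (k, k, Cin, F)."""
    k, _, cin, f = w.shape
    n, h, wid, _ = x.shape
    cols = _im2col(x, k)
    out = cols @ w.reshape(-1, f) + b
    return out.reshape(n, h, wid, f), cols


def conv_backward(dout: np.ndarray, cols: np.ndarray, x_shape, w: np.ndarray):
    k, _, cin, f = w.shape
    n, h, wid, _ = x_shape
    dflat = dout.reshape(-1, f)
    dw = (cols.T @ dflat).reshape(w.shape)
    db = dflat.sum(axis=0)
    dcols = dflat @ w.reshape(-1, f).T  # (N*H*W, k*k*Cin)
    # scatter patches back (col2im)
    pad = k // 2
    dxp = np.zeros((n, h + 2 * pad, wid + 2 * pad, cin))
    dcols = dcols.reshape(n, h, wid, k, k, cin)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + wid, :] += dcols[:, :, :, i, j, :]
    dx = dxp[:, pad : pad + h, pad : pad + wid, :]
    return dx, dw, db


def maxpool_forward(x: np.ndarray):
    """2x2 stride-2 max pooling; odd trailing rows/cols are dropped."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xr = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
    xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
    arg = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
    return out, (arg, x.shape)


def maxpool_backward(dout: np.ndarray, cache):
    arg, x_shape = cache
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    dxr = np.zeros((n, h2, w2, c, 4))
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=-1)
    dxr = dxr.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    dx = np.zeros(x_shape)
    dx[:, : h2 * 2, : w2 * 2, :] = dxr.reshape(n, h2 * 2, w2 * 2, c)
    return dx


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; the trial failed but the run is not fatal."""


class ConvNet:
    """The fixed 3-conv-stage case/control classifier."""

    N_CLASSES = 2

    def __init__(self, config: ModelConfig, hp: HyperParams, rng: np.random.Generator | None = None):
        self.config = config
        self.hp = hp
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        k = hp.filter_size
        chans = [config.input_channels, *config.conv_filters]
        self.params: dict[str, np.ndarray] = {}
        for i in range(3):
            fan_in = k * k * chans[i]
            self.params[f"w{i + 1}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(k, k, chans[i], chans[i + 1])
            )
            self.params[f"b{i + 1}"] = np.zeros(chans[i + 1])
        side = config.input_side
        self.spatial_sizes = []
        for _ in range(3):
            side //= 2  # 'same' conv keeps size; each pool halves (floor)
            self.spatial_sizes.append(side)
        flat = self.spatial_sizes[-1] ** 2 * config.conv_filters[-1]
        self.params["wd"] = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, self.N_CLASSES))
        self.params["bd"] = np.zeros(self.N_CLASSES)

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, dropout_rng: np.random.Generator | None = None):
        """Return (logits, cache). x: (N, side, side, C) floats in [0, 1]."""
        p = self.params
        cache: dict = {"x": x}
        a = x
        for i in (1, 2, 3):
            z, cols = conv_forward(a, p[f"w{i}"], p[f"b{i}"])
            r = np.maximum(z, 0.0)
            cache[f"cols{i}"] = cols
            cache[f"zpos{i}"] = z > 0
            cache[f"xshape{i}"] = a.shape
            if i == 3:
                cache["a3"] = r  # last conv activations (Grad-CAM target)
                if train and self.config.dropout_rate > 0:
                    keep = 1.0 - self.config.dropout_rate
                    mask = (dropout_rng.random(r.shape) < keep) / keep
                    r = r * mask
                    cache["dropmask"] = mask
            a, pcache = maxpool_forward(r)
            cache[f"pool{i}"] = pcache
        n = a.shape[0]
        flat = a.reshape(n, -1)
        cache["flat"] = flat
        logits = flat @ p["wd"] + p["bd"]
        cache["pooled_shape"] = a.shape
        return logits, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for s in range(0, len(x), batch_size):
            logits, _ = self.forward(x[s : s + batch_size])
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.vstack(out)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    # -- backward ---------------------------------------------------------

    def _backward_from_logits(self, dlogits: np.ndarray, cache: dict, want_params: bool = True):
        """Backprop dlogits to (grads, d_a3). grads is None if not requested."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        if want_params:
            grads["wd"] = cache["flat"].T @ dlogits
            grads["bd"] = dlogits.sum(axis=0)
        da = (dlogits @ p["wd"].T).reshape(cache["pooled_shape"])
        d_a3 = None
        for i in (3, 2, 1):
            dr = maxpool_backward(da, cache[f"pool{i}"])
            if i == 3:
                if "dropmask" in cache:
                    dr = dr * cache["dropmask"]
                d_a3 = dr
            dz = dr * cache[f"zpos{i}"]
            da, dw, db = conv_backward(dz, cache[f"cols{i}"], cache[f"xshape{i}"], p[f"w{i}"])
            if want_params:
                grads[f"w{i}"] = dw
                grads[f"b{i}"] = db
        return grads if want_params else None, d_a3

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, dropout_rng: np.random.Generator):
        """Mean cross-entropy + L2 on weights; returns (loss, grads)."""
        n = len(x)
        logits, cache = self.forward(x, train=True, dropout_rng=dropout_rng)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        ce = -np.log(probs[np.arange(n), y] + 1e-12).mean()
        l2_term = sum((self.params[k] ** 2).sum() for k in ("w1", "w2", "w3", "wd"))
        loss = ce + 0.5 * self.hp.l2 * l2_term
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads, _ = self._backward_from_logits(dlogits, cache)
        for k in ("w1", "w2", "w3", "wd"):
            grads[k] += self.hp.l2 * self.params[k]
        return loss, grads

    def class_score_grad_last_conv(self, x: np.ndarray, target_class: int):
        """Last conv activations and d(score)/d(activations) per sample.

        The score is the pre-softmax logit of ``target_class`` (eval mode,
        no dropout). Returns (a3, d_a3), both (N, h, w, F).
        """
        if not (0 <= target_class < self.N_CLASSES):
            raise ValidationError(f"invalid class index {target_class}")
        logits, cache = self.forward(x, train=False)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        _, d_a3 = self._backward_from_logits(dlogits, cache, want_params=False)
        return cache["a3"], d_a3

    def clone_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: v.copy() for k, v in params.items()}


def build_model(config: ModelConfig, hp: HyperParams) -> ConvNet:
    """Instantiate the fixed-skeleton CNN with seeded initialization."""
    return ConvNet(config, hp, np.random.default_rng(config.seed))


def save_model(model: ConvNet, path) -> None:
    """Serialize parameters plus config/hyperparameters to a single .npz."""
    meta = {
        "config": {
            "input_side": model.config.input_side,
            "input_channels": model.config.input_channels,
            "conv_filters": list(model.config.conv_filters),
            "dropout_rate": model.config.dropout_rate,
            "batch_size": model.config.batch_size,
            "max_epochs": model.config.max_epochs,
            "seed": model.config.seed,
        },
        "hp": {
            "filter_size": model.hp.filter_size,
            "learning_rate": model.hp.learning_rate,
            "momentum": model.hp.momentum,
            "l2": model.hp.l2,
        },
    }
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **model.params)


def load_model(path) -> ConvNet:
    data = np.load(path)
    meta = json.loads(bytes(data["_meta"]).decode())
    cfg = meta["config"]
    cfg["conv_filters"] = tuple(cfg["conv_filters"])
    model = build_model(ModelConfig(**cfg), HyperParams(**meta["hp"]))
    model.set_params({k: data[k] for k in data.files if k != "_meta"})
    return model
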