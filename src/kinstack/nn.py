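"""Convolutional regression network for kinship images, plus the greedy
stepwise hyperparameter search.

The final architecture is a sequential CNN for single-channel inputs of
shape (n_ref, 15):

    conv(32, 3x3, same, ReLU) -> dropout
    conv(64, 3x3, same, ReLU) -> maxpool(2x2) -> dropout
    flatten -> dense(64, ReLU) -> dropout -> dense(32, ReLU) -> dropout
    -> dense(16, ReLU) -> dropout -> dense(1, linear)

Training uses RMSprop (learning rate 0.001, rho 0.9) on a mean squared
error loss for a fixed number of epochs (default 300; no early stopping).
Dropout is inverted (surviving activations scaled by 1/(1 - rate)) and
inactive at prediction time. Optional L1/L2 penalties are available as a
configuration knob (default off). All randomness — Glorot weight
initialization, minibatch shuffling, dropout masks — derives from one
master seed, giving same-platform reproducibility.

The engine is a compact, fully tested numpy implementation: forward and
backward convolution use an im2col layout, and every layer exposes its
parameter count so architectures can be audited against hand computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import pearson
from .representation import augment

__all__ = ["DNNConfig", "Model", "build_model", "train", "predict", "greedy_stepwise_search"]


@dataclass
class DNNConfig:
    """Hyperparameters of the kinship-image CNN (defaults = final model)."""

    conv_filters: tuple = (32, 64)
    kernel: int = 3
    padding: str = "same"
    dense_nodes: tuple = (64, 32, 16)
    drop_rate: float = 0.25
    l1: float = 0.0
    l2: float = 0.0
    pool: int = 2
    epochs: int = 300
    learning_rate: float = 0.001
    batch_size: int = 32
    augmentation: tuple = (1, 0.1)  # (reps, noise SD)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conv_filters:
            raise ValueError("need at least one convolutional layer")
        if not (0.0 <= self.drop_rate < 1.0):
            raise ValueError("drop_rate must lie in [0, 1)")
        if self.padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")


# ---------------------------------------------------------------------------
# layers

class _Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, training, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Conv2D(_Layer):
    """2D convolution + ReLU, via im2col."""

    def __init__(self, in_ch, filters, kernel, padding, rng):
        super().__init__()
        self.kh = self.kw = kernel
        self.padding = padding
        fan_in = kernel * kernel * in_ch
        self.w = _glorot(rng, (fan_in, filters), fan_in, filters)
        self.b = np.zeros(filters)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.in_ch, self.filters = in_ch, filters
        self.name = f"conv{filters}_{kernel}x{kernel}_{padding}"

    def _pad(self):
        if self.padding == "same":
            return (self.kh - 1) // 2, self.kh - 1 - (self.kh - 1) // 2
        return 0, 0

    def out_shape(self, h, w):
        if self.padding == "same":
            return h, w
        return h - self.kh + 1, w - self.kw + 1

    def forward(self, x, training, rng):
        b, h, w, c = x.shape
        p0, p1 = self._pad()
        xp = np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0))) if p0 or p1 else x
        ho, wo = self.out_shape(h, w)
        if ho < 1 or wo < 1:
            raise ValueError("input smaller than convolution kernel under 'valid' padding")
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        # win: (b, ho, wo, c, kh, kw) -> cols (b*ho*wo, kh*kw*c)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(b * ho * wo, -1)
        z = cols @ self.w + self.b
        self._cache = (cols, z > 0, (b, h, w, c, ho, wo))
        return np.maximum(z, 0.0).reshape(b, ho, wo, self.filters)

    def backward(self, grad):
        cols, relu_mask, (b, h, w, c, ho, wo) = self._cache
        dz = grad.reshape(b * ho * wo, self.filters) * relu_mask
        self.grads[0][...] = cols.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        dcols = (dz @ self.w.T).reshape(b, ho, wo, self.kh, self.kw, c)
        p0, p1 = self._pad()
        dxp = np.zeros((b, h + p0 + p1, w + p0 + p1, c))
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i : i + ho, j : j + wo, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p0 : p0 + h, p0 : p0 + w, :] if (p0 or p1) else dxp


class _MaxPool(_Layer):
    """2x2 max pooling (stride 2, remainder rows/cols dropped)."""

    def __init__(self, size=2):
        super().__init__()
        self.s = size
        self.name = f"maxpool{size}x{size}"

    def forward(self, x, training, rng):
        b, h, w, c = x.shape
        s = self.s
        ho, wo = h // s, w // s
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} smaller than pool window {s}x{s}")
        xc = x[:, : ho * s, : wo * s, :].reshape(b, ho, s, wo, s, c)
        flat = xc.transpose(0, 1, 3, 5, 2, 4).reshape(b, ho, wo, c, s * s)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        (b, h, w, c), idx = self._cache
        s = self.s
        ho, wo = h // s, w // s
        dflat = np.zeros((b, ho, wo, c, s * s))
        np.put_along_axis(dflat, idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros((b, h, w, c))
        dx[:, : ho * s, : wo * s, :] = (
            dflat.reshape(b, ho, wo, c, s, s).transpose(0, 1, 4, 2, 5, 3).reshape(b, ho * s, wo * s, c)
        )
        return dx


class _Dropout(_Layer):
    def __init__(self, rate):
        super().__init__()
        self.rate = rate
        self.name = f"dropout{rate}"

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class _Flatten(_Layer):
    def __init__(self):
        super().__init__()
        self.name = "flatten"

    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in, n_out, activation, rng):
        super().__init__()
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        self.activation = activation
        self.name = f"dense{n_out}_{activation}"

    def forward(self, x, training, rng):
        z = x @ self.w + self.b
        if self.activation == "relu":
            self._cache = (x, z > 0)
            return np.maximum(z, 0.0)
        self._cache = (x, None)
        return z

    def backward(self, grad):
        x, relu_mask = self._cache
        dz = grad * relu_mask if relu_mask is not None else grad
        self.grads[0][...] = x.T @ dz
        self.grads[1][...] = dz.sum(axis=0)
        return dz @ self.w.T


# ---------------------------------------------------------------------------
# model

class Model:
    """Sequential CNN regressor with an RMSprop trainer."""

    def __init__(self, layers, cfg: DNNConfig, input_shape):
        self.layers = layers
        self.cfg = cfg
        self.input_shape = input_shape  # (H, W)
        self._rng = np.random.default_rng(cfg.seed)
        self._cache_sq = [
            [np.zeros_like(p) for p in layer.params] for layer in layers
        ]

    def parameter_counts(self) -> list[tuple[str, int]]:
        """Per-layer (name, trainable parameter count)."""
        return [(layer.name, layer.n_params()) for layer in self.layers]

    def n_params(self) -> int:
        return sum(c for _, c in self.parameter_counts())

    def _forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training, self._rng)
        return x

    def predict(self, slices, batch_size: int = 256) -> np.ndarray:
        """Deterministic forward pass (dropout off); one value per slice."""
        x = np.asarray(slices, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != self.input_shape:
            raise ValueError(
                f"slice shape {x.shape[1:3]} does not match model input {self.input_shape}"
            )
        out = [self._forward(x[i : i + batch_size], training=False) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0).ravel()

    def _step(self, xb, yb):
        pred = self._forward(xb, training=True)
        err = pred.ravel() - yb
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise RuntimeError(
                "NaN/inf training loss; consider lowering the learning rate or "
                "rescaling the input slices"
            )
        grad = (2.0 * err / len(yb))[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        lr, rho, eps = self.cfg.learning_rate, 0.9, 1e-7
        for layer, caches in zip(self.layers, self._cache_sq):
            for p, g, c in zip(layer.params, layer.grads, caches):
                if self.cfg.l2:
                    g = g + 2.0 * self.cfg.l2 * p
                if self.cfg.l1:
                    g = g + self.cfg.l1 * np.sign(p)
                c *= rho
                c += (1.0 - rho) * g * g
                p -= lr * g / (np.sqrt(c) + eps)
        return loss

    def fit(self, slices, phenotypes, validation=None, epochs=None):
        """Train with minibatch RMSprop; returns the per-epoch history.

        ``validation`` is an optional (slices, phenotypes) pair monitored
        each epoch (loss and Pearson correlation).
        """
        x = np.asarray(slices, dtype=float)
        if x.ndim == 3:
            x = x[..., None]
        y = np.asarray(phenotypes, dtype=float)
        if len(x) != len(y):
            raise ValueError("slices and phenotypes are not aligned")
        epochs = self.cfg.epochs if epochs is None else epochs
        bs = self.cfg.batch_size
        history = {"loss": [], "val_loss": [], "val_pearson": []}
        for _ in range(epochs):
            order = self._rng.permutation(len(x))
            losses = []
            for start in range(0, len(x), bs):
                idx = order[start : start + bs]
                losses.append(self._step(x[idx], y[idx]))
            history["loss"].append(float(np.mean(losses)))
            if validation is not None:
                vx, vy = validation
                vp = self.predict(vx)
                history["val_loss"].append(float(np.mean((vp - vy) ** 2)))
                try:
                    history["val_pearson"].append(pearson(vy, vp))
                except ValueError:
                    history["val_pearson"].append(float("nan"))
        return history


def build_model(cfg: DNNConfig, input_height: int, input_width: int = 15) -> Model:
    """Assemble the layer stack for single-channel (H, W) kinship slices.

    Dropout follows every trainable intermediate layer; a single max-pool
    sits after the last convolutional layer.
    """
    if input_height < cfg.pool or input_width < cfg.pool:
        raise ValueError("input smaller than the pooling window")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x1A7]))
    layers: list[_Layer] = []
    h, w, ch = input_height, input_width, 1
    for i, f in enumerate(cfg.conv_filters):
        conv = _Conv2D(ch, f, cfg.kernel, cfg.padding, rng)
        layers.append(conv)
        h, w = conv.out_shape(h, w)
        if h < 1 or w < 1:
            raise ValueError("convolution output collapsed to zero size; use 'same' padding")
        ch = f
        if i == len(cfg.conv_filters) - 1:
            layers.append(_MaxPool(cfg.pool))
            h, w = h // cfg.pool, w // cfg.pool
            if h < 1 or w < 1:
                raise ValueError("pooled output collapsed to zero size")
        layers.append(_Dropout(cfg.drop_rate))
    layers.append(_Flatten())
    n_in = h * w * ch
    for d in cfg.dense_nodes:
        layers.append(_Dense(n_in, d, "relu", rng))
        layers.append(_Dropout(cfg.drop_rate))
        n_in = d
    layers.append(_Dense(n_in, 1, "linear", rng))
    return Model(layers, cfg, (input_height, input_width))


def train(model: Model, slices, phenotypes, validation=None, apply_augmentation: bool = True):
    """Train a built model, applying the configured noise augmentation first."""
    x = np.asarray(slices, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    reps, sigma = model.cfg.augmentation
    if apply_augmentation and reps:
        x, y = augment(x, y, reps=int(reps), sigma=float(sigma),
                       seed=np.random.SeedSequence([model.cfg.seed, 0xA06]))
    return model.fit(x, y, validation=validation)


def predict(model: Model, slices) -> np.ndarray:
    return model.predict(slices)


# ---------------------------------------------------------------------------
# greedy stepwise hyperparameter selection

def _evaluate_config(cfg, slices, phenotypes, n_replicates, seed, train_fraction, epochs):
    """Mean validation Pearson over resampled train/validation splits."""
    x = np.asarray(slices, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    n = len(x)
    scores = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        perm = rng.permutation(n)
        n_val = max(1, int(round((1.0 - train_fraction) * n)))
        val, tr = perm[:n_val], perm[n_val:]
        m = build_model(replace(cfg, seed=int(seed + 7919 * rep)), x.shape[1], x.shape[2])
        train(m, x[tr], y[tr])
        pred = m.predict(x[val])
        try:
            scores.append(pearson(y[val], pred))
        except ValueError:
            scores.append(0.0)
    return float(np.mean(scores))


def greedy_stepwise_search(
    base: DNNConfig,
    option_grid: dict[str, list],
    slices,
    phenotypes,
    n_replicates: int = 10,
    seed: int = 0,
    train_fraction: float = 0.8,
):
    """Optimize one hyperparameter at a time, fixing each winner in turn.

    ``option_grid`` maps DNNConfig field names to candidate lists, in the
    order they should be tuned (kernel, padding, layout, penalties, drop
    rate, augmentation). Each candidate is scored by the mean validation
    Pearson correlation over ``n_replicates`` resampled splits; ties keep
    the earlier-listed candidate. Returns the winning config and a step log
    with the selected value, its score, and the percentage improvement over
    the previous step.
    """
    cfg = base
    log = []
    prev_score = None
    for step, (hp, candidates) in enumerate(option_grid.items(), start=1):
        if not candidates:
            raise ValueError(f"empty candidate list for hyperparameter {hp!r}")
        best_score, best_value = -np.inf, None
        step_scores = []
        for cand in candidates:
            trial = replace(cfg, **(cand if isinstance(cand, dict) else {hp: cand}))
            score = _evaluate_config(
                trial, slices, phenotypes, n_replicates, seed + step, train_fraction, trial.epochs
            )
            step_scores.append(score)
            if score > best_score:  # strict: ties keep the earlier candidate
                best_score, best_value = score, cand
        cfg = replace(cfg, **(best_value if isinstance(best_value, dict) else {hp: best_value}))
        improvement = (
            float("nan") if prev_score in (None, 0.0)
            else 100.0 * (best_score - prev_score) / prev_score
        )
        within = (
            float("nan") if min(step_scores) == 0.0
            else 100.0 * (max(step_scores) - min(step_scores)) / abs(min(step_scores))
        )
        log.append(
            {
                "step": step,
                "hyperparameter": hp,
                "selected": best_value,
                "score": best_score,
                "improvement_pct": improvement,
                "within_step_pct": within,
            }
        )
        prev_score = best_score
    return cfg, log
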