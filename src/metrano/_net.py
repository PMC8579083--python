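"""Minimal CPU encoder-decoder segmentation networks.

A compact U-Net-style architecture (conv -> pool -> conv -> upsample ->
skip-concat -> 1x1 convs) implemented directly on numpy: convolutions run
as im2col matrix products, gradients are hand-derived, and optimization is
Adam with a stepwise learning-rate schedule. Works in 2D and 3D with the
same code. Small by design — sized for desk-scale volumes (64³ cubes,
128² patches) on one CPU — but a faithful encoder-decoder with skip
connections, trained under the Dice loss.

All tensors are channels-first ``(C, *spatial)`` float32. Spatial dims must
be divisible by 2 (one pooling level).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SegNet", "TrainConfig", "soft_dice_loss"]

_EPS = 1e-7


def soft_dice_loss(pred: np.ndarray, truth: np.ndarray, eps: float = _EPS) -> tuple[float, np.ndarray]:
    """Dice loss ``1 - 2*sum(p*t)/(sum(p)+sum(t)+eps)`` and its gradient in p."""
    p = pred.astype(np.float64)
    t = truth.astype(np.float64)
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + eps
    loss = 1.0 - 2.0 * inter / denom
    grad = -(2.0 * t * denom - 2.0 * inter) / denom**2
    return loss, grad.astype(np.float32)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Conv:
    """Same-padding stride-1 convolution, any spatial rank.

    Implemented as a sum of shifted tensor contractions (one small GEMM per
    kernel offset), which beats explicit im2col on CPU for the small channel
    counts used here. ``input_grad=False`` skips the input-gradient pass for
    the first layer.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, ndim: int, rng: np.random.Generator,
                 input_grad: bool = True):
        self.c_in, self.c_out, self.k, self.ndim = c_in, c_out, kernel, ndim
        self.input_grad = input_grad
        fan_in = c_in * kernel**ndim
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in) + (kernel,) * ndim).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None
        self._spatial: tuple | None = None

    def _offsets(self):
        from itertools import product

        return product(*[range(self.k)] * self.ndim)

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        spatial = x.shape[1:]
        pad = self.k // 2
        xp = np.pad(x, ((0, 0),) + ((pad, pad),) * self.ndim) if pad else x
        out = np.empty((self.c_out,) + spatial, dtype=np.float32)
        out[:] = self.b.reshape((self.c_out,) + (1,) * self.ndim)
        spatial_axes = list(range(1, self.ndim + 1))
        for off in self._offsets():
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
            w_off = self.W[(slice(None), slice(None)) + off]  # (C_out, C_in)
            out += np.tensordot(w_off, xp[sl], axes=(1, 0))
        if keep:
            self._xp, self._spatial = xp, spatial
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray | None:
        spatial = self._spatial
        spatial_axes = list(range(1, self.ndim + 1))
        gout = gout.astype(np.float32, copy=False)
        self.gb += gout.sum(axis=tuple(spatial_axes))
        for off in self._offsets():
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
            self.gW[(slice(None), slice(None)) + off] += np.tensordot(
                gout, self._xp[sl], axes=(spatial_axes, spatial_axes)
            )
        gx = None
        if self.input_grad:
            gxp = np.zeros_like(self._xp)
            for off in self._offsets():
                sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial))
                w_off = self.W[(slice(None), slice(None)) + off]
                gxp[sl] += np.tensordot(w_off, gout, axes=(0, 0))
            pad = self.k // 2
            if pad:
                core = (slice(None),) + tuple(slice(pad, pad + s) for s in spatial)
                gx = gxp[core]
            else:
                gx = gxp
        self._xp = None
        return gx

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]

    def zero_grad(self):
        self.gW[...] = 0
        self.gb[...] = 0


def _pool2(x: np.ndarray, ndim: int) -> np.ndarray:
    """2x average pooling along every spatial axis."""
    for ax in range(1, ndim + 1):
        n = x.shape[ax]
        x = x.reshape(x.shape[:ax] + (n // 2, 2) + x.shape[ax + 1 :]).mean(axis=ax + 1)
    return x


def _pool2_back(g: np.ndarray, ndim: int) -> np.ndarray:
    for ax in range(1, ndim + 1):
        g = np.repeat(g, 2, axis=ax)
    return g / (2**ndim)


def _up2(x: np.ndarray, ndim: int) -> np.ndarray:
    for ax in range(1, ndim + 1):
        x = np.repeat(x, 2, axis=ax)
    return x


def _up2_back(g: np.ndarray, ndim: int) -> np.ndarray:
    for ax in range(1, ndim + 1):
        n = g.shape[ax]
        g = g.reshape(g.shape[:ax] + (n // 2, 2) + g.shape[ax + 1 :]).sum(axis=ax + 1)
    return g


@dataclass
class TrainConfig:
    """Optimization settings for the segmenters.

    The reference schedule is 300 epochs at learning rate 1e-3 dropping to
    1e-4 at epoch 100 and 1e-5 at epoch 250 with batch size 1 under Adam;
    the ``tiny`` profile keeps the same shape (two decays at 1/3 and 5/6 of
    the run) compressed into a short CPU-scale run.
    """

    epochs: int = 300
    batch_size: int = 1
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    milestones: dict[int, float] = field(default_factory=lambda: {100: 1e-4, 250: 1e-5})
    val_fraction: float = 0.1
    augment: bool = True
    patches_per_volume: int = 1  # optimization steps drawn per sample per epoch
    grad_clip: float = 1.0  # global-norm clip; Dice gradients spike on tiny foregrounds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0 or any(lr <= 0 for lr in self.milestones.values()):
            raise ValueError("learning rates must be positive")
        if not 0 <= self.val_fraction <= 0.5:
            raise ValueError("val_fraction must be in [0, 0.5]")
        if self.patches_per_volume < 1:
            raise ValueError("patches_per_volume must be >= 1")

    @classmethod
    def tiny(cls, epochs: int = 10, seed: int = 0, learning_rate: float = 3e-3, **overrides) -> "TrainConfig":
        cfg = cls(
            epochs=epochs,
            learning_rate=learning_rate,
            milestones={max(1, (3 * epochs) // 5): learning_rate / 3, max(2, (9 * epochs) // 10): learning_rate / 10},
            **overrides,
        )
        cfg.seed = seed
        return cfg

    def lr_at(self, epoch: int) -> float:
        lr = self.learning_rate
        for m in sorted(self.milestones):
            if epoch >= m:
                lr = self.milestones[m]
        return lr


class _Adam:
    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SegNet:
    """One-level encoder-decoder with skip connection, in 2D or 3D.

    Topology: conv3(1->C) -> pool2 -> conv3(C->2C) -> up2 -> concat skip ->
    conv1(3C->C) -> conv1(C->1 logits). Sigmoid is applied by callers.
    """

    def __init__(self, ndim: int, base_channels: int = 8, kernel: int = 3, in_channels: int = 1, seed: int = 0,
                 out_bias: float = -4.0):
        self.ndim = ndim
        self.base_channels = base_channels
        self.kernel = kernel
        self.in_channels = in_channels
        self.seed = seed
        rng = np.random.default_rng(seed)
        C = base_channels
        self.conv1 = _Conv(in_channels, C, kernel, ndim, rng, input_grad=False)
        self.conv2 = _Conv(C, 2 * C, kernel, ndim, rng)
        self.conv3 = _Conv(3 * C, C, 1, ndim, rng)
        self.conv4 = _Conv(C, 1, 1, ndim, rng)
        # negative output-bias prior: foreground is sparse, so starting near
        # p ~ sigmoid(out_bias) avoids the degenerate flat region of the Dice loss
        self.conv4.b[:] = out_bias
        self._layers = [self.conv1, self.conv2, self.conv3, self.conv4]

    # -- forward / backward ---------------------------------------------------
    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        """Logits for input ``x`` of shape (C_in, *spatial)."""
        if any(s % 2 for s in x.shape[1:]):
            raise ValueError(f"spatial dims must be even, got {x.shape[1:]}")
        a1 = self.conv1.forward(x, keep)
        r1 = np.maximum(a1, 0)
        p = _pool2(r1, self.ndim)
        a2 = self.conv2.forward(p, keep)
        r2 = np.maximum(a2, 0)
        u = _up2(r2, self.ndim)
        cat = np.concatenate([r1, u], axis=0)
        a3 = self.conv3.forward(cat, keep)
        r3 = np.maximum(a3, 0)
        z = self.conv4.forward(r3, keep)
        if keep:
            self._cache = (a1, a2, a3)
        return z

    def backward(self, gz: np.ndarray) -> None:
        a1, a2, a3 = self._cache
        g3 = self.conv4.backward(gz)
        g3 = g3 * (a3 > 0)
        gcat = self.conv3.backward(g3)
        C = self.base_channels
        gr1_skip, gu = gcat[:C], gcat[C:]
        gr2 = _up2_back(gu, self.ndim)
        gr2 = gr2 * (a2 > 0)
        gp = self.conv2.backward(gr2)
        gr1 = _pool2_back(gp, self.ndim) + gr1_skip
        gr1 = gr1 * (a1 > 0)
        self.conv1.backward(gr1)
        self._cache = None

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability map for a single-channel spatial array."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == self.ndim:
            x = x[None]
        return _sigmoid(self.forward(x, keep=False))[0]

    # -- training -------------------------------------------------------------
    def fit(self, samples: list[tuple[np.ndarray, np.ndarray]], cfg: TrainConfig,
            augment_fn=None) -> dict[str, list[float]]:
        """Train under Dice loss; returns per-epoch loss history.

        ``samples`` is a list of (input, binary target) spatial arrays.
        ``augment_fn(x, y, rng) -> (x, y)`` applies data augmentation when
        ``cfg.augment`` is true.
        """
        if not samples:
            raise ValueError("empty training set")
        if all(not np.any(y) for _, y in samples):
            import warnings

            warnings.warn("all training labels are background; training will be degenerate")
        rng = np.random.default_rng(cfg.seed)
        n_val = int(round(cfg.val_fraction * len(samples)))
        order0 = rng.permutation(len(samples))
        val_idx = order0[:n_val]
        train_idx = order0[n_val:]
        if len(train_idx) == 0:
            train_idx, val_idx = order0, order0[:0]
        params = [p for l in self._layers for p in l.params]
        opt = _Adam(params)
        history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        for epoch in range(cfg.epochs):
            lr = cfg.lr_at(epoch)
            epoch_losses = []
            for i in rng.permutation(np.repeat(train_idx, cfg.patches_per_volume)):
                x, y = samples[int(i)]
                if augment_fn is not None:  # callers gate augmentation on cfg.augment
                    x, y = augment_fn(x, y, rng)
                x = np.asarray(x, dtype=np.float32)
                if x.ndim == self.ndim:
                    x = x[None]
                for l in self._layers:
                    l.zero_grad()
                z = self.forward(x)
                p = _sigmoid(z)[0]
                loss, gp_ = soft_dice_loss(p, y)
                gz = (gp_ * p * (1.0 - p)).astype(np.float32)[None]
                self.backward(gz)
                grads = [g for l in self._layers for g in l.grads]
                if cfg.grad_clip:
                    norm = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
                    if norm > cfg.grad_clip:
                        grads = [g * (cfg.grad_clip / norm) for g in grads]
                opt.step(grads, lr)
                epoch_losses.append(loss)
            history["train_loss"].append(float(np.mean(epoch_losses)))
            if len(val_idx):
                vl = []
                for i in val_idx:
                    x, y = samples[int(i)]
                    p = self.predict_proba(x)
                    vl.append(soft_dice_loss(p, y)[0])
                history["val_loss"].append(float(np.mean(vl)))
        return history

    # -- persistence ----------------------------------------------------------
    def state_dict(self) -> dict:
        d = {
            "ndim": self.ndim,
            "base_channels": self.base_channels,
            "kernel": self.kernel,
            "in_channels": self.in_channels,
            "seed": self.seed,
        }
        for i, l in enumerate(self._layers):
            d[f"W{i}"] = l.W
            d[f"b{i}"] = l.b
        return d

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    @classmethod
    def load(cls, path) -> "SegNet":
        with np.load(path) as d:
            net = cls(int(d["ndim"]), int(d["base_channels"]), int(d["kernel"]), int(d["in_channels"]),
                      int(d["seed"]))
            for i, l in enumerate(net._layers):
                l.W[...] = d[f"W{i}"]
                l.b[...] = d[f"b{i}"]
        return net
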