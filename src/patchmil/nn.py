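"""Minimal numpy neural-network stack for the per-patch encoder.

Implements exactly what the patch classifier needs and nothing more: 2-D
convolution (im2col), ReLU, global average pooling, fully connected layers,
reverse-mode gradients, the AdamW optimizer with decoupled weight decay, and
a one-cycle learning-rate schedule.  Everything is float64 and seeded, so
two runs with the same seed produce identical parameter trajectories.

The bundled :class:`TinyCNN` and :class:`PatchMLP` encoders satisfy the
:class:`patchmil.core.EncoderContract`: they map a ``(N, p, p)`` batch of
single-channel patches to ``(N, C)`` logits, share parameters across all
patches, and receive no positional information.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Sequential",
    "TinyCNN",
    "PatchMLP",
    "AdamW",
    "one_cycle_lr",
    "save_encoder",
    "load_encoder",
    "build_encoder",
]


class Layer:
    """Base class: forward caches what backward needs; params/grads are lists."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold (N, C, H, W) into (N, out_h, out_w, C*k*k) patches."""
    N, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out_h = (H + 2 * pad - k) // stride + 1
    out_w = (W + 2 * pad - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(N, C, out_h, out_w, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
    )
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(N, out_h, out_w, C * k * k)
    return np.ascontiguousarray(cols), out_h, out_w


class Conv2d(Layer):
    """k x k convolution with stride and zero padding, He-initialized."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        k: int = 3,
        stride: int = 1,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, k, k))
        self.b = np.zeros(out_ch)
        self.k, self.stride, self.pad = k, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, out_h, out_w = _im2col(x, self.k, self.stride, self.pad)
        Wm = self.W.reshape(self.out_ch, -1)
        out = cols @ Wm.T + self.b  # (N, oh, ow, out_ch)
        self._cache = (x.shape, cols)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        N, _, H, W = x_shape
        g = grad_out.transpose(0, 2, 3, 1)  # (N, oh, ow, out_ch)
        gflat = g.reshape(-1, self.out_ch)
        cflat = cols.reshape(-1, cols.shape[-1])
        self.dW[...] = (gflat.T @ cflat).reshape(self.W.shape)
        self.db[...] = gflat.sum(axis=0)
        # grad wrt input: scatter the column gradients back (col2im)
        gcols = gflat @ self.W.reshape(self.out_ch, -1)  # (N*oh*ow, C*k*k)
        oh, ow = g.shape[1], g.shape[2]
        gcols = gcols.reshape(N, oh, ow, self.in_ch, self.k, self.k)
        Hp, Wp = H + 2 * self.pad, W + 2 * self.pad
        gx = np.zeros((N, self.in_ch, Hp, Wp))
        for i in range(self.k):
            for j in range(self.k):
                gx[:, :, i : i + oh * self.stride : self.stride,
                   j : j + ow * self.stride : self.stride] += gcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if self.pad:
            gx = gx[:, :, self.pad : Hp - self.pad, self.pad : Wp - self.pad]
        return gx

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(
            grad_out[:, :, None, None] / (H * W), self._shape
        ).copy()


class GlobalAvgMaxPool(Layer):
    """(N, C, H, W) -> (N, 2C): spatial mean and spatial max per channel.

    The max half matters for detecting small high-contrast structure (a
    lesion edge crossing a patch) that plain averaging would dilute.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        flat = x.reshape(N, C, H * W)
        self._shape = x.shape
        self._argmax = flat.argmax(axis=2)
        return np.concatenate([flat.mean(axis=2), flat.max(axis=2)], axis=1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        g_avg, g_max = grad_out[:, :C], grad_out[:, C:]
        gx = np.broadcast_to(g_avg[:, :, None] / (H * W), (N, C, H * W)).copy()
        n_idx, c_idx = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
        gx[n_idx, c_idx, self._argmax] += g_max
        return gx.reshape(self._shape)


class Center(Layer):
    """Fixed affine input normalization: [0, 1] intensities -> [-1, 1]."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return 2.0 * x - 1.0

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return 2.0 * grad_out


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad_out
        self.db[...] = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]


class _EncoderBase:
    """Shared plumbing: EncoderContract __call__ plus train-time forward/backward."""

    net: Sequential
    n_labels: int
    patch_side: int
    arch: str
    hyper: dict

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(patches, dtype=np.float64))

    def forward(self, patches: np.ndarray) -> np.ndarray:
        return self.net.forward(patches[:, None, :, :])

    def backward(self, grad_logits: np.ndarray) -> None:
        self.net.backward(grad_logits)

    @property
    def params(self) -> list[np.ndarray]:
        return self.net.params

    @property
    def grads(self) -> list[np.ndarray]:
        return self.net.grads


class TinyCNN(_EncoderBase):
    """Two stride-2 conv blocks + global avg/max pooling + linear C-logit head.

    Sized for small patches (p of 8-64); a few thousand parameters at the
    defaults.  The single-channel first layer and C-logit head are native
    here; inputs are centered from [0, 1] to [-1, 1] inside the network.
    ``head_hidden`` > 0 inserts a small ReLU layer before the logit head.
    """

    arch = "tiny_cnn"

    def __init__(
        self,
        patch_side: int,
        n_labels: int,
        channels: tuple[int, int] = (12, 24),
        head_hidden: int = 0,
        first_stride: int = 2,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        head: list[Layer] = [GlobalAvgMaxPool()]
        if head_hidden:
            head += [Linear(2 * c2, head_hidden, rng=rng), ReLU(),
                     Linear(head_hidden, n_labels, rng=rng)]
        else:
            head += [Linear(2 * c2, n_labels, rng=rng)]
        self.net = Sequential(
            Center(),
            Conv2d(1, c1, k=3, stride=first_stride, pad=1, rng=rng),
            ReLU(),
            Conv2d(c1, c2, k=3, stride=2, pad=1, rng=rng),
            ReLU(),
            *head,
        )
        self.n_labels = n_labels
        self.patch_side = patch_side
        self.hyper = {
            "channels": list(channels),
            "head_hidden": head_hidden,
            "first_stride": first_stride,
            "seed": seed,
        }


class PatchMLP(_EncoderBase):
    """Flatten + two fully connected layers; the simplest trainable encoder."""

    arch = "patch_mlp"

    def __init__(self, patch_side: int, n_labels: int, hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.net = Sequential(
            Flatten(),
            Linear(patch_side * patch_side, hidden, rng=rng),
            ReLU(),
            Linear(hidden, n_labels, rng=rng),
        )
        self.n_labels = n_labels
        self.patch_side = patch_side
        self.hyper = {"hidden": hidden, "seed": seed}


_ARCHS = {"tiny_cnn": TinyCNN, "patch_mlp": PatchMLP}


def build_encoder(arch: str, patch_side: int, n_labels: int, **hyper):
    """Construct a bundled encoder by architecture name."""
    if arch not in _ARCHS:
        raise ValueError(f"unknown encoder arch {arch!r}; choose from {sorted(_ARCHS)}")
    return _ARCHS[arch](patch_side=patch_side, n_labels=n_labels, **hyper)


class AdamW:
    """Adam with decoupled weight decay (decay applied directly to weights)."""

    def __init__(
        self,
        params: list[np.ndarray],
        grads: list[np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-2,
    ):
        self.params, self.grad_refs = params, grads
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def one_cycle_lr(
    step: int,
    total_steps: int,
    peak_lr: float,
    warmup_frac: float = 0.05,
    start_div: float = 25.0,
    final_div: float = 1e4,
) -> float:
    """One-cycle schedule: linear rise to ``peak_lr`` over the first
    ``warmup_frac`` of training, then cosine anneal to ``peak_lr/final_div``.

    ``step`` is 0-based; the peak is reached exactly at
    ``step = round(warmup_frac * total_steps)``.
    """
    if total_steps < 1:
        raise ValueError("total_steps must be >= 1")
    warm = max(1, round(warmup_frac * total_steps))
    if step <= warm:
        lo = peak_lr / start_div
        return lo + (peak_lr - lo) * step / warm
    frac = (step - warm) / max(1, total_steps - warm)
    frac = min(1.0, frac)
    lo = peak_lr / final_div
    return lo + 0.5 * (peak_lr - lo) * (1.0 + np.cos(np.pi * frac))


def save_encoder(enc, path: str | Path) -> None:
    """Write parameters (.npz) plus a JSON architecture sidecar."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **{f"p{i:03d}": p for i, p in enumerate(enc.params)})
    meta = {
        "arch": enc.arch,
        "patch_side": enc.patch_side,
        "n_labels": enc.n_labels,
        "hyper": enc.hyper,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_encoder(path: str | Path):
    """Rebuild an encoder saved by :func:`save_encoder`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    enc = build_encoder(
        meta["arch"], meta["patch_side"], meta["n_labels"], **meta["hyper"]
    )
    with np.load(path) as data:
        keys = sorted(data.files)
        if len(keys) != len(enc.params):
            raise ValueError(
                f"checkpoint has {len(keys)} arrays, encoder expects {len(enc.params)}"
            )
        for p, key in zip(enc.params, keys):
            p[...] = data[key]
    return enc
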