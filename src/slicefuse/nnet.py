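"""A small reference CNN for binary image classification, in pure NumPy.

This is the desk-scale classifier behind the pluggable-classifier contract:
three convolution blocks (two batch-normalized 3x3 convolutions with
leaky-ReLU, then a 2x2 max-pool each), global average pooling, and a single
logit trained with binary cross-entropy under Adam. The double conv widens
the last block's receptive field enough to see a whole lesion triplet at
32 px input; batch normalization and the leaky activation make from-scratch
optimization fast and robust to the weight-initialization seed, to which
small single-logit nets are otherwise prone. Heavyweight
pretrained backbones (EfficientNetB0/B2/B4 at 224/260/380 input) satisfy the
same contract when a deep-learning framework is available; nothing else in
the package depends on which classifier is plugged in.

The contract:

* ``fit_step(images, labels, lr) -> loss`` — one gradient step;
* ``predict_scores(images) -> scores in [0, 1]`` for the positive class;
* ``cam_inputs(image) -> (activations, gradients)`` — last conv stage probe
  for Grad-CAM;
* deterministic given fixed weights and inputs; weight init and every
  stochastic choice derive from an explicit seed.

Images are H x W x 3 uint8; internally they are scaled to [0, 1] floats
(no ImageNet-style per-channel normalization, which only applies to
pretrained backbones).
"""

from __future__ import annotations

import copy
from typing import Protocol

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TrainableClassifier", "ReferenceCNN"]


class TrainableClassifier(Protocol):
    """Duck-typed contract any plugged-in classifier must satisfy."""

    def fit_step(self, images: np.ndarray, labels: np.ndarray, lr: float) -> float: ...

    def predict_scores(self, images: np.ndarray) -> np.ndarray: ...

    def cam_inputs(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]: ...

    def get_weights(self) -> dict: ...

    def set_weights(self, weights: dict) -> None: ...


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of the zero-padded 3x3 windows."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)


class _Conv3x3:
    """Same-padded 3x3 convolution with He-initialized weights."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * 9)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x)
        self._cols, self._shape = cols, x.shape
        out = cols @ self.w.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n, c, h, w = self._shape
        dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        dw = dy_mat.T @ self._cols
        db = dy_mat.sum(axis=0)
        # dX is a full correlation of dY with the 180-degree-rotated kernels
        c_out = self.w.shape[0]
        w_rot = self.w.reshape(c_out, c, 9)[:, :, ::-1].transpose(1, 0, 2).reshape(c, c_out * 9)
        dy_cols = _im2col(dy.astype(np.float32))
        dx = (dy_cols @ w_rot.T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        return dx, dw, db


class _BatchNorm:
    """Per-channel batch normalization over batch and spatial dimensions."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._invstd: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._xhat, self._invstd = xhat.astype(np.float32), invstd.astype(np.float32)
        return (self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]).astype(
            np.float32
        )

    def backward(self, dy: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xhat, invstd = self._xhat, self._invstd
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        g = self.gamma * invstd / n
        dx = g[None, :, None, None] * (
            n * dy
            - dbeta[None, :, None, None]
            - xhat * dgamma[None, :, None, None]
        )
        return dx.astype(np.float32), dgamma.astype(np.float32), dbeta.astype(np.float32)


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _maxpool2_backward(dy: np.ndarray, idx: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    n, c, h, w = shape
    dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dwin, idx[..., None], dy[..., None], axis=-1)
    return dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


_LEAK = 0.1  # leaky-ReLU negative slope


class ReferenceCNN:
    """3 double-conv blocks -> global average pooling -> 1 logit, Adam-trained.

    Parameters
    ----------
    resolution : input side length (images are resolution x resolution x 3).
    channels : feature maps per conv block (both convs of a block share it).
    seed : weight-initialization seed; fixing it makes training runs
        bit-reproducible in single-threaded CPU mode.
    """

    def __init__(
        self,
        resolution: int = 32,
        channels: tuple[int, int, int] = (8, 16, 32),
        seed: int = 0,
    ):
        if resolution % 8 != 0:
            raise ValueError("resolution must be divisible by 8 (three 2x2 pools)")
        self.resolution = resolution
        self.channels = channels
        rng = np.random.default_rng(seed)
        widths = [3, channels[0], channels[0], channels[1], channels[1], channels[2], channels[2]]
        self.conv = [_Conv3x3(widths[i], widths[i + 1], rng) for i in range(6)]
        self.bn = [_BatchNorm(widths[i + 1]) for i in range(6)]
        self.fc_w = rng.normal(0.0, np.sqrt(1.0 / channels[2]), size=(channels[2],)).astype(
            np.float32
        )
        self.fc_b = np.float32(0.0)
        self._adam_m: dict | None = None
        self._adam_v: dict | None = None
        self._adam_t = 0

    # ---------------- forward / backward ----------------

    @staticmethod
    def _prepare(images: np.ndarray) -> np.ndarray:
        """HWC uint8 batch (or single image) -> NCHW float32 in [0, 1]."""
        arr = np.asarray(images)
        if arr.ndim == 3:
            arr = arr[None]
        return (arr.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)

    def _forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, dict]:
        cache: dict = {"pool": [], "relu": [], "acts": None}
        for i, conv in enumerate(self.conv):
            z = self.bn[i].forward(conv.forward(x), train)
            a = np.where(z > 0, z, _LEAK * z).astype(np.float32)
            cache["relu"].append(z > 0)
            if i == len(self.conv) - 1:
                cache["acts"] = a  # last conv stage, post-activation (Grad-CAM probe)
            x = a
            if i % 2 == 1:  # pool closes each double-conv block
                x, idx = _maxpool2(a)
                cache["pool"].append((idx, a.shape))
        cache["gap_in_shape"] = x.shape
        pooled = x.mean(axis=(2, 3))
        cache["pooled"] = pooled
        logit = pooled @ self.fc_w + self.fc_b
        return logit, cache

    def _backward(self, dlogit: np.ndarray, cache: dict) -> dict:
        grads: dict = {}
        grads["fc_w"] = cache["pooled"].T @ dlogit
        grads["fc_b"] = dlogit.sum()
        n, c, h, w = cache["gap_in_shape"]
        dx = (dlogit[:, None] * self.fc_w[None, :])[:, :, None, None] * np.ones(
            (n, c, h, w), dtype=np.float32
        ) / (h * w)
        for i in reversed(range(len(self.conv))):
            if i % 2 == 1:
                idx, a_shape = cache["pool"][i // 2]
                dx = _maxpool2_backward(dx, idx, a_shape)
            dx = np.where(cache["relu"][i], dx, _LEAK * dx).astype(np.float32)
            dx, dgamma, dbeta = self.bn[i].backward(dx)
            grads[f"bn{i}_g"], grads[f"bn{i}_b"] = dgamma, dbeta
            dx, dw, db = self.conv[i].backward(dx)
            grads[f"conv{i}_w"], grads[f"conv{i}_b"] = dw, db
        return grads

    def _params(self) -> dict:
        p = {"fc_w": self.fc_w, "fc_b": self.fc_b}
        for i, conv in enumerate(self.conv):
            p[f"conv{i}_w"], p[f"conv{i}_b"] = conv.w, conv.b
            p[f"bn{i}_g"], p[f"bn{i}_b"] = self.bn[i].gamma, self.bn[i].beta
        return p

    def _assign(self, params: dict) -> None:
        self.fc_w = params["fc_w"]
        self.fc_b = params["fc_b"]
        for i, conv in enumerate(self.conv):
            conv.w, conv.b = params[f"conv{i}_w"], params[f"conv{i}_b"]
            self.bn[i].gamma, self.bn[i].beta = params[f"bn{i}_g"], params[f"bn{i}_b"]

    # ---------------- contract methods ----------------

    def fit_step(self, images: np.ndarray, labels: np.ndarray, lr: float) -> float:
        """One Adam step on binary cross-entropy; returns the batch loss."""
        x = self._prepare(images)
        y = np.asarray(labels, dtype=np.float32)
        logit, cache = self._forward(x, train=True)
        # stable BCE-with-logits: softplus(z) - y*z
        loss = float(np.mean(np.logaddexp(0.0, logit) - y * logit))
        prob = 1.0 / (1.0 + np.exp(-logit))
        dlogit = ((prob - y) / len(y)).astype(np.float32)
        grads = self._backward(dlogit, cache)
        self._adam_update(grads, lr)
        return loss

    def _adam_update(self, grads: dict, lr: float, b1: float = 0.9, b2: float = 0.999) -> None:
        params = self._params()
        if self._adam_m is None:
            self._adam_m = {k: np.zeros_like(np.asarray(v, dtype=np.float32)) for k, v in params.items()}
            self._adam_v = {k: np.zeros_like(np.asarray(v, dtype=np.float32)) for k, v in params.items()}
        self._adam_t += 1
        t = self._adam_t
        new = {}
        for k, v in params.items():
            g = np.asarray(grads[k], dtype=np.float32)
            self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            m_hat = self._adam_m[k] / (1 - b1**t)
            v_hat = self._adam_v[k] / (1 - b2**t)
            new[k] = (np.asarray(v, dtype=np.float32) - lr * m_hat / (np.sqrt(v_hat) + 1e-8)).astype(
                np.float32
            )
        self._assign(new)

    def predict_scores(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Positive-class probabilities in [0, 1]."""
        x = self._prepare(images)
        out = []
        for start in range(0, len(x), batch_size):
            logit, _ = self._forward(x[start : start + batch_size])
            out.append(1.0 / (1.0 + np.exp(-logit)))
        return np.concatenate(out)

    def loss_on(self, images: np.ndarray, labels: np.ndarray, batch_size: int = 256) -> float:
        """Mean binary cross-entropy without updating weights."""
        x = self._prepare(images)
        y = np.asarray(labels, dtype=np.float32)
        total = 0.0
        for start in range(0, len(x), batch_size):
            logit, _ = self._forward(x[start : start + batch_size])
            yb = y[start : start + batch_size]
            total += float(np.sum(np.logaddexp(0.0, logit) - yb * logit))
        return total / len(y)

    def cam_inputs(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Last-conv-stage activations and d(logit)/d(activations) for one image.

        Returns two (K, h, w) arrays: the post-ReLU feature maps A^k and the
        gradient of the positive-class logit with respect to each.
        """
        x = self._prepare(image)
        if len(x) != 1:
            raise ValueError("cam_inputs takes a single image")
        logit, cache = self._forward(x)
        acts = cache["acts"][0]
        # backprop d(logit) only down to the last conv activations
        n, c, h, w = cache["gap_in_shape"]
        dx = np.broadcast_to(
            self.fc_w[None, :, None, None] / (h * w), (1, c, h, w)
        ).astype(np.float32)
        idx, a_shape = cache["pool"][-1]
        dacts = _maxpool2_backward(dx, idx, a_shape)
        return acts.copy(), dacts[0].copy()

    def save(self, path) -> None:
        """Persist weights and BN statistics as a versioned .npz checkpoint."""
        arrays = {k: np.asarray(v) for k, v in self._params().items()}
        for i, bn in enumerate(self.bn):
            arrays[f"bn{i}_mean"], arrays[f"bn{i}_var"] = bn.running_mean, bn.running_var
        arrays["_meta"] = np.array(
            [1, self.resolution, *self.channels], dtype=np.int64
        )  # [format version, resolution, widths...]
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ReferenceCNN":
        with np.load(path) as data:
            meta = data["_meta"]
            if meta[0] != 1:
                raise ValueError(f"unsupported checkpoint version {meta[0]}")
            net = cls(resolution=int(meta[1]), channels=tuple(int(c) for c in meta[2:5]))
            net._assign({k: data[k].astype(np.float32) for k in net._params()})
            net.fc_b = np.float32(data["fc_b"])
            for i, bn in enumerate(net.bn):
                bn.running_mean = data[f"bn{i}_mean"].astype(np.float32)
                bn.running_var = data[f"bn{i}_var"].astype(np.float32)
        return net

    def get_weights(self) -> dict:
        state = {k: np.copy(v) for k, v in self._params().items()}
        state["_bn_stats"] = [
            (np.copy(bn.running_mean), np.copy(bn.running_var)) for bn in self.bn
        ]
        state["_adam"] = (
            copy.deepcopy(self._adam_m),
            copy.deepcopy(self._adam_v),
            self._adam_t,
        )
        return state

    def set_weights(self, weights: dict) -> None:
        self._assign(
            {k: np.copy(v) for k, v in weights.items() if k not in ("_adam", "_bn_stats")}
        )
        if "_bn_stats" in weights:
            for bn, (mean, var) in zip(self.bn, weights["_bn_stats"]):
                bn.running_mean, bn.running_var = np.copy(mean), np.copy(var)
        if "_adam" in weights:
            m, v, t = weights["_adam"]
            self._adam_m = copy.deepcopy(m)
            self._adam_v = copy.deepcopy(v)
            self._adam_t = t
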