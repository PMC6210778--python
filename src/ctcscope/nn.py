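"""Minimal convolutional network machinery in numpy.

Implements exactly what the thumbnail segmenter needs: 3x3 same-padding
convolutions, ReLU, 2x2 max pooling, nearest-neighbour upsampling with a skip
concatenation, a sigmoid/binary-cross-entropy head, and Adam — all with
hand-written backward passes.  The network is a two-level U-net: at 80x80
thumbnails and a handful of filters, a full deep-learning framework would be
overkill and the whole forward/backward fits in a few batched matrix
products (float32, so BLAS does the heavy lifting).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np


def _conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padding 3x3 convolution.  x: (B,C,H,W), W: (O,C,3,3), b: (O,).

    Implemented as nine batched GEMMs (one per kernel tap) so the heavy
    lifting stays in BLAS.
    """
    B, C, H, Wd = x.shape
    O = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    y = np.zeros((B, O, H * Wd), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di : di + H, dj : dj + Wd].reshape(B, C, H * Wd)
            y += np.matmul(W[:, :, di, dj], patch)
    y = y.reshape(B, O, H, Wd) + b[None, :, None, None]
    return y, xp


def _conv3x3_backward(gy: np.ndarray, xp: np.ndarray, W: np.ndarray):
    B, O, H, Wd = gy.shape
    C = W.shape[1]
    gy2 = np.ascontiguousarray(gy.reshape(B, O, H * Wd))
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di : di + H, dj : dj + Wd].reshape(B, C, H * Wd)
            dW[:, :, di, dj] = np.matmul(gy2, patch.transpose(0, 2, 1)).sum(axis=0)
            dpatch = np.matmul(W[:, :, di, dj].T, gy2).reshape(B, C, H, Wd)
            dxp[:, :, di : di + H, dj : dj + Wd] += dpatch
    db = gy.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _conv1x1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    B, C, H, Wd = x.shape
    y = np.matmul(W, x.reshape(B, C, H * Wd)).reshape(B, W.shape[0], H, Wd)
    return y + b[None, :, None, None]


def _conv1x1_backward(gy: np.ndarray, x: np.ndarray, W: np.ndarray):
    B, O, H, Wd = gy.shape
    C = x.shape[1]
    gy2 = gy.reshape(B, O, H * Wd)
    x2 = x.reshape(B, C, H * Wd)
    dW = np.matmul(gy2, x2.transpose(0, 2, 1)).sum(axis=0)
    db = gy.sum(axis=(0, 2, 3))
    dx = np.matmul(W.T, gy2).reshape(B, C, H, Wd)
    return dx, dW, db


def _maxpool2_forward(x: np.ndarray):
    B, C, H, Wd = x.shape
    xr = x.reshape(B, C, H // 2, 2, Wd // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(B, C, H // 2, Wd // 2, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, idx


def _maxpool2_backward(gy: np.ndarray, idx: np.ndarray, in_shape):
    B, C, H, Wd = in_shape
    flat = np.zeros((B, C, H // 2, Wd // 2, 4), dtype=gy.dtype)
    np.put_along_axis(flat, idx[..., None], gy[..., None], axis=-1)
    return (
        flat.reshape(B, C, H // 2, Wd // 2, 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(B, C, H, Wd)
    )


def _upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample2_backward(gy: np.ndarray) -> np.ndarray:
    B, C, H, Wd = gy.shape
    return gy.reshape(B, C, H // 2, 2, Wd // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross entropy and its gradient w.r.t. the logits."""
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad


class TinyUNet:
    """Two-level U-net with a skip connection: 1 -> F -> F | pool | -> 2F
    -> upsample + concat -> F -> 1 logit per pixel."""

    def __init__(self, base_filters: int = 8, seed: int = 0):
        self.base_filters = int(base_filters)
        rng = np.random.default_rng(seed)
        F = self.base_filters

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)

        self.params: Dict[str, np.ndarray] = {
            "W1": he((F, 1, 3, 3), 9), "b1": np.zeros(F, dtype=np.float32),
            "W2": he((F, F, 3, 3), 9 * F), "b2": np.zeros(F, dtype=np.float32),
            "W3": he((2 * F, F, 3, 3), 9 * F), "b3": np.zeros(2 * F, dtype=np.float32),
            "W4": he((F, 3 * F, 3, 3), 9 * 3 * F), "b4": np.zeros(F, dtype=np.float32),
            "W5": he((1, F), F), "b5": np.zeros(1, dtype=np.float32),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        p = self.params
        z1, xp1 = _conv3x3_forward(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0)
        z2, xp2 = _conv3x3_forward(a1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0)  # skip tensor
        pooled, pool_idx = _maxpool2_forward(a2)
        z3, xp3 = _conv3x3_forward(pooled, p["W3"], p["b3"])
        a3 = np.maximum(z3, 0)
        up = _upsample2(a3)
        cat = np.concatenate([up, a2], axis=1)
        z4, xp4 = _conv3x3_forward(cat, p["W4"], p["b4"])
        a4 = np.maximum(z4, 0)
        logits = _conv1x1_forward(a4, p["W5"], p["b5"])
        if keep_cache:
            self._cache = dict(
                xp1=xp1, z1=z1, xp2=xp2, z2=z2, a2_shape=a2.shape,
                pool_idx=pool_idx, xp3=xp3, z3=z3, xp4=xp4, z4=z4, a4=a4,
            )
        return logits

    def backward(self, dlogits: np.ndarray) -> Dict[str, np.ndarray]:
        p, c = self.params, self._cache
        F = self.base_filters
        grads: Dict[str, np.ndarray] = {}
        da4, grads["W5"], grads["b5"] = _conv1x1_backward(dlogits, c["a4"], p["W5"])
        dz4 = da4 * (c["z4"] > 0)
        dcat, grads["W4"], grads["b4"] = _conv3x3_backward(dz4, c["xp4"], p["W4"])
        dup, da2_skip = dcat[:, : 2 * F], dcat[:, 2 * F :]
        da3 = _upsample2_backward(dup)
        dz3 = da3 * (c["z3"] > 0)
        dpool, grads["W3"], grads["b3"] = _conv3x3_backward(dz3, c["xp3"], p["W3"])
        da2 = _maxpool2_backward(dpool, c["pool_idx"], c["a2_shape"]) + da2_skip
        dz2 = da2 * (c["z2"] > 0)
        da1, grads["W2"], grads["b2"] = _conv3x3_backward(dz2, c["xp2"], p["W2"])
        dz1 = da1 * (c["z1"] > 0)
        _, grads["W1"], grads["b1"] = _conv3x3_backward(dz1, c["xp1"], p["W1"])
        return grads

    def adam_step(self, grads: Dict[str, np.ndarray], lr: float = 1e-3,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = self._adam_m[k] / (1 - beta1**t)
            v_hat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(np.asarray(x, dtype=np.float32), keep_cache=False))

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32).copy()


def train(
    net: TinyUNet,
    x: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int = 10,
    batch_size: int = 16,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> List[float]:
    """Mini-batch Adam training; returns the mean loss of each epoch.

    Raises ``RuntimeError`` on a non-finite loss (divergence).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    n = x.shape[0]
    losses: List[float] = []
    for _epoch in range(epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            logits = net.forward(x[sel], keep_cache=True)
            loss, dlogits = bce_with_logits(logits, y[sel])
            if not np.isfinite(loss):
                raise RuntimeError("training diverged: non-finite loss")
            grads = net.backward(dlogits)
            net.adam_step(grads, lr=learning_rate)
            epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))
    return losses
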