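"""Minimal CPU convolutional-network engine.

A small, deterministic numpy implementation of everything the transfer
model needs: 3x3 strided convolutions (im2col), ReLU, global average
pooling, a linear head, softmax cross-entropy and Adam.  Arrays are
(N, C, H, W) float64 throughout; all randomness comes from an explicit
``numpy.random.Generator``, so identical seeds give bit-identical runs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ShapeError

__all__ = ["StageConvNet", "Adam", "softmax_cross_entropy", "sigmoid"]


def sigmoid(z):
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), y] + 1e-300).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def _conv_forward(x, W, b, stride):
    """x (N,C,H,W), W (Cout,Cin,3,3) -> y (N,Cout,Ho,Wo) with pad 1."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    ho = (h + 2 - 3) // stride + 1
    wo = (w + 2 - 3) // stride + 1
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))[:, :, ::stride, ::stride]
    win = win[:, :, :ho, :wo]  # (N,C,Ho,Wo,3,3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * 9)
    wmat = W.reshape(W.shape[0], c * 9)
    y = cols @ wmat.T + b
    y = y.reshape(n, ho, wo, W.shape[0]).transpose(0, 3, 1, 2)
    cache = (x.shape, cols, wmat, stride, ho, wo)
    return y, cache


def _conv_backward(dy, cache):
    (n, c, h, w), cols, wmat, stride, ho, wo = cache
    dy_mat = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, -1)
    dW = (dy_mat.T @ cols).reshape(-1, c, 3, 3)
    db = dy_mat.sum(axis=0)
    dcols = dy_mat @ wmat  # (N*Ho*Wo, C*9)
    dcols = dcols.reshape(n, ho, wo, c, 3, 3).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, h + 2, w + 2))
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += dcols[
                :, :, :, :, ki, kj
            ]
    return dW, db, dxp[:, :, 1 : h + 1, 1 : w + 1]


class StageConvNet:
    """A backbone of strided 3x3 conv + ReLU stages with a linear head.

    Stage ``i`` halves the spatial resolution (stride 2) except the last,
    which keeps it (stride 1).  The classification head is a linear map on
    the globally average-pooled last stage.  The pooled concatenation of
    all stage activations is the network's feature vector, of width
    ``sum(stage_channels)``.
    """

    def __init__(self, stage_channels, n_classes, rng: np.random.Generator,
                 in_channels: int = 3):
        self.stage_channels = list(stage_channels)
        self.n_classes = int(n_classes)
        self.in_channels = in_channels
        self.params: dict[str, np.ndarray] = {}
        c_prev = in_channels
        for i, c in enumerate(self.stage_channels):
            fan_in = c_prev * 9
            self.params[f"conv{i}_W"] = rng.standard_normal((c, c_prev, 3, 3)) * np.sqrt(
                2.0 / fan_in
            )
            self.params[f"conv{i}_b"] = np.zeros(c)
            c_prev = c
        self.params["head_W"] = rng.standard_normal((c_prev, self.n_classes)) * np.sqrt(
            1.0 / c_prev
        )
        self.params["head_b"] = np.zeros(self.n_classes)
        self._cache = None

    @property
    def feature_width(self) -> int:
        return int(sum(self.stage_channels))

    def strides(self):
        return [2] * (len(self.stage_channels) - 1) + [1]

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, keep_cache: bool = True):
        """Return (logits, stage_activations) for x of shape (N, C, H, W)."""
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ShapeError(f"expected (N,{self.in_channels},H,W), got {x.shape}")
        stages, caches, relus = [], [], []
        out = x
        for i, stride in enumerate(self.strides()):
            out, cache = _conv_forward(
                out, self.params[f"conv{i}_W"], self.params[f"conv{i}_b"], stride
            )
            mask = out > 0
            out = out * mask
            stages.append(out)
            caches.append(cache)
            relus.append(mask)
        pooled = out.mean(axis=(2, 3))
        logits = pooled @ self.params["head_W"] + self.params["head_b"]
        if keep_cache:
            self._cache = (caches, relus, stages, pooled, out.shape)
        return logits, stages

    def backward(self, dlogits: np.ndarray, stage_grads=None):
        """Gradients of params given dLoss/dlogits.

        ``stage_grads``, when given, is a list of extra gradients (or None)
        to inject at each post-ReLU stage activation — used by the
        feature-matching transfer constraint.
        """
        caches, relus, stages, pooled, last_shape = self._cache
        grads = {
            "head_W": pooled.T @ dlogits,
            "head_b": dlogits.sum(axis=0),
        }
        n, c, h, w = last_shape
        dstage = (dlogits @ self.params["head_W"].T)[:, :, None, None] * np.ones(
            (1, 1, h, w)
        ) / (h * w)
        for i in reversed(range(len(self.stage_channels))):
            if stage_grads is not None and stage_grads[i] is not None:
                dstage = dstage + stage_grads[i]
            dstage = dstage * relus[i]
            dW, db, dstage = _conv_backward(dstage, caches[i])
            grads[f"conv{i}_W"] = dW
            grads[f"conv{i}_b"] = db
        return grads

    # ------------------------------------------------------------------
    def pooled_stage_features(self, x: np.ndarray) -> list[np.ndarray]:
        """Per-stage globally average-pooled activations, list of (N, C_i)."""
        _, stages = self.forward(x, keep_cache=False)
        return [s.mean(axis=(2, 3)) for s in stages]

    def features(self, x: np.ndarray) -> np.ndarray:
        """Concatenated pooled stage features, shape (N, sum(stage_channels))."""
        return np.concatenate(self.pooled_stage_features(x), axis=1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(x, keep_cache=False)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


class Adam:
    """Adam over a dict of named parameter arrays."""

    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
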