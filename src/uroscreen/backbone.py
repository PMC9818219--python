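"""Pluggable tile-classifier contract and a small pure-numpy CNN backbone.

Any backbone that maps a batch of RGB tiles to per-tile neoplastic
probabilities and exposes its parameter inventory partitioned into
``norm_affine`` / ``head`` / ``other`` groups satisfies the contract; the
partial fine-tuning mask is defined over those groups.  The bundled
:class:`TinyCNN` exists so the whole pipeline trains on one CPU without a
deep-learning framework: two strided convolutions with batch-normalisation,
global average pooling and a single-logit sigmoid head, trained with Adam
on binary cross-entropy.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from typing import Iterator

import numpy as np

from .errors import ContractError

__all__ = ["TileClassifier", "TinyCNN", "Adam", "sigmoid", "bce_loss"]

NORM_AFFINE = "norm_affine"
HEAD = "head"
OTHER = "other"

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class TileClassifier(ABC):
    """Contract every backbone must satisfy."""

    input_size: int  # expected square tile side in pixels

    @abstractmethod
    def predict_proba(self, tiles: np.ndarray) -> np.ndarray:
        """Per-tile neoplastic probability in [0, 1] for uint8 (B,H,W,3) tiles."""

    @abstractmethod
    def parameter_groups(self) -> dict[str, str]:
        """Map parameter name -> group in {norm_affine, head, other}."""

    @abstractmethod
    def get_params(self) -> dict[str, np.ndarray]: ...

    @abstractmethod
    def set_params(self, params: dict[str, np.ndarray]) -> None: ...

    @abstractmethod
    def loss_and_grads(
        self, tiles: np.ndarray, labels: np.ndarray
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Training-mode BCE loss and parameter gradients for one batch."""

    def check_input(self, tiles: np.ndarray) -> None:
        if tiles.ndim != 4 or tiles.shape[1] != self.input_size or tiles.shape[2] != self.input_size:
            raise ContractError(
                f"backbone expects (B, {self.input_size}, {self.input_size}, 3) tiles, "
                f"got {tiles.shape}"
            )


# ---------------------------------------------------------------------------
# im2col convolution primitives


def _conv_forward(x, W, b, stride, pad):
    B, H, Wd, C = x.shape
    kh, kw, _, co = W.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    oh = (H + 2 * pad - kh) // stride + 1
    ow = (Wd + 2 * pad - kw) // stride + 1
    cols = np.empty((B, oh, ow, kh * kw * C), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            slot = (i * kw + j) * C
            cols[..., slot : slot + C] = xp[
                :, i : i + stride * oh : stride, j : j + stride * ow : stride, :
            ]
    out = cols @ W.reshape(-1, co) + b
    return out, (cols, xp.shape, x.shape)


def _conv_backward(dout, W, cache, stride, pad):
    cols, xp_shape, x_shape = cache
    kh, kw, C, co = W.shape
    B, oh, ow, _ = dout.shape
    dW = (cols.reshape(-1, kh * kw * C).T @ dout.reshape(-1, co)).reshape(W.shape)
    db = dout.sum(axis=(0, 1, 2))
    dcols = dout @ W.reshape(-1, co).T
    dxp = np.zeros(xp_shape, dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            slot = (i * kw + j) * C
            dxp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :] += dcols[
                ..., slot : slot + C
            ]
    H, Wd = x_shape[1], x_shape[2]
    dx = dxp[:, pad : pad + H, pad : pad + Wd, :]
    return dx, dW, db


def _bn_forward(x, gamma, beta, running_mean, running_var, train):
    if train:
        mu = x.mean(axis=(0, 1, 2))
        var = x.var(axis=(0, 1, 2))
        running_mean *= _BN_MOMENTUM
        running_mean += (1 - _BN_MOMENTUM) * mu
        running_var *= _BN_MOMENTUM
        running_var += (1 - _BN_MOMENTUM) * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mu) * inv_std
    return gamma * xhat + beta, (xhat, inv_std)


def _bn_backward(dout, gamma, cache):
    xhat, inv_std = cache
    n = dout.shape[0] * dout.shape[1] * dout.shape[2]
    dgamma = (dout * xhat).sum(axis=(0, 1, 2))
    dbeta = dout.sum(axis=(0, 1, 2))
    dxhat = dout * gamma
    dx = (inv_std / n) * (n * dxhat - dxhat.sum(axis=(0, 1, 2)) - xhat * dgamma)
    return dx, dgamma, dbeta


class TinyCNN(TileClassifier):
    """Minimal CNN: avg-pool -> [conv/BN/ReLU] x2 -> GAP -> sigmoid head.

    ``input_size`` is configurable like the paper-scale backbones; tests and
    the end-to-end acceptance run use 128-px tiles.
    """

    def __init__(
        self,
        input_size: int = 128,
        channels: tuple[int, int] = (8, 16),
        pool_factor: int = 4,
        seed: int = 0,
    ):
        if input_size % pool_factor != 0:
            raise ContractError("input_size must be divisible by pool_factor")
        self.input_size = input_size
        self.pool_factor = pool_factor
        rng = np.random.default_rng(seed)
        c1, c2 = channels
        he = lambda *shape: rng.normal(0, np.sqrt(2.0 / np.prod(shape[:-1])), size=shape)
        self.params: dict[str, np.ndarray] = {
            "conv1_W": he(3, 3, 3, c1),
            "conv1_b": np.zeros(c1),
            "bn1_gamma": np.ones(c1),
            "bn1_beta": np.zeros(c1),
            "conv2_W": he(3, 3, c1, c2),
            "conv2_b": np.zeros(c2),
            "bn2_gamma": np.ones(c2),
            "bn2_beta": np.zeros(c2),
            "head_W": rng.normal(0, 0.1, size=(c2, 1)),
            "head_b": np.zeros(1),
        }
        self.buffers: dict[str, np.ndarray] = {
            "bn1_mean": np.zeros(c1),
            "bn1_var": np.ones(c1),
            "bn2_mean": np.zeros(c2),
            "bn2_var": np.ones(c2),
        }

    # -- contract -----------------------------------------------------------

    def parameter_groups(self) -> dict[str, str]:
        groups = {}
        for name in self.params:
            if name.startswith("bn"):
                groups[name] = NORM_AFFINE
            elif name.startswith("head"):
                groups[name] = HEAD
            else:
                groups[name] = OTHER
        return groups

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            self.params[k] = np.array(v, dtype=float)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param/{k}": v.copy() for k, v in self.params.items()}
        state.update({f"buffer/{k}": v.copy() for k, v in self.buffers.items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            kind, name = key.split("/", 1)
            target = self.params if kind == "param" else self.buffers
            target[name] = np.array(value, dtype=float)

    # -- forward / backward -------------------------------------------------

    def _forward(self, tiles: np.ndarray, train: bool):
        self.check_input(tiles)
        p = self.pool_factor
        x = tiles.astype(float) / 255.0
        B, H, W, _ = x.shape
        x = x.reshape(B, H // p, p, W // p, p, 3).mean(axis=(2, 4))

        prm, buf = self.params, self.buffers
        h1, c1cache = _conv_forward(x, prm["conv1_W"], prm["conv1_b"], stride=2, pad=1)
        n1, bn1cache = _bn_forward(
            h1, prm["bn1_gamma"], prm["bn1_beta"], buf["bn1_mean"], buf["bn1_var"], train
        )
        a1 = np.maximum(n1, 0)
        h2, c2cache = _conv_forward(a1, prm["conv2_W"], prm["conv2_b"], stride=2, pad=1)
        n2, bn2cache = _bn_forward(
            h2, prm["bn2_gamma"], prm["bn2_beta"], buf["bn2_mean"], buf["bn2_var"], train
        )
        a2 = np.maximum(n2, 0)
        feat = a2.mean(axis=(1, 2))
        logit = feat @ prm["head_W"] + prm["head_b"]
        prob = sigmoid(logit[:, 0])
        cache = (c1cache, bn1cache, a1, c2cache, bn2cache, a2, feat)
        return prob, logit, cache

    def predict_proba(self, tiles: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = np.empty(len(tiles), dtype=float)
        for start in range(0, len(tiles), batch_size):
            chunk = tiles[start : start + batch_size]
            out[start : start + len(chunk)], _, _ = self._forward(chunk, train=False)
        return out

    def loss_and_grads(self, tiles, labels):
        y = np.asarray(labels, dtype=float)
        prob, logit, cache = self._forward(tiles, train=True)
        loss = bce_loss(prob, y)
        c1cache, bn1cache, a1, c2cache, bn2cache, a2, feat = cache
        B = len(y)
        prm = self.params
        grads: dict[str, np.ndarray] = {}

        dlogit = ((prob - y) / B)[:, None]
        grads["head_W"] = feat.T @ dlogit
        grads["head_b"] = dlogit.sum(axis=0)
        dfeat = dlogit @ prm["head_W"].T

        hw = a2.shape[1] * a2.shape[2]
        da2 = np.broadcast_to(dfeat[:, None, None, :], a2.shape) / hw
        dn2 = da2 * (a2 > 0)
        dh2, grads["bn2_gamma"], grads["bn2_beta"] = _bn_backward(dn2, prm["bn2_gamma"], bn2cache)
        da1, grads["conv2_W"], grads["conv2_b"] = _conv_backward(
            dh2, prm["conv2_W"], c2cache, stride=2, pad=1
        )
        dn1 = da1 * (a1 > 0)
        dh1, grads["bn1_gamma"], grads["bn1_beta"] = _bn_backward(dn1, prm["bn1_gamma"], bn1cache)
        # conv1 input needs no gradient (nothing trainable before it)
        _, grads["conv1_W"], grads["conv1_b"] = _conv_backward(
            dh1, prm["conv1_W"], c1cache, stride=2, pad=1
        )
        return loss, grads


class Adam:
    """Adam optimiser over named parameter dicts with a trainable mask."""

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(
        self,
        params: dict[str, np.ndarray],
        grads: dict[str, np.ndarray],
        lr: float,
        trainable: dict[str, bool] | None = None,
    ) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, g in grads.items():
            if trainable is not None and not trainable.get(name, True):
                continue
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            params[name] -= lr * mhat / (np.sqrt(vhat) + self.eps)
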