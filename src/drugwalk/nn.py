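"""Compact NumPy feed-forward network engine.

Implements exactly what the two classifiers in this pipeline need: fully
connected layers with batch normalization, dropout and ELU / leaky-ReLU
activations, trained with Adam (decoupled L2 weight decay added to the
gradient) against either a three-class focal loss on softmax probabilities
or a binary cross-entropy on logits.  Everything is seeded through a
``numpy.random.Generator``; identical data + seed reproduce identical
parameters bit for bit.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("drugwalk")

_P_FLOOR = 1e-12  # numerical guard for log(p)


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
    if kind == "leaky_relu":
        return np.where(x > 0, x, 0.01 * x)
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "elu":
        return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))
    if kind == "leaky_relu":
        return np.where(x > 0, 1.0, 0.01)
    raise ValueError(kind)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def focal_loss(probs: np.ndarray, true_class: np.ndarray, gamma: float) -> float:
    """Mean focal loss (1-p_t)^gamma * (-ln p_t) over a batch.

    ``probs`` rows must be valid probability vectors; p_t = 0 is clamped at
    1e-12 (with a warning) so the loss stays finite.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    true_class = np.atleast_1d(np.asarray(true_class, dtype=int))
    pt = probs[np.arange(len(true_class)), true_class]
    if np.any(pt <= 0):
        logger.warning("focal_loss: clamping %d zero probabilities", int((pt <= 0).sum()))
        pt = np.maximum(pt, _P_FLOOR)
    return float(np.mean((1.0 - pt) ** gamma * (-np.log(pt))))


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy computed stably from raw logits."""
    z = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    # log(1+exp(-|z|)) + max(z,0) - z*y
    return float(np.mean(np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - z * y))


@dataclass
class _Layer:
    W: np.ndarray
    b: np.ndarray
    bn_gamma: Optional[np.ndarray] = None
    bn_beta: Optional[np.ndarray] = None
    bn_mean: Optional[np.ndarray] = None
    bn_var: Optional[np.ndarray] = None


class MLP:
    """Fully connected net: (Linear -> BatchNorm -> act -> Dropout)* -> Linear."""

    def __init__(self, sizes: Sequence[int], activation: str = "elu",
                 dropout: float = 0.0, batchnorm: bool = True,
                 seed: int = 0, bn_momentum: float = 0.1):
        if len(sizes) < 2:
            raise ValueError("need at least input and output sizes")
        self.sizes = tuple(int(s) for s in sizes)
        self.activation = activation
        self.dropout = float(dropout)
        self.batchnorm = batchnorm
        self.bn_momentum = bn_momentum
        rng = np.random.default_rng(seed)
        self.layers: List[_Layer] = []
        for i, (fan_in, fan_out) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            layer = _Layer(W=W, b=np.zeros(fan_out))
            if batchnorm and i < len(self.sizes) - 2:  # hidden layers only
                layer.bn_gamma = np.ones(fan_out)
                layer.bn_beta = np.zeros(fan_out)
                layer.bn_mean = np.zeros(fan_out)
                layer.bn_var = np.ones(fan_out)
            self.layers.append(layer)
        self._adam_state: Optional[Dict] = None

    # ---- forward / backward -------------------------------------------------

    def forward(self, X: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None):
        """Returns (output, cache).  Dropout/batch statistics only in training."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cache = {"inputs": [], "pre_bn": [], "bn": [], "pre_act": [], "masks": []}
        h = X
        eps = 1e-5
        n_hidden = len(self.layers) - 1
        for i, L in enumerate(self.layers):
            cache["inputs"].append(h)
            z = h @ L.W + L.b
            if i < n_hidden:
                if L.bn_gamma is not None:
                    if training:
                        mu = z.mean(axis=0)
                        var = z.var(axis=0)
                        L.bn_mean = (1 - self.bn_momentum) * L.bn_mean + self.bn_momentum * mu
                        L.bn_var = (1 - self.bn_momentum) * L.bn_var + self.bn_momentum * var
                    else:
                        mu, var = L.bn_mean, L.bn_var
                    zhat = (z - mu) / np.sqrt(var + eps)
                    cache["pre_bn"].append(z)
                    cache["bn"].append((zhat, mu, var))
                    z = L.bn_gamma * zhat + L.bn_beta
                else:
                    cache["pre_bn"].append(None)
                    cache["bn"].append(None)
                cache["pre_act"].append(z)
                h = _act(z, self.activation)
                if training and self.dropout > 0:
                    if rng is None:
                        raise ValueError("training forward pass needs an rng for dropout")
                    mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                    h = h * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
            else:
                h = z
        return h, cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(X, training=False)
        return out

    def _backward(self, dout: np.ndarray, cache) -> List[Tuple[np.ndarray, np.ndarray,
                                                               Optional[np.ndarray],
                                                               Optional[np.ndarray]]]:
        """Gradient of the mean loss wrt every parameter; dout is dL/d(output)."""
        grads = [None] * len(self.layers)
        eps = 1e-5
        n_hidden = len(self.layers) - 1
        d = dout
        for i in reversed(range(len(self.layers))):
            L = self.layers[i]
            if i < n_hidden:
                if cache["masks"][i] is not None:
                    d = d * cache["masks"][i]
                d = d * _act_grad(cache["pre_act"][i], self.activation)
                if L.bn_gamma is not None:
                    zhat, mu, var = cache["bn"][i]
                    dgamma = (d * zhat).sum(axis=0)
                    dbeta = d.sum(axis=0)
                    n = d.shape[0]
                    inv = 1.0 / np.sqrt(var + eps)
                    dzhat = d * L.bn_gamma
                    # standard batchnorm backward
                    d = (inv / n) * (n * dzhat - dzhat.sum(axis=0)
                                     - zhat * (dzhat * zhat).sum(axis=0))
                else:
                    dgamma = dbeta = None
            else:
                dgamma = dbeta = None
            h = cache["inputs"][i]
            dW = h.T @ d
            db = d.sum(axis=0)
            grads[i] = (dW, db, dgamma, dbeta)
            if i > 0:
                d = d @ L.W.T
        return grads

    # ---- optimisation -------------------------------------------------------

    def _adam_step(self, grads, lr: float, weight_decay: float,
                   betas=(0.9, 0.999), eps: float = 1e-8):
        if self._adam_state is None:
            self._adam_state = {"t": 0, "m": [], "v": []}
            for L in self.layers:
                params = [L.W, L.b] + ([L.bn_gamma, L.bn_beta] if L.bn_gamma is not None else [])
                self._adam_state["m"].append([np.zeros_like(p) for p in params])
                self._adam_state["v"].append([np.zeros_like(p) for p in params])
        st = self._adam_state
        st["t"] += 1
        b1, b2 = betas
        bc1 = 1 - b1 ** st["t"]
        bc2 = 1 - b2 ** st["t"]
        for i, (L, (dW, db, dg, dbta)) in enumerate(zip(self.layers, grads)):
            params = [L.W, L.b]
            gs = [dW + weight_decay * L.W, db]
            if L.bn_gamma is not None:
                params += [L.bn_gamma, L.bn_beta]
                gs += [dg, dbta]
            for j, (p, g) in enumerate(zip(params, gs)):
                m = st["m"][i][j]
                v = st["v"][i][j]
                m *= b1; m += (1 - b1) * g
                v *= b2; v += (1 - b2) * g * g
                p -= lr * (m / bc1) / (np.sqrt(v / bc2) + eps)

    def clone(self) -> "MLP":
        c = copy.deepcopy(self)
        c._adam_state = None
        return c

    def state_dict(self):
        return copy.deepcopy(self.layers)

    def load_state_dict(self, layers):
        self.layers = copy.deepcopy(layers)


def train_mlp(model: MLP, X: np.ndarray, y: np.ndarray, *, loss: str,
              lr: float, weight_decay: float, epochs: int, batch_size: int,
              seed: int = 0, gamma: float = 2.0,
              epoch_callback=None) -> List[float]:
    """Mini-batch Adam training loop; returns the per-epoch mean training loss.

    ``loss`` is "focal" (multi-class; y holds class indices) or "bce"
    (binary; y in {0,1}, single logit output).  ``epoch_callback(epoch,
    model)`` runs after each epoch — used for checkpoint selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trace: List[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            out, cache = model.forward(xb, training=True, rng=rng)
            if loss == "focal":
                p = softmax(out)
                yi = yb.astype(int)
                pt = np.maximum(p[np.arange(len(yi)), yi], _P_FLOOR)
                losses.append(focal_loss(p, yi, gamma) * len(yi))
                # dL/dp_t through the modulating factor, then softmax jacobian
                dL_dpt = (gamma * (1 - pt) ** (gamma - 1) * np.log(pt)
                          - (1 - pt) ** gamma / pt)
                onehot = np.zeros_like(p)
                onehot[np.arange(len(yi)), yi] = 1.0
                dout = dL_dpt[:, None] * pt[:, None] * (onehot - p) / len(yi)
            elif loss == "bce":
                z = out.ravel()
                yf = yb.astype(float).ravel()
                losses.append(bce_with_logits(z, yf) * len(yf))
                sig = 1.0 / (1.0 + np.exp(-z))
                dout = ((sig - yf) / len(yf))[:, None]
            else:
                raise ValueError(f"unknown loss {loss!r}")
            grads = model._backward(dout, cache)
            model._adam_step(grads, lr=lr, weight_decay=weight_decay)
        trace.append(sum(losses) / n)
        if epoch_callback is not None:
            epoch_callback(epoch, model)
    return trace
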