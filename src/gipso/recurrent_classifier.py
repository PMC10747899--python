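"""Lightweight Elman recurrent network for binary anomaly classification.

The network consumes a lag window as a length-``lags`` sequence of scalar
inputs.  Each recurrent layer updates its hidden state as

    a_t = b + W h_{t-1} + U x_t,      h_t = tanh(a_t)

and the class-1 (anomalous) probability is read from the final hidden state
through a single sigmoid unit.  Dropout is applied to each layer's output
stream during training (the recurrent state itself is kept intact).  Training
minimizes binary cross-entropy with Adam and full backpropagation through
time, with early stopping on validation loss at a patience of one third of
the requested epoch budget, restoring the best-validation weights.

Everything is plain numpy and seed-deterministic, which keeps hyperparameter
tuning runs cheap and exactly reproducible.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import WindowedDataset
from .search_space import HyperparameterSet

__all__ = [
    "RNNParameters",
    "TrainingRun",
    "build_model",
    "forward",
    "train",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class RNNParameters:
    """Weights and input-standardization state of one network."""

    U: list[np.ndarray]  # input weights per layer, (n_l, d_in)
    W: list[np.ndarray]  # recurrent weights per layer, (n_l, n_l)
    b: list[np.ndarray]  # biases per layer, (n_l,)
    v: np.ndarray        # output weights, (n_last,)
    c: float             # output bias
    dropout: float
    lags: int
    mu: float = 0.0      # training-split standardization
    sd: float = 1.0

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(w.shape[0] for w in self.W)

    def copy_weights(self) -> tuple:
        return (
            [u.copy() for u in self.U],
            [w.copy() for w in self.W],
            [bb.copy() for bb in self.b],
            self.v.copy(),
            self.c,
        )

    def set_weights(self, weights: tuple) -> None:
        self.U, self.W, self.b, self.v, self.c = (
            [u.copy() for u in weights[0]],
            [w.copy() for w in weights[1]],
            [bb.copy() for bb in weights[2]],
            weights[3].copy(),
            weights[4],
        )


@dataclass
class TrainingRun:
    """Record of one training: epoch budget, early-stopping state, loss
    history (weights are restored to the best-validation epoch)."""

    epochs_requested: int
    epochs_executed: int
    patience: int
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.epochs_executed + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
            }
        )


def build_model(hp: HyperparameterSet, lags: int = 15, seed: int = 0) -> RNNParameters:
    """Glorot-uniform initialized network matching the hyperparameter set:
    ``lags`` scalar input steps, hp.num_layers recurrent layers of
    hp.neurons units, one sigmoid output."""
    rng = np.random.default_rng(seed)
    U, W, b = [], [], []
    d_in = 1
    for n in hp.neurons:
        s_u = math.sqrt(6.0 / (d_in + n))
        s_w = math.sqrt(6.0 / (n + n))
        U.append(rng.uniform(-s_u, s_u, size=(n, d_in)))
        W.append(rng.uniform(-s_w, s_w, size=(n, n)))
        b.append(np.zeros(n))
        d_in = n
    n_last = hp.neurons[-1]
    s_v = math.sqrt(6.0 / (n_last + 1))
    v = rng.uniform(-s_v, s_v, size=n_last)
    return RNNParameters(U, W, b, v, 0.0, hp.dropout, lags)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _forward_cached(
    model: RNNParameters,
    X: np.ndarray,
    masks: list[np.ndarray] | None = None,
):
    """Run the recurrence over a (B, lags) batch; return probabilities and
    the per-timestep caches needed for backpropagation through time."""
    B, T = X.shape
    L = len(model.W)
    h = [np.zeros((B, w.shape[0])) for w in model.W]
    cache_in = [[None] * T for _ in range(L)]
    cache_hprev = [[None] * T for _ in range(L)]
    cache_h = [[None] * T for _ in range(L)]
    x = None
    for t in range(T):
        x = X[:, t : t + 1]
        for l in range(L):
            a = x @ model.U[l].T + h[l] @ model.W[l].T + model.b[l]
            h_new = np.tanh(a)
            cache_in[l][t] = x
            cache_hprev[l][t] = h[l]
            cache_h[l][t] = h_new
            h[l] = h_new
            x = h_new if masks is None else h_new * masks[l]
    logits = x @ model.v + model.c
    p = _sigmoid(logits)
    return p, (cache_in, cache_hprev, cache_h, x)


def forward(model: RNNParameters, windows: np.ndarray) -> np.ndarray:
    """Class-1 probability for one window (shape (lags,)) or a batch
    (shape (n, lags)).  Inputs are standardized with the model's stored
    training statistics; dropout is inactive."""
    w = np.asarray(windows, dtype=float)
    single = w.ndim == 1
    if single:
        w = w[None, :]
    if w.shape[1] != model.lags:
        raise ValueError(f"window length {w.shape[1]} != lags {model.lags}")
    w = (w - model.mu) / model.sd
    p, _ = _forward_cached(model, w)
    return p[0] if single else p


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _backward(
    model: RNNParameters,
    Xb: np.ndarray,
    yb: np.ndarray,
    masks: list[np.ndarray],
):
    """BPTT gradients of mean binary cross-entropy over the batch."""
    B, T = Xb.shape
    L = len(model.W)
    p, (cache_in, cache_hprev, cache_h, top_out) = _forward_cached(model, Xb, masks)

    gU = [np.zeros_like(u) for u in model.U]
    gW = [np.zeros_like(w) for w in model.W]
    gb = [np.zeros_like(bb) for bb in model.b]

    dz = (p - yb) / B                       # (B,)
    gv = top_out.T @ dz
    gc = float(dz.sum())

    # Gradient flowing into each layer's hidden state from t+1 (recurrence).
    dh_rec = [np.zeros((B, w.shape[0])) for w in model.W]
    for t in range(T - 1, -1, -1):
        d_from_above = None
        for l in range(L - 1, -1, -1):
            dh = dh_rec[l].copy()
            if l == L - 1 and t == T - 1:
                dh += np.outer(dz, model.v) * masks[l]
            if d_from_above is not None:
                dh += d_from_above
            da = dh * (1.0 - cache_h[l][t] ** 2)
            gU[l] += da.T @ cache_in[l][t]
            gW[l] += da.T @ cache_hprev[l][t]
            gb[l] += da.sum(axis=0)
            dh_rec[l] = da @ model.W[l]
            d_from_above = (da @ model.U[l]) * masks[l - 1] if l > 0 else None
    return p, (gU, gW, gb, gv, gc)


class _Adam:
    """Adam over the model's parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train(
    model: RNNParameters,
    train_set: WindowedDataset,
    val_set: WindowedDataset,
    hp: HyperparameterSet,
    seed: int = 0,
    batch_size: int = 32,
) -> TrainingRun:
    """Fit the network with Adam at hp.learning_rate for at most hp.epochs
    epochs, early-stopping when validation loss fails to improve for
    ceil(epochs / 3) consecutive epochs; restores best-validation weights."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(seed)
    patience = math.ceil(hp.epochs / 3)

    model.mu = float(train_set.X.mean())
    model.sd = float(train_set.X.std()) or 1.0
    Xtr = (train_set.X - model.mu) / model.sd
    ytr = train_set.y.astype(float)
    Xval = (val_set.X - model.mu) / model.sd
    yval = val_set.y.astype(float)

    params = model.U + model.W + model.b + [model.v]
    opt = _Adam(params, hp.learning_rate)
    c_state = {"m": 0.0, "v": 0.0}
    keep = 1.0 - hp.dropout

    run = TrainingRun(hp.epochs, 0, patience)
    best_val = np.inf
    best_weights = model.copy_weights()
    stall = 0
    n = len(ytr)
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb, yb = Xtr[idx], ytr[idx]
            masks = [
                rng.binomial(1, keep, size=(len(idx), w.shape[0])) / keep
                for w in model.W
            ]
            p, (gU, gW, gb, gv, gc) = _backward(model, Xb, yb, masks)
            losses.append(_bce(p, yb))
            opt.step(params, gU + gW + gb + [gv])
            # scalar output bias shares the Adam recurrences
            c_state["m"] += (1 - opt.b1) * (gc - c_state["m"])
            c_state["v"] += (1 - opt.b2) * (gc * gc - c_state["v"])
            model.c -= hp.learning_rate * (
                c_state["m"] / (1 - opt.b1**opt.t)
            ) / (math.sqrt(c_state["v"] / (1 - opt.b2**opt.t)) + opt.eps)

        p_val, _ = _forward_cached(model, Xval)
        vloss = _bce(p_val, yval)
        run.train_loss.append(float(np.mean(losses)))
        run.val_loss.append(vloss)
        run.epochs_executed = epoch + 1
        if vloss < best_val - 1e-12:
            best_val = vloss
            best_weights = model.copy_weights()
            run.best_epoch = epoch + 1
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    model.set_weights(best_weights)
    return run


def predict(
    model: RNNParameters, windows: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Hard labels: 1 (anomalous) iff the predicted probability >= threshold."""
    p = forward(model, np.atleast_2d(np.asarray(windows, dtype=float)))
    return (p >= threshold).astype(int)


def save_model(model: RNNParameters, path: str | Path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> RNNParameters:
    with open(path, "rb") as fh:
        return pickle.load(fh)
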