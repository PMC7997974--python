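"""Minimal fully connected network with Adam, dropout and early stopping.

Both learners in this package are deliberately small, shallow networks (a
single hidden layer), trained with the adaptive-moment (Adam) optimizer,
inverted dropout on the hidden layer, and early stopping when the validation
loss stops decreasing.  Losses are supplied as callables so that the power
predictor can train through the EOM calibration (squared error in power
space) and the candidate classifier through a logistic loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "fit_mlp"]


class MLP:
    """Fully connected net with ReLU hidden layers and a linear output."""

    def __init__(self, layer_sizes: list[int], seed: int = 0):
        rng = np.random.default_rng(seed)
        self.sizes = list(layer_sizes)
        self.W = []
        self.b = []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._cache = None

    def forward(
        self,
        X: np.ndarray,
        training: bool = False,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        acts = [a]
        masks = []
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < n_layers - 1:
                a = np.maximum(z, 0.0)
                if training and dropout > 0.0:
                    mask = (rng.uniform(size=a.shape) >= dropout) / (1.0 - dropout)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                a = z
            acts.append(a)
        self._cache = (acts, masks)
        return a[:, 0] if self.sizes[-1] == 1 else a

    def backward(self, dout: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Gradients of the loss given d(loss)/d(output); call after forward."""
        acts, masks = self._cache
        delta = np.atleast_2d(np.asarray(dout, dtype=float))
        if delta.shape[0] == 1 and acts[0].shape[0] != 1:
            delta = delta.T
        if delta.ndim == 1:
            delta = delta[:, None]
        if delta.shape[1] != self.sizes[-1]:
            delta = delta.reshape(-1, self.sizes[-1])
        grads = [None] * len(self.W)
        for i in reversed(range(len(self.W))):
            a_prev = acts[i]
            grads[i] = (a_prev.T @ delta, delta.sum(axis=0))
            if i > 0:
                delta = delta @ self.W[i].T
                delta = delta * (acts[i] > 0)
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
        return grads

    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


def fit_mlp(
    net: MLP,
    X: np.ndarray,
    y: np.ndarray,
    loss_grad,
    *,
    batch_size: int = 1000,
    lr: float = 1e-3,
    max_epochs: int = 500,
    patience: int = 10,
    val_fraction: float = 0.1,
    dropout: float = 0.0,
    seed: int = 0,
    lr_decay_steps: int = 0,
) -> dict:
    """Train with Adam and early stopping on a held-out validation split.

    ``loss_grad(out, y)`` returns ``(mean_loss, d_loss/d_out)`` with the
    gradient already averaged over the batch.  When ``lr_decay_steps > 0``,
    each validation plateau restores the best weights and halves the learning
    rate (up to that many times) before stopping for good.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(X)
    idx = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if val_fraction > 0 and n >= 10 else 0
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    Xt, yt = X[train_idx], y[train_idx]
    Xv, yv = X[val_idx], y[val_idx]

    m = [np.zeros_like(w) for w in net.W] + [np.zeros_like(b) for b in net.b]
    v = [np.zeros_like(w) for w in net.W] + [np.zeros_like(b) for b in net.b]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best = (np.inf, net.get_weights())
    stall = 0
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(max_epochs):
        order = rng.permutation(len(Xt))
        losses = []
        for s in range(0, len(Xt), batch_size):
            sel = order[s : s + batch_size]
            out = net.forward(Xt[sel], training=True, dropout=dropout, rng=rng)
            loss, dout = loss_grad(out, yt[sel])
            grads = net.backward(dout)
            params = net.W + net.b
            glist = [gw for gw, _ in grads] + [gb for _, gb in grads]
            t += 1
            for k, (p, g) in enumerate(zip(params, glist)):
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**t)
                vhat = v[k] / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))
        if n_val:
            out = net.forward(Xv)
            vloss, _ = loss_grad(out, yv)
        else:
            vloss = history["train_loss"][-1]
        history["val_loss"].append(float(vloss))
        if vloss < best[0] - 1e-12:
            best = (vloss, net.get_weights())
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                if lr_decay_steps > 0:
                    lr_decay_steps -= 1
                    lr *= 0.5
                    net.set_weights(best[1])
                    stall = 0
                else:
                    break
    net.set_weights(best[1])
    history["best_val_loss"] = float(best[0])
    history["epochs"] = epoch + 1
    return history
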