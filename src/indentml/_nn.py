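"""Minimal dense-network engine: leaky-ReLU MLP trained with Adam.

Implements exactly what the surrogate networks need — fully connected
layers, leaky-ReLU hidden activations (slope ``alpha``), linear output,
MSE or MAE loss, minibatch Adam with early stopping on a validation set —
with deterministic behaviour for a given seed.  Weights use Glorot
uniform initialisation.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import NDArray

__all__ = ["DenseNet"]


class DenseNet:
    """A fully connected network ``sizes[0] -> ... -> sizes[-1]``."""

    def __init__(self, sizes: list[int], alpha: float = 0.3, seed: int = 0):
        self.sizes = list(sizes)
        self.alpha = float(alpha)
        rng = np.random.default_rng(seed)
        self.W: list[NDArray] = []
        self.b: list[NDArray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.W.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))

    # ---- forward / backward ---------------------------------------------
    def forward(self, X: NDArray) -> NDArray:
        a = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            a = z if i == last else np.where(z > 0, z, self.alpha * z)
        return a

    def _forward_cached(self, X: NDArray):
        acts = [X]
        zs = []
        a = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            zs.append(z)
            a = z if i == last else np.where(z > 0, z, self.alpha * z)
            acts.append(a)
        return acts, zs

    def _backward(self, X: NDArray, Y: NDArray, loss: str):
        """Return (loss value, weight grads, bias grads) for a minibatch."""
        n = X.shape[0]
        acts, zs = self._forward_cached(X)
        out = acts[-1]
        resid = out - Y
        if loss == "mse":
            value = float(np.mean(resid**2))
            delta = 2.0 * resid / resid.size
        elif loss == "mae":
            value = float(np.mean(np.abs(resid)))
            delta = np.sign(resid) / resid.size
        else:
            raise ValueError(f"unknown loss {loss!r}")
        gW = [np.empty_like(W) for W in self.W]
        gb = [np.empty_like(b) for b in self.b]
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                delta = delta * np.where(zs[i - 1] > 0, 1.0, self.alpha)
        del n
        return value, gW, gb

    def loss_value(self, X: NDArray, Y: NDArray, loss: str) -> float:
        resid = self.forward(X) - Y
        return float(np.mean(resid**2) if loss == "mse" else np.mean(np.abs(resid)))

    # ---- training --------------------------------------------------------
    def train(
        self,
        X: NDArray,
        Y: NDArray,
        X_val: NDArray,
        Y_val: NDArray,
        *,
        loss: str = "mse",
        learning_rate: float = 1.0e-3,
        batch_size: int = 64,
        max_epochs: int = 2000,
        patience: int = 100,
        seed: int = 0,
        lr_decay: str = "cosine",
        min_learning_rate: float = 1.0e-5,
        val_metric=None,
    ) -> dict:
        """Minibatch Adam with early stopping on validation loss.

        The weights from the best-validation epoch are restored at the
        end.  Returns a history dict with per-epoch train/validation loss
        and the running best ("best_val_so_far"), plus ``best_epoch``.

        Raises
        ------
        FloatingPointError
            If the training loss becomes non-finite (divergence), with
            the epoch in the message.
        """
        rng = np.random.default_rng(seed)
        mW = [np.zeros_like(W) for W in self.W]
        vW = [np.zeros_like(W) for W in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1.0e-8
        t = 0

        n = X.shape[0]
        history = {"epoch": [], "train_loss": [], "val_loss": [], "best_val_so_far": []}
        if val_metric is not None:
            history["val_metric"] = []
        best_val = np.inf
        best_epoch = -1
        best_weights = None
        since_best = 0

        for epoch in range(max_epochs):
            if lr_decay == "cosine":
                frac = epoch / max(max_epochs - 1, 1)
                lr = min_learning_rate + 0.5 * (learning_rate - min_learning_rate) * (
                    1.0 + np.cos(np.pi * frac)
                )
            elif lr_decay == "none":
                lr = learning_rate
            else:
                raise ValueError(f"unknown lr_decay {lr_decay!r}")
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                value, gW, gb = self._backward(X[idx], Y[idx], loss)
                epoch_loss += value
                n_batches += 1
                t += 1
                corr1 = 1.0 - beta1**t
                corr2 = 1.0 - beta2**t
                for i in range(len(self.W)):
                    for g, m, v, p in ((gW[i], mW[i], vW[i], self.W[i]),
                                       (gb[i], mb[i], vb[i], self.b[i])):
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g * g
                        p -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)
            epoch_loss /= max(n_batches, 1)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    f"training loss diverged (non-finite) at epoch {epoch}"
                )
            val_loss = self.loss_value(X_val, Y_val, loss)
            if val_loss < best_val:
                best_val = val_loss
                best_epoch = epoch
                best_weights = ([W.copy() for W in self.W], [b.copy() for b in self.b])
                since_best = 0
            else:
                since_best += 1
            history["epoch"].append(epoch)
            history["train_loss"].append(epoch_loss)
            history["val_loss"].append(val_loss)
            history["best_val_so_far"].append(best_val)
            if val_metric is not None:
                history["val_metric"].append(float(val_metric(self)))
            if since_best > patience:
                break

        if best_weights is not None:
            self.W, self.b = best_weights
        history["best_epoch"] = best_epoch
        history["best_val_loss"] = best_val
        return history

    # ---- (de)serialisation ----------------------------------------------
    def state(self) -> dict:
        return {
            "sizes": self.sizes,
            "alpha": self.alpha,
            "weights": [W.copy() for W in self.W],
            "biases": [b.copy() for b in self.b],
        }

    @classmethod
    def from_state(cls, state: dict) -> "DenseNet":
        net = cls(state["sizes"], alpha=state["alpha"])
        net.W = [np.asarray(W, dtype=float) for W in state["weights"]]
        net.b = [np.asarray(b, dtype=float) for b in state["biases"]]
        return net
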