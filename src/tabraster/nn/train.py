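"""SGD-with-momentum training loop for the numpy residual networks."""

from __future__ import annotations

import numpy as np

from .layers import softmax_cross_entropy

__all__ = ["SGDMomentum", "fit"]


class SGDMomentum:
    """Classical momentum: v <- mu*v - lr*g; w <- w + v.

    The learning rate follows a step schedule: it is multiplied by
    ``drop_factor`` every ``drop_period`` epochs (so with the default
    period of 20 and 5 training epochs it never drops).
    """

    def __init__(self, params, lr: float = 0.001, momentum: float = 0.9,
                 drop_factor: float = 0.1, drop_period: int = 20):
        self.params = list(params)
        self.base_lr = lr
        self.momentum = momentum
        self.drop_factor = drop_factor
        self.drop_period = drop_period

    def lr_at(self, epoch: int) -> float:
        """Learning rate in force during ``epoch`` (0-based)."""
        return self.base_lr * self.drop_factor ** (epoch // self.drop_period)

    def step(self, epoch: int) -> None:
        lr = self.lr_at(epoch)
        for p in self.params:
            p.velocity = self.momentum * p.velocity - lr * p.grad
            p.data = p.data + p.velocity

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def fit(
    model,
    x: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int = 32,
    optimizer: SGDMomentum | None = None,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> dict:
    """Train a model in-place; returns per-epoch loss/accuracy curves.

    Runs exactly ``epochs`` epochs of mini-batch SGD over ``(x, y)``
    (shuffled each epoch with a seeded generator). When a held-out set is
    given, its accuracy/loss are evaluated after every epoch with the
    network in inference mode.
    """
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    opt = optimizer or SGDMomentum(model.params())
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
               "lr": []}
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step(epoch)
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(correct / n)
        history["lr"].append(opt.lr_at(epoch))
        if x_val is not None:
            vloss, vacc = evaluate_model(model, x_val, y_val, batch_size)
            history["val_loss"].append(vloss)
            history["val_acc"].append(vacc)
        if verbose:
            msg = (f"epoch {epoch + 1}/{epochs} "
                   f"loss {history['train_loss'][-1]:.4f} "
                   f"acc {history['train_acc'][-1]:.3f}")
            if x_val is not None:
                msg += f" val_acc {history['val_acc'][-1]:.3f}"
            print(msg)
    return history


def evaluate_model(model, x, y, batch_size: int = 32) -> tuple[float, float]:
    """Mean loss and accuracy in inference mode."""
    losses, correct = [], 0
    n = x.shape[0]
    for start in range(0, n, batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return sum(losses) / n, correct / n
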