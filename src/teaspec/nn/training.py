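"""Optimization for the spectral-index regressor: AdamW with cosine
annealing, Smooth-L1 loss, early stopping with best-checkpoint restore."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, smooth_l1
from .layers import Module


class AdamW:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int, min_lr_frac: float = 0.01) -> float:
    """Cosine-annealed learning rate over the full training horizon."""
    lr_min = base_lr * min_lr_frac
    return lr_min + 0.5 * (base_lr - lr_min) * (1 + np.cos(np.pi * epoch / max(total_epochs, 1)))


def train_network(
    model: Module,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int,
    base_lr: float,
    weight_decay: float,
    batch_size: int | None,
    patience: int,
    rng: np.random.Generator,
    beta: float = 1.0,
) -> dict:
    """Train with early stopping on validation Smooth-L1 loss.

    Returns a history dict; the model is left holding the best checkpoint.
    """
    optimizer = AdamW(model.parameters(), lr=base_lr, weight_decay=weight_decay)
    n = len(x_train)
    best_loss = np.inf
    best_state = model.state()
    best_epoch = -1
    waited = 0
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(epochs):
        optimizer.lr = cosine_lr(base_lr, epoch, epochs)
        model.set_training(True)
        order = rng.permutation(n)
        batches = [order] if batch_size is None else [
            order[i: i + batch_size] for i in range(0, n, batch_size)
        ]
        epoch_loss = 0.0
        for batch in batches:
            model.zero_grad()
            pred = model(Tensor(x_train[batch]))
            loss = smooth_l1(pred, y_train[batch], beta=beta)
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(batch)
        history["train_loss"].append(epoch_loss / n)

        model.set_training(False)
        val_pred = model(Tensor(x_val))
        val_loss = float(smooth_l1(val_pred, y_val, beta=beta).data)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_state = model.state()
            best_epoch = epoch
            waited = 0
        else:
            waited += 1
            if waited > patience:
                break

    model.load_state(best_state)
    model.set_training(False)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = best_loss
    return history


def predict(model: Module, x: np.ndarray) -> np.ndarray:
    model.set_training(False)
    return model(Tensor(x)).data
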