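"""Finite-difference verification of the autograd engine and layer stack."""

import numpy as np
import pytest

from teaspec.models import CNNArchitectureConfig
from teaspec.nn import (
    AdamW,
    CNNBiLSTMAttention,
    Tensor,
    conv1d,
    cosine_lr,
    smooth_l1,
    softmax,
    stack,
    train_network,
)
from teaspec.nn.layers import BatchNorm1d, BiLSTM, MultiHeadSelfAttention


def numeric_grad(fn, array, idx, eps=1e-6):
    orig = array[idx]
    array[idx] = orig + eps
    up = fn()
    array[idx] = orig - eps
    down = fn()
    array[idx] = orig
    return (up - down) / (2 * eps)


def check_against_fd(loss_fn, tensors, rng, n_probes=4, tol=1e-5):
    loss = loss_fn()
    loss.backward()
    for t in tensors:
        for _ in range(n_probes):
            idx = tuple(rng.integers(0, s) for s in t.data.shape)
            num = numeric_grad(lambda: float(loss_fn().data), t.data, idx)
            ana = t.grad[idx]
            assert num == pytest.approx(ana, abs=tol, rel=1e-4), (t.shape, idx)


@pytest.mark.parametrize(
    "op",
    [
        lambda a, b: (a @ b).tanh().sum(),
        lambda a, b: ((a @ b) * a + a / (a.sigmoid() + 3.0)).sigmoid().mean(),
        lambda a, b: softmax(a @ b, axis=-1).sum(axis=0).mean(),
        lambda a, b: (a[:, 1:] * 2.0).exp().sum() + b.leaky_relu(0.01).sum(),
        lambda a, b: stack([a[:, 0], a[:, 1]], axis=1).mean() + (b**2.0).sum(),
    ],
)
def test_elementwise_and_matmul_gradients(op, rng):
    a = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
    b = Tensor(rng.normal(size=(4, 4)), requires_grad=True)
    check_against_fd(lambda: _fresh(op, a, b), [a, b], rng)


def _fresh(op, a, b):
    # rebuild the graph each call so finite differencing sees current data
    return op(a, b)


def test_batched_matmul_gradients(rng):
    a = Tensor(rng.normal(size=(2, 3, 4, 5)), requires_grad=True)
    b = Tensor(rng.normal(size=(2, 3, 5, 4)), requires_grad=True)
    check_against_fd(lambda: (a @ b).tanh().sum(), [a, b], rng)


@pytest.mark.parametrize("stride,pad", [(1, 2), (2, 1)])
def test_conv1d_gradients(stride, pad, rng):
    x = Tensor(rng.normal(size=(2, 3, 11)), requires_grad=True)
    w = Tensor(rng.normal(size=(4, 3, 5 if pad == 2 else 3)), requires_grad=True)
    b = Tensor(rng.normal(size=4), requires_grad=True)
    check_against_fd(
        lambda: conv1d(x, w, b, stride=stride, pad=pad).sigmoid().sum(), [x, w, b], rng
    )


def test_smooth_l1_gradient_both_branches(rng):
    pred = Tensor(np.array([0.1, 2.5, -3.0, 0.4]), requires_grad=True)
    target = np.zeros(4)
    check_against_fd(lambda: smooth_l1(pred, target, beta=1.0), [pred], rng)


def test_lstm_and_attention_gradients(rng):
    lstm = BiLSTM(3, 4, rng)
    attn = MultiHeadSelfAttention(8, 2, rng)
    x = Tensor(rng.normal(size=(2, 5, 3)), requires_grad=True)
    params = [x] + lstm.parameters()[:2] + attn.parameters()[:2]
    check_against_fd(lambda: attn(lstm(x)).mean(), params, rng, n_probes=3)


def test_batchnorm_train_mode_gradients(rng):
    bn = BatchNorm1d(3)
    x = Tensor(rng.normal(size=(4, 3, 6)), requires_grad=True)

    def loss():
        bn.running_mean[:] = 0.0  # keep state fixed across FD evaluations
        bn.running_var[:] = 1.0
        return bn(x).tanh().sum()

    check_against_fd(loss, [x, bn.gamma, bn.beta], rng)


def test_full_network_gradients(rng):
    arch = CNNArchitectureConfig(
        channels=(4, 4, 4, 4, 4), lstm_hidden=4, attention_heads=2,
        head_hidden=8, dropout=0.0, epochs=1, batch_size=None, patience=1,
    )
    model = CNNBiLSTMAttention(arch, np.random.default_rng(1))
    x = rng.normal(size=(3, 1, 16))
    y = rng.normal(size=3)

    def loss():
        model.set_training(False)
        return smooth_l1(model(Tensor(x)), y)

    model.zero_grad()
    probe = model.parameters()
    picks = [probe[i] for i in np.random.default_rng(2).choice(len(probe), 6, replace=False)]
    check_against_fd(loss, picks, rng, n_probes=2)


def test_training_reduces_loss_and_is_deterministic():
    rng = np.random.default_rng(0)
    n = 40
    s = rng.normal(size=n)
    x = (0.8 * s[:, None] + 0.2 * rng.normal(size=(n, 12)))[:, None, :]
    y = s
    arch = CNNArchitectureConfig(
        channels=(4, 4, 4, 4, 4), strides=(1, 2, 2, 1, 1), lstm_hidden=4,
        attention_heads=2, head_hidden=8, dropout=0.0, epochs=50,
        base_lr=1e-2, batch_size=None, patience=50,
    )

    def run():
        model = CNNBiLSTMAttention(arch, np.random.default_rng(3))
        history = train_network(
            model, x[:32], y[:32], x[32:], y[32:], epochs=arch.epochs,
            base_lr=arch.base_lr, weight_decay=1e-4, batch_size=None,
            patience=arch.patience, rng=np.random.default_rng(4),
        )
        return history

    h1 = run()
    assert h1["train_loss"][-1] < h1["train_loss"][0] * 0.5
    h2 = run()
    np.testing.assert_array_equal(h1["train_loss"], h2["train_loss"])


def test_cosine_schedule_endpoints():
    assert cosine_lr(1.0, 0, 100) == pytest.approx(1.0)
    assert cosine_lr(1.0, 100, 100) == pytest.approx(0.01)


def test_adamw_decays_unused_weights():
    p = Tensor(np.ones(3), requires_grad=True)
    p.grad = np.zeros(3)
    opt = AdamW([p], lr=0.1, weight_decay=0.5)
    opt.step()
    assert np.all(p.data < 1.0)
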