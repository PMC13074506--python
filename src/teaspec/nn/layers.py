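"""Neural-network layers for the spectral-index regressor.

Built on :mod:`teaspec.nn.autograd`.  Initialization follows the usual
fan-based schemes: Kaiming (He) for convolutional weights feeding LeakyReLU
activations, Xavier (Glorot) for dense layers.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv1d, dropout, softmax, stack


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal parameter container with a shared train/eval flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.set_training(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()


def kaiming_normal(rng, shape, fan_in, a=0.01):
    gain = np.sqrt(2.0 / (1.0 + a**2))
    return rng.normal(0.0, gain / np.sqrt(fan_in), size=shape)


def xavier_uniform(rng, shape, fan_in, fan_out):
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Dense(Module):
    def __init__(self, n_in, n_out, rng, init="xavier"):
        super().__init__()
        if init == "xavier":
            w = xavier_uniform(rng, (n_in, n_out), n_in, n_out)
        else:
            w = kaiming_normal(rng, (n_in, n_out), n_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-padded 1-D convolution, Kaiming-initialized."""

    def __init__(self, c_in, c_out, kernel, rng, stride=1):
        super().__init__()
        self.stride = stride
        self.pad = (kernel - 1) // 2
        self.weight = Parameter(kaiming_normal(rng, (c_out, c_in, kernel), c_in * kernel))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm1d(Module):
    """Per-channel normalization over (batch, time) for (B, C, T) inputs."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
            inv = (var + self.eps) ** -0.5
            norm = centered * inv
        else:
            mu = self.running_mean[None, :, None]
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            norm = (x - mu) * inv[None, :, None]
        return norm * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class SEBlock(Module):
    """Squeeze-and-excitation channel attention for (B, C, T) features."""

    def __init__(self, channels, reduction, rng):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)

    def __call__(self, x: Tensor) -> Tensor:
        squeeze = x.mean(axis=2)                      # (B, C)
        scale = self.fc2(self.fc1(squeeze).relu()).sigmoid()
        return x * scale.reshape(scale.shape[0], scale.shape[1], 1)


class ConvBlock(Module):
    """Conv -> BatchNorm -> LeakyReLU -> SE, with a residual shortcut when
    the shapes allow it (stride 1, matching channel width)."""

    def __init__(self, c_in, c_out, kernel, rng, stride=1, se_reduction=4):
        super().__init__()
        self.conv = Conv1d(c_in, c_out, kernel, rng, stride=stride)
        self.bn = BatchNorm1d(c_out)
        self.se = SEBlock(c_out, se_reduction, rng)
        self.residual = stride == 1 and c_in == c_out

    def __call__(self, x: Tensor) -> Tensor:
        y = self.se(self.bn(self.conv(x)).leaky_relu(0.01))
        return y + x if self.residual else y


class LSTMDirection(Module):
    """Single-direction LSTM over (B, T, C) input; returns (B, T, H)."""

    def __init__(self, n_in, hidden, rng):
        super().__init__()
        self.hidden = hidden
        self.wx = Parameter(xavier_uniform(rng, (n_in, 4 * hidden), n_in, 4 * hidden))
        self.wh = Parameter(xavier_uniform(rng, (hidden, 4 * hidden), hidden, 4 * hidden))
        bias = np.zeros(4 * hidden)
        bias[hidden: 2 * hidden] = 1.0  # forget-gate bias
        self.bias = Parameter(bias)

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        batch, steps, _ = x.shape
        h_dim = self.hidden
        pre = x.reshape(batch * steps, x.shape[2]) @ self.wx + self.bias
        pre = pre.reshape(batch, steps, 4 * h_dim)
        h = Tensor(np.zeros((batch, h_dim)))
        c = Tensor(np.zeros((batch, h_dim)))
        order = range(steps - 1, -1, -1) if reverse else range(steps)
        outputs: list[Tensor] = [None] * steps
        for t in order:
            z = pre[:, t, :] + h @ self.wh
            i = z[:, :h_dim].sigmoid()
            f = z[:, h_dim: 2 * h_dim].sigmoid()
            g = z[:, 2 * h_dim: 3 * h_dim].tanh()
            o = z[:, 3 * h_dim:].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outputs[t] = h
        return stack(outputs, axis=1)


class BiLSTM(Module):
    def __init__(self, n_in, hidden, rng):
        super().__init__()
        self.forward_dir = LSTMDirection(n_in, hidden, rng)
        self.backward_dir = LSTMDirection(n_in, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return concat([self.forward_dir(x), self.backward_dir(x, reverse=True)], axis=2)


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention over (B, T, D)."""

    def __init__(self, dim, heads, rng):
        super().__init__()
        if dim % heads:
            raise ValueError(f"attention width {dim} not divisible by {heads} heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.wq = Dense(dim, dim, rng)
        self.wk = Dense(dim, dim, rng)
        self.wv = Dense(dim, dim, rng)
        self.wo = Dense(dim, dim, rng)

    def _split(self, x: Tensor, batch, steps):
        return x.reshape(batch, steps, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        batch, steps, dim = x.shape
        flat = x.reshape(batch * steps, dim)
        q = self._split(self.wq(flat).reshape(batch, steps, dim), batch, steps)
        k = self._split(self.wk(flat).reshape(batch, steps, dim), batch, steps)
        v = self._split(self.wv(flat).reshape(batch, steps, dim), batch, steps)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(batch * steps, dim)
        return self.wo(mixed).reshape(batch, steps, dim)


class CNNBiLSTMAttention(Module):
    """The full regressor: 5 conv blocks -> 3 BiLSTM layers -> multi-head
    self-attention -> mean-pooled dense head.  Input (B, 1, T) -> output (B,)."""

    def __init__(self, arch, rng: np.random.Generator):
        super().__init__()
        self.arch = arch
        self.rng = rng
        blocks = []
        c_in = 1
        for c_out, kernel, stride in zip(arch.channels, arch.kernel_sizes, arch.strides):
            blocks.append(ConvBlock(c_in, c_out, kernel, rng, stride, arch.se_reduction))
            c_in = c_out
        self.conv_blocks = blocks
        lstms = []
        n_in = c_in
        for _ in range(arch.lstm_layers):
            lstms.append(BiLSTM(n_in, arch.lstm_hidden, rng))
            n_in = 2 * arch.lstm_hidden
        self.lstms = lstms
        self.attention = MultiHeadSelfAttention(2 * arch.lstm_hidden, arch.attention_heads, rng)
        self.head1 = Dense(2 * arch.lstm_hidden, arch.head_hidden, rng)
        self.head2 = Dense(arch.head_hidden, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.conv_blocks:
            x = block(x)
        x = x.transpose(0, 2, 1)  # (B, T, C)
        for lstm in self.lstms:
            x = lstm(x)
            x = dropout(x, self.arch.dropout, self.rng, self.training)
        x = self.attention(x)
        pooled = x.mean(axis=1)
        hidden = self.head1(pooled).leaky_relu(0.01)
        hidden = dropout(hidden, self.arch.dropout, self.rng, self.training)
        return self.head2(hidden).reshape(-1)
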