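"""Neural building blocks used by the omics encoders and the fusion block.

Layers follow the conventional shapes: batches lead, time steps second,
features last.  Every layer draws its initial weights from a caller-supplied
``numpy.random.Generator`` so a single seed reproduces the whole model
bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, exp, gather_steps, log, relu, sigmoid, softmax, stack, tanh


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery plus a train/eval flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self, mode: bool = True):
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # checkpoint support -------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float64).copy()


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(glorot(rng, in_dim, out_dim, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm1d(Module):
    """Per-channel normalization over a (B, C, T) activation map.

    Batch statistics in training mode; exponential running estimates
    (momentum 0.1) in inference mode.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_channels)
        self.running_var = np.ones(num_channels)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.mean(axis=(0, 2), keepdims=True)  # (1,C,1)
            var = ((x - mean) ** 2).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
        else:
            mean = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
        xhat = (x - mean) / ((var + Tensor(self.eps)) ** 0.5)
        C = self.gamma.data.shape[0]
        return xhat * self.gamma.reshape(1, C, 1) + self.beta.reshape(1, C, 1)


class LSTM(Module):
    """Single-direction LSTM unrolled over a padded batch (B, T, D)."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        H = hidden_size
        self.hidden_size = H
        self.w_ih = Parameter(glorot(rng, input_size, 4 * H, (input_size, 4 * H)))
        self.w_hh = Parameter(glorot(rng, H, 4 * H, (H, 4 * H)))
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.b = Parameter(b)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        H = self.hidden_size
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outs = []
        xw = x @ self.w_ih  # (B, T, 4H) — hoist the input projection
        for t in range(T):
            gates = xw[:, t, :] + h @ self.w_hh + self.b
            i = sigmoid(gates[:, 0:H])
            f = sigmoid(gates[:, H : 2 * H])
            g = tanh(gates[:, 2 * H : 3 * H])
            o = sigmoid(gates[:, 3 * H : 4 * H])
            c = f * c + i * g
            h = o * tanh(c)
            outs.append(h)
        return stack(outs, axis=1)  # (B, T, H)


class BiLSTM(Module):
    """Bidirectional LSTM over variable-length padded batches.

    The reverse direction runs the same-architecture LSTM on per-sample
    reversed inputs (padding stays trailing), and its outputs are re-aligned
    so that step t of the result concatenates forward(t) and backward(t).
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(input_size, hidden_size, rng)
        self.bwd = LSTM(input_size, hidden_size, rng)

    def __call__(self, x: Tensor, lengths: np.ndarray | None = None) -> Tensor:
        B, T, _ = x.shape
        if lengths is None:
            lengths = np.full(B, T, dtype=int)
        idx = _reversal_index(lengths, T)
        x_rev = Tensor(x.data[np.arange(B)[:, None], idx])  # inputs are constants
        out_f = self.fwd(x)
        out_b_rev = self.bwd(x_rev)
        out_b = gather_steps(out_b_rev, idx)  # re-align to original step order
        return concat([out_f, out_b], axis=-1)


def _reversal_index(lengths: np.ndarray, T: int) -> np.ndarray:
    """idx[b, t] = lengths[b]-1-t inside the valid span, identity beyond it."""
    t = np.arange(T)[None, :]
    L = np.asarray(lengths)[:, None]
    return np.where(t < L, L - 1 - t, t)


class AdditiveAttention(Module):
    """Soft additive attention: score_t = v . tanh(W s_t + b); context = sum w_t s_t."""

    def __init__(self, dim: int, attn_dim: int, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(dim, attn_dim, rng)
        self.v = Parameter(glorot(rng, attn_dim, 1, (attn_dim,)))

    def __call__(self, states: Tensor, mask: np.ndarray | None = None):
        scores = tanh(self.proj(states)) @ self.v  # (B, T)
        weights = softmax(scores, axis=-1, mask=mask)  # masked rows -> all-zero
        context = (states * weights.reshape(*weights.shape, 1)).sum(axis=1)
        return context, weights


class Adam:
    """Adaptive-moment optimizer over a flat parameter list."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def bce_with_logits(scores: Tensor, y01: np.ndarray) -> Tensor:
    """Numerically stable binary cross-entropy on raw scores; y01 in {0,1}."""
    y = Tensor(np.asarray(y01, dtype=np.float64))
    abs_s = relu(scores) + relu(-scores)
    return (relu(scores) - scores * y + log(exp(-abs_s) + Tensor(1.0))).mean()
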