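"""Neural building blocks: embeddings, linear maps, bidirectional LSTMs,
a character-level CNN, dropout and the Adam optimizer.

Layers follow the usual container conventions: a :class:`Module` discovers
its parameters recursively through attributes, and ``state_dict`` /
``load_state_dict`` move raw arrays in and out for checkpointing.  All
randomness (initialization, dropout masks, shuffling) flows through
numpy ``Generator`` objects handed in explicitly, which is what makes the
deterministic-mode contract of the trainers possible.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Parameter, Tensor, concat, logsumexp, stack

__all__ = [
    "Module", "Embedding", "Linear", "BiLSTM", "CharCNN",
    "Adam", "dropout", "cross_entropy",
]


def glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Module:
    """Parameter container with recursive discovery over attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state mismatch on keys: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()


class Embedding(Module):
    """Index → dense vector lookup table. Index 0 is reserved for padding
    and its row is initialized to zero; consumers mask padded positions."""

    def __init__(self, n: int, dim: int, rng: np.random.Generator,
                 padded: bool = True):
        self.weight = Parameter(rng.normal(0.0, 0.1, size=(n, dim)))
        self.padded = padded
        if padded:
            self.weight.data[0] = 0.0

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight.take((np.asarray(idx, dtype=np.intp),))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.W = Parameter(glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class _LSTMCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.Wx = Parameter(glorot(rng, n_in, 4 * n_hidden))
        self.Wh = Parameter(glorot(rng, n_hidden, 4 * n_hidden))
        b = np.zeros(4 * n_hidden)
        b[n_hidden:2 * n_hidden] = 1.0  # forget-gate bias
        self.b = Parameter(b)
        self.n_hidden = n_hidden

    def step(self, x: Tensor, h: Tensor, c: Tensor, mask: np.ndarray):
        H = self.n_hidden
        z = x @ self.Wx + h @ self.Wh + self.b
        i = z[:, 0 * H:1 * H].sigmoid()
        f = z[:, 1 * H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        o = z[:, 3 * H:4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        m = Tensor(mask)  # (B, 1) constant: frozen state on padding steps
        return m * h_new + (1.0 - m) * h, m * c_new + (1.0 - m) * c


class BiLSTM(Module):
    """Bidirectional LSTM over right-padded batches.

    Input ``x`` is (B, T, n_in); ``mask`` is (B, T) with 1 on real tokens.
    Output is (B, T, 2*n_hidden); entries at padded positions are zero-state
    artifacts and must be masked by the consumer.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.fwd = _LSTMCell(n_in, n_hidden, rng)
        self.bwd = _LSTMCell(n_in, n_hidden, rng)
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, T, _ = x.shape
        zero = Tensor(np.zeros((B, self.n_hidden)))
        outs_f, outs_b = [], [None] * T
        h = c = zero
        for t in range(T):
            h, c = self.fwd.step(x[:, t, :], h, c, mask[:, t:t + 1])
            outs_f.append(h)
        h = c = zero
        for t in range(T - 1, -1, -1):
            # padding sits on the right, so masked steps precede real ones
            # here and the state is still the zero initial state
            h, c = self.bwd.step(x[:, t, :], h, c, mask[:, t:t + 1])
            outs_b[t] = h
        fwd = stack(outs_f, axis=1)
        bwd = stack(outs_b, axis=1)
        return concat([fwd, bwd], axis=2)


class CharCNN(Module):
    """Character composition: embed, convolve with width-k filters, max-pool.

    Produces a fixed-length vector per token regardless of word length;
    words shorter than the kernel are implicitly padded (index 0)."""

    def __init__(self, n_chars: int, char_dim: int, n_filters: int,
                 kernel: int, rng: np.random.Generator):
        self.emb = Embedding(n_chars, char_dim, rng)
        self.kernels = [Parameter(glorot(rng, char_dim, n_filters))
                        for _ in range(kernel)]
        self.b = Parameter(np.zeros(n_filters))
        self.kernel = kernel

    def __call__(self, char_idx: np.ndarray) -> Tensor:
        # char_idx: (N, W) int, 0-padded; ensure at least one full window
        N, W = char_idx.shape
        if W < self.kernel:
            pad = np.zeros((N, self.kernel - W), dtype=char_idx.dtype)
            char_idx = np.concatenate([char_idx, pad], axis=1)
            W = self.kernel
        x = self.emb(char_idx)                       # (N, W, d)
        k = self.kernel
        win = x[:, 0:W - k + 1, :] @ self.kernels[0]
        for i in range(1, k):
            win = win + x[:, i:W - k + 1 + i, :] @ self.kernels[i]
        win = (win + self.b).tanh()                  # (N, W-k+1, F)
        return win.max(axis=1)                       # (N, F)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None,
            train: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate is 0."""
    if not train or rate <= 0.0 or rng is None:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.shape) < keep).astype(np.float64) / keep
    return x * Tensor(mask)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer `labels` under row softmax."""
    n = logits.shape[0]
    log_z = logsumexp(logits, axis=1)
    gold = logits.take((np.arange(n), np.asarray(labels, dtype=np.intp)))
    return (log_z - gold).mean()


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip: float = 5.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps, self.clip = lr, *betas, eps, clip
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        # global gradient-norm clipping stabilizes the recurrent layers
        if self.clip:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in self.params if p.grad is not None))
            scale = self.clip / total if total > self.clip else 1.0
        else:
            scale = 1.0
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
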