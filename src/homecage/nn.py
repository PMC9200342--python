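"""A compact, seeded neural-network engine on numpy.

Implements exactly the layer vocabulary the classifiers in this package
need — Dense, Conv1D/Conv2D (stride 1, 'same' padding, odd kernels),
BatchNorm, ReLU, MaxPool (pool 2), LSTM, Dropout, Flatten — with manual
reverse-mode gradients, an Adam optimiser and a class-weighted sparse
categorical cross-entropy loss with L2 kernel regularisation.

Design constraints:
* every source of randomness (initialisation, shuffling, dropout) flows from
  one integer seed, so builds and training runs are reproducible;
* gradients are exact (they are verified against central finite differences
  in the test suite);
* batch operations are expressed as matrix products (im2col) so desk-scale
  training stays fast without any compiled extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class TrainingError(RuntimeError):
    """Raised when optimisation diverges (non-finite loss)."""


#: dtype of parameters and activations. float32 keeps desk-scale training
#: fast; tests that verify gradients against finite differences switch to
#: float64 via :func:`set_default_dtype`.
_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def default_dtype():
    return _DTYPE


@dataclass
class Param:
    """A trainable tensor with its gradient accumulator."""

    value: np.ndarray
    grad: np.ndarray = field(init=False)
    l2: float = 0.0  # coefficient of the lambda*||w||^2 penalty (0 = unregularised)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


class Layer:
    """Base class: forward caches whatever backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, l2: float = 0.0):
        self.w = Param(_glorot(rng, (n_in, n_out), n_in, n_out), l2=l2)
        self.b = Param(np.zeros(n_out, dtype=_DTYPE))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)).astype(x.dtype)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Normalises over all axes except the last (feature/channel) axis."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features, dtype=_DTYPE))
        self.beta = Param(np.zeros(n_features, dtype=_DTYPE))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_features, dtype=_DTYPE)
        self.running_var = np.ones(n_features, dtype=_DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._training = training
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        dgamma = (grad * self._xhat).sum(axis=self._axes)
        dbeta = grad.sum(axis=self._axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        if not self._training:
            return grad * self.gamma.value / self._std
        return (self.gamma.value / self._std) * (
            grad - dbeta / self._m - self._xhat * dgamma / self._m
        )


class Conv1D(Layer):
    """1-D convolution, stride 1, 'same' padding, odd kernel size."""

    def __init__(self, n_in: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, l2: float = 0.0):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        fan_in, fan_out = kernel_size * n_in, kernel_size * filters
        self.w = Param(_glorot(rng, (kernel_size, n_in, filters), fan_in, fan_out), l2=l2)
        self.b = Param(np.zeros(filters, dtype=_DTYPE))
        self.k = kernel_size

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        b, length, _ = x.shape
        if length < self.k:
            raise ValueError(f"input length {length} < kernel size {self.k}")
        p = (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        cols = sliding_window_view(xp, self.k, axis=1)  # (B, L, Cin, k)
        self._cols = cols.transpose(0, 1, 3, 2).reshape(b * length, -1)  # (B*L, k*Cin)
        wf = self.w.value.reshape(-1, self.w.value.shape[-1])
        out = self._cols @ wf + self.b.value
        return out.reshape(b, length, -1)

    def backward(self, grad):
        b, length, filters = grad.shape
        gf = grad.reshape(b * length, filters)
        self.w.grad += (self._cols.T @ gf).reshape(self.w.value.shape)
        self.b.grad += gf.sum(axis=0)
        # dX is a 'same' correlation of the gradient with the rotated kernel
        p = (self.k - 1) // 2
        gp = np.pad(grad, ((0, 0), (p, p), (0, 0)))
        gcols = sliding_window_view(gp, self.k, axis=1).transpose(0, 1, 3, 2)
        gcols = gcols.reshape(b * length, -1)  # (B*L, k*F)
        wrot = self.w.value[::-1].transpose(0, 2, 1).reshape(-1, self.w.value.shape[1])
        return (gcols @ wrot).reshape(b, length, -1)


class Conv2D(Layer):
    """2-D convolution, stride 1, 'same' padding, odd kernel sizes."""

    def __init__(self, n_in: int, filters: int, kernel_size: tuple[int, int],
                 rng: np.random.Generator, l2: float = 0.0):
        kh, kw = kernel_size
        if kh % 2 != 1 or kw % 2 != 1:
            raise ValueError("kernel sizes must be odd for 'same' padding")
        fan_in, fan_out = kh * kw * n_in, kh * kw * filters
        self.w = Param(_glorot(rng, (kh, kw, n_in, filters), fan_in, fan_out), l2=l2)
        self.b = Param(np.zeros(filters, dtype=_DTYPE))
        self.kh, self.kw = kh, kw

    def params(self):
        return [self.w, self.b]

    def forward(self, x, training):
        b, h, w, _ = x.shape
        if h < self.kh or w < self.kw:
            raise ValueError("input smaller than kernel")
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        cols = sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))  # (B,H,W,C,kh,kw)
        self._cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, -1)  # (BHW, kh*kw*C)
        wf = self.w.value.reshape(-1, self.w.value.shape[-1])
        out = self._cols @ wf + self.b.value
        return out.reshape(b, h, w, -1)

    def backward(self, grad):
        b, h, w, filters = grad.shape
        gf = grad.reshape(b * h * w, filters)
        self.w.grad += (self._cols.T @ gf).reshape(self.w.value.shape)
        self.b.grad += gf.sum(axis=0)
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        gp = np.pad(grad, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        gcols = sliding_window_view(gp, (self.kh, self.kw), axis=(1, 2))
        gcols = gcols.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, -1)  # (BHW, kh*kw*F)
        wrot = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2).reshape(-1, self.w.value.shape[2])
        return (gcols @ wrot).reshape(b, h, w, -1)


class MaxPool1D(Layer):
    """Non-overlapping max pooling (pool 2, stride 2); odd tails are dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training):
        b, length, c = x.shape
        l2 = length // self.pool
        self._in_shape = x.shape
        xr = x[:, : l2 * self.pool].reshape(b, l2, self.pool, c)
        self._idx = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        b, l2, c = grad.shape
        onehot = (
            np.arange(self.pool)[None, None, :, None] == self._idx[:, :, None, :]
        )
        dxr = grad[:, :, None, :] * onehot
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : l2 * self.pool] = dxr.reshape(b, l2 * self.pool, c)
        return dx


class MaxPool2D(Layer):
    """Non-overlapping 2x2 max pooling."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, training):
        p = self.pool
        b, h, w, c = x.shape
        h2, w2 = h // p, w // p
        self._in_shape = x.shape
        xr = (
            x[:, : h2 * p, : w2 * p]
            .reshape(b, h2, p, w2, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h2, w2, p * p, c)
        )
        self._idx = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, grad):
        p = self.pool
        b, h2, w2, c = grad.shape
        onehot = (
            np.arange(p * p)[None, None, None, :, None] == self._idx[:, :, :, None, :]
        )
        dxr = grad[:, :, :, None, :] * onehot
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : h2 * p, : w2 * p] = (
            dxr.reshape(b, h2, w2, p, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h2 * p, w2 * p, c)
        )
        return dx


class LSTM(Layer):
    """Single LSTM layer returning the last hidden state.

    Gate order (i, f, g, o); forget-gate bias initialised to 1.
    """

    def __init__(self, n_in: int, units: int, rng: np.random.Generator, l2: float = 0.0):
        self.units = units
        self.w = Param(_glorot(rng, (n_in, 4 * units), n_in, 4 * units), l2=l2)
        self.u = Param(_glorot(rng, (units, 4 * units), units, 4 * units), l2=l2)
        b = np.zeros(4 * units, dtype=_DTYPE)
        b[units : 2 * units] = 1.0
        self.b = Param(b)

    def params(self):
        return [self.w, self.u, self.b]

    def forward(self, x, training):
        b, t_steps, _ = x.shape
        u = self.units
        h = np.zeros((b, u), dtype=x.dtype)
        c = np.zeros((b, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        sig = lambda z: 1.0 / (1.0 + np.exp(-z))
        for t in range(t_steps):
            z = x[:, t] @ self.w.value + h @ self.u.value + self.b.value
            i, f = sig(z[:, :u]), sig(z[:, u : 2 * u])
            g, o = np.tanh(z[:, 2 * u : 3 * u]), sig(z[:, 3 * u :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            self._cache.append((i, f, g, o, c, c_prev, h_prev))
        return h

    def backward(self, grad):
        b, t_steps, n_in = self._x.shape
        u = self.units
        dh, dc = grad, np.zeros((b, u), dtype=grad.dtype)
        dx = np.zeros((b, t_steps, n_in), dtype=grad.dtype)
        for t in range(t_steps - 1, -1, -1):
            i, f, g, o, c, c_prev, h_prev = self._cache[t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.w.grad += self._x[:, t].T @ dz
            self.u.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.w.value.T
            dh = dz @ self.u.value.T
            dc = dc * f
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class DualBranchNet:
    """Two input branches whose outputs are concatenated into one head."""

    def __init__(self, branch_a: Sequential, branch_b: Sequential, head: Sequential):
        self.branch_a = branch_a
        self.branch_b = branch_b
        self.head = head

    def params(self):
        return self.branch_a.params() + self.branch_b.params() + self.head.params()

    def forward(self, inputs: tuple[np.ndarray, np.ndarray], training: bool):
        fa = self.branch_a.forward(inputs[0], training)
        fb = self.branch_b.forward(inputs[1], training)
        self._split = fa.shape[1]
        return self.head.forward(np.concatenate([fa, fb], axis=1), training)

    def backward(self, grad):
        g = self.head.backward(grad)
        ga = self.branch_a.backward(g[:, : self._split])
        gb = self.branch_b.backward(g[:, self._split :])
        return ga, gb


# ---------------------------------------------------------------------------
# Loss, optimiser, training loop
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_sparse_ce(
    logits: np.ndarray,
    labels: np.ndarray,
    sample_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Class/sample-weighted sparse categorical cross-entropy.

    Returns the weighted-mean loss and the gradient w.r.t. the logits.
    """
    n = logits.shape[0]
    p = softmax(logits)
    if sample_weights is None:
        sample_weights = np.ones(n)
    wsum = sample_weights.sum()
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    loss = float(-(sample_weights * logp).sum() / wsum)
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    grad *= (sample_weights / wsum)[:, None]
    return loss, grad


def l2_penalty(params: list[Param], accumulate_grad: bool = True) -> float:
    """Add lambda * ||w||^2 penalties; optionally accumulate their gradients."""
    total = 0.0
    for p in params:
        if p.l2 > 0.0:
            total += p.l2 * float((p.value**2).sum())
            if accumulate_grad:
                p.grad += 2.0 * p.l2 * p.value
    return total


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def _take(inputs, idx):
    if isinstance(inputs, tuple):
        return tuple(x[idx] for x in inputs)
    return inputs[idx]


def _cast(inputs):
    if isinstance(inputs, tuple):
        return tuple(np.asarray(x, dtype=_DTYPE) for x in inputs)
    return np.asarray(inputs, dtype=_DTYPE)


def n_samples(inputs) -> int:
    return (inputs[0] if isinstance(inputs, tuple) else inputs).shape[0]


def train(
    net,
    inputs,
    labels: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
    class_weight: dict[int, float] | None = None,
) -> list[float]:
    """Minibatch Adam training; returns the per-epoch mean training loss."""
    labels = np.asarray(labels, dtype=int)
    inputs = _cast(inputs)
    n = n_samples(inputs)
    weights = np.ones(n)
    if class_weight:
        for c, w in class_weight.items():
            weights[labels == c] = w
    params = net.params()
    opt = Adam(params, lr=lr)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            logits = net.forward(_take(inputs, idx), training=True)
            loss, dlogits = weighted_sparse_ce(logits, labels[idx], weights[idx])
            loss += l2_penalty(params)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch + 1}; "
                    "check learning rate / input scaling"
                )
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return history


def predict_proba(net, inputs, batch_size: int = 256) -> np.ndarray:
    """Row-stochastic class probabilities in inference mode."""
    inputs = _cast(inputs)
    n = n_samples(inputs)
    out = []
    for start in range(0, n, batch_size):
        idx = np.arange(start, min(start + batch_size, n))
        out.append(softmax(net.forward(_take(inputs, idx), training=False)))
    return np.vstack(out)
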