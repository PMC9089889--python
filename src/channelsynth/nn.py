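"""Minimal numpy neural-network layers with hand-derived backpropagation.

Just enough machinery for a 1-D deep-convolutional GAN over 2 x W signal
"images": dense, strided convolution, transposed (fractionally strided)
convolution, batch normalisation, LeakyReLU/tanh, inverted dropout and an
Adam optimiser.  Everything is seeded through numpy Generators, so whole
training runs are bit-reproducible on CPU.

Convolutions treat the signal as 1-D with channels (the two rows of a
window are input channels), which is equivalent to the 2-D formulation
with a kernel spanning both rows.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Dense", "Conv1d", "ConvTranspose1d", "BatchNorm",
    "LeakyReLU", "Tanh", "Dropout", "Reshape", "Flatten", "Sequential", "Adam",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, w_sd: float = 0.02):
        self.W = Param(rng.normal(0.0, w_sd, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def forward(self, x, training):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class Conv1d(Layer):
    """Strided 1-D convolution (cross-correlation), 'same'-family padding."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, pad: int = 1, w_sd: float = 0.02):
        self.k, self.s, self.p = kernel, stride, pad
        self.W = Param(rng.normal(0.0, w_sd, size=(c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))

    def out_length(self, L: int) -> int:
        return (L + 2 * self.p - self.k) // self.s + 1

    def forward(self, x, training):
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p)))
        Lout = self.out_length(L)
        out = np.zeros((B, self.W.value.shape[0], Lout))
        for t in range(self.k):
            xs = xp[:, :, t : t + self.s * Lout : self.s]
            out += np.matmul(self.W.value[:, :, t], xs[:, :, :Lout])
        out += self.b.value[None, :, None]
        self._xp, self._Lout, self._shape = xp, Lout, x.shape
        return out

    def backward(self, grad):
        B, C, L = self._shape
        Lout = self._Lout
        dxp = np.zeros_like(self._xp)
        gT = np.ascontiguousarray(grad.transpose(1, 0, 2)).reshape(grad.shape[1], -1)
        for t in range(self.k):
            xs = self._xp[:, :, t : t + self.s * Lout : self.s][:, :, :Lout]
            xsT = np.ascontiguousarray(xs.transpose(1, 0, 2)).reshape(xs.shape[1], -1)
            self.W.grad[:, :, t] += gT @ xsT.T
            sl = dxp[:, :, t : t + self.s * Lout : self.s]
            sl[:, :, :Lout] += np.matmul(self.W.value[:, :, t].T, grad)
        self.b.grad += grad.sum(axis=(0, 2))
        if self.p:
            return dxp[:, :, self.p : -self.p]
        return dxp

    def params(self):
        return [self.W, self.b]


class ConvTranspose1d(Layer):
    """Fractionally strided convolution: the upsampling stage of the generator."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 4, stride: int = 2, pad: int = 1, w_sd: float = 0.02):
        self.k, self.s, self.p = kernel, stride, pad
        self.W = Param(rng.normal(0.0, w_sd, size=(c_in, c_out, kernel)))
        self.b = Param(np.zeros(c_out))

    def out_length(self, L: int) -> int:
        return (L - 1) * self.s + self.k - 2 * self.p

    def forward(self, x, training):
        B, C, L = x.shape
        c_out = self.W.value.shape[1]
        full = (L - 1) * self.s + self.k
        buf = np.zeros((B, c_out, full))
        for t in range(self.k):
            buf[:, :, t : t + self.s * L : self.s] += np.matmul(
                self.W.value[:, :, t].T, x
            )
        out = buf[:, :, self.p : full - self.p] + self.b.value[None, :, None]
        self._x, self._full = x, full
        return out

    def backward(self, grad):
        B, C, L = self._x.shape
        dbuf = np.zeros((B, grad.shape[1], self._full))
        dbuf[:, :, self.p : self._full - self.p] = grad
        dx = np.zeros_like(self._x)
        xT = np.ascontiguousarray(self._x.transpose(1, 0, 2)).reshape(C, -1)
        for t in range(self.k):
            seg = dbuf[:, :, t : t + self.s * L : self.s]
            segT = np.ascontiguousarray(seg.transpose(1, 0, 2)).reshape(seg.shape[1], -1)
            self.W.grad[:, :, t] += xT @ segT.T
            dx += np.matmul(self.W.value[:, :, t], seg)
        self.b.grad += grad.sum(axis=(0, 2))
        return dx

    def params(self):
        return [self.W, self.b]


class BatchNorm(Layer):
    """Batch normalisation over the batch (and length, for conv maps)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(n_features)
        self.run_var = np.ones(n_features)

    def _axes_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        return (0, 2), (1, -1, 1)

    def forward(self, x, training):
        axes, shape = self._axes_shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) / std.reshape(shape)
        self._xhat, self._std, self._axes, self._bshape = xhat, std, axes, shape
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, grad):
        axes, shape = self._axes, self._bshape
        xhat, std = self._xhat, self._std
        m = np.prod([grad.shape[a] for a in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value.reshape(shape)
        s1 = dxhat.sum(axis=axes).reshape(shape)
        s2 = (dxhat * xhat).sum(axis=axes).reshape(shape)
        return (dxhat - s1 / m - xhat * s2 / m) / std.reshape(shape)

    def params(self):
        return [self.gamma, self.beta]


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, training):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Tanh(Layer):
    def forward(self, x, training):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Dropout(Layer):
    """Inverted dropout; a no-op outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape  # per-sample shape

    def forward(self, x, training):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class Flatten(Layer):
    def forward(self, x, training):
        self._in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))


class Adam:
    """Adam with bias correction; state is serialisable for resuming."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)

    def state(self) -> dict:
        return {"m": self.m, "v": self.v, "t": self.t}

    def load_state(self, state: dict) -> None:
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]
        self.t = int(state["t"])
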