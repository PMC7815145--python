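"""Minimal feed-forward / convolutional network engine on numpy.

Supports exactly what the classifiers here need: stride-1 "same"
convolutions with odd kernels (im2col + BLAS matmul), 3x3/stride-2 max
pooling with ceil-mode output (H -> ceil(H/2)), inverted dropout, batch
normalization, dense layers, ReLU/tanh, a softmax + class-weighted
categorical cross-entropy head, and Adam or plain gradient descent.
Everything is float32 and deterministic given the generator passed in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "Dropout",
    "BatchNorm",
    "ReLU",
    "Tanh",
    "Network",
    "Adam",
    "GradientDescent",
    "softmax",
]


def uniform_init(
    rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int
) -> np.ndarray:
    """Scaled-uniform weight init, limit sqrt(6 / (fan_in + fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.w = uniform_init(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


def _conv_same(x: np.ndarray, w: np.ndarray):
    """Stride-1 same-padding correlation; x (N,H,W,Cin), w (kh,kw,Cin,Cout).

    Returns (out, cols) where cols is the (N*H*W, kh*kw*Cin) patch matrix.
    """
    kh, kw, cin, cout = w.shape
    n, h, wd, _ = x.shape
    xp = np.pad(x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2), (0, 0)))
    cols = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # (N,H,W,C,kh,kw)
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
    cols = cols.reshape(n * h * wd, kh * kw * cin)
    out = cols @ w.reshape(kh * kw * cin, cout)
    return out.reshape(n, h, wd, cout), cols


class Conv2D(Layer):
    """Odd-kernel, stride-1, same-padding convolutional layer.

    ``input_grad=False`` (for the first layer of a network) skips the
    gradient with respect to the input, which no earlier layer consumes.
    """

    input_grad: bool = True

    def __init__(
        self, kernel: tuple[int, int], c_in: int, c_out: int,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        kh, kw = kernel
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("kernels must be odd-sized")
        fan_in = kh * kw * c_in
        fan_out = kh * kw * c_out
        self.w = uniform_init(rng, (kh, kw, c_in, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train):
        out, cols = _conv_same(x, self.w)
        self._cols = cols
        self._n = x.shape[0]
        return out + self.b

    def backward(self, dout):
        kh, kw, cin, cout = self.w.shape
        dflat = dout.reshape(-1, cout)
        self.grads[0][...] = (self._cols.T @ dflat).reshape(self.w.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        self._cols = None
        if not self.input_grad:
            return None
        # gradient w.r.t. input = same-conv of dout with the flipped kernel
        w_flip = self.w[::-1, ::-1].transpose(0, 1, 3, 2)
        dx, _ = _conv_same(dout, np.ascontiguousarray(w_flip))
        return dx


class MaxPool2D(Layer):
    """3x3 window, stride 2, tail-padded with -inf so H -> ceil(H/2)."""

    def __init__(self, pool: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.pool = pool
        self.stride = stride

    def forward(self, x, train):
        p, s = self.pool, self.stride
        n, h, w, c = x.shape
        oh = -(-h // s)
        ow = -(-w // s)
        ph = (oh - 1) * s + p - h
        pw = (ow - 1) * s + p - w
        xp = np.pad(
            x, ((0, 0), (0, ph), (0, pw), (0, 0)),
            constant_values=-np.inf,
        )
        # running max over the p*p window offsets (cheaper than gathering
        # all windows at once)
        best = np.full((n, oh, ow, c), -np.inf, dtype=x.dtype)
        arg = np.zeros((n, oh, ow, c), dtype=np.int8)
        for a in range(p):
            for b in range(p):
                cand = xp[:, a : a + oh * s : s, b : b + ow * s : s, :]
                mask = cand > best
                np.copyto(best, cand, where=mask)
                arg[mask] = a * p + b
        self._arg = arg
        self._xshape = x.shape
        self._pshape = xp.shape
        return best

    def backward(self, dout):
        p, s = self.pool, self.stride
        n, oh, ow, c = dout.shape
        dy, dx_off = np.divmod(self._arg, p)
        ii = np.arange(oh)[None, :, None, None] * s + dy
        jj = np.arange(ow)[None, None, :, None] * s + dx_off
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, None, None, :]
        dxp = np.zeros(self._pshape, dtype=dout.dtype)
        np.add.at(dxp, (nn, ii, jj, cc), dout)
        h, w = self._xshape[1:3]
        return dxp[:, :h, :w, :]


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (
            self.rng.random(x.shape) < keep
        ).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class BatchNorm(Layer):
    """Batch normalization over feature vectors (N, D)."""

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(dim, dtype=np.float32)
        self.beta = np.zeros(dim, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim, dtype=np.float32)
        self.running_var = np.ones(dim, dtype=np.float32)

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        self.grads[0][...] = (dout * self._xhat).sum(axis=0)
        self.grads[1][...] = dout.sum(axis=0)
        dxhat = dout * self.gamma
        return (
            dxhat
            - dxhat.mean(axis=0)
            - self._xhat * (dxhat * self._xhat).mean(axis=0)
        ) / self._std


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Tanh(Layer):
    def forward(self, x, train):
        self._out = np.tanh(x)
        return self._out

    def backward(self, dout):
        return dout * (1.0 - self._out**2)


class Adam:
    def __init__(
        self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class GradientDescent:
    def __init__(self, lr: float) -> None:
        self.lr = lr

    def step(self, params, grads) -> None:
        for p, g in zip(params, grads):
            p -= self.lr * g


class Network:
    """A sequential network ending in logits (softmax lives in the loss)."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.vstack(out)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        epochs: int,
        batch_size: int,
        optimizer,
        rng: np.random.Generator,
        class_weight: np.ndarray | None = None,
        shuffle: bool = True,
    ) -> list[float]:
        """Train with softmax + class-weighted categorical cross-entropy.

        ``y`` holds integer class indices; ``class_weight`` (if given) is
        one positive weight per class index.  Returns per-epoch mean loss.
        Raises ``RuntimeError`` if the loss turns non-finite.
        """
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y)
        n = x.shape[0]
        history: list[float] = []
        for epoch in range(epochs):
            order = rng.permutation(n) if shuffle else np.arange(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                xb, yb = x[idx], y[idx]
                logits = self.forward(xb, train=True)
                probs = softmax(logits)
                w = (
                    class_weight[yb]
                    if class_weight is not None
                    else np.ones(yb.size)
                ).astype(np.float32)
                eps = 1e-12
                nll = -np.log(probs[np.arange(yb.size), yb] + eps)
                loss = float(np.mean(w * nll))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {i // batch_size}"
                    )
                onehot = np.zeros_like(probs)
                onehot[np.arange(yb.size), yb] = 1.0
                dlogits = w[:, None] * (probs - onehot) / yb.size
                self.backward(dlogits.astype(np.float32))
                optimizer.step(self.params, self.grads)
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history
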