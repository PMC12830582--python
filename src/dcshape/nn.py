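"""Minimal CPU neural-network stack used by the event classifier.

Implements exactly what the classifier needs — strided 3x3/7x7
convolutions (im2col), batch normalisation, ReLU, dropout, dense
layers, residual blocks, the Adam optimiser and weighted softmax
cross-entropy — in plain numpy with explicit backward passes.  Training
is fully deterministic given the seed, which keeps pipeline runs
reproducible bit-for-bit.

Tensors are (N, C, H, W) float64 throughout; gradients are exact
(verified against finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: params/grads lists are aligned pairs."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def set_rng(self, rng: np.random.Generator) -> None:
        pass


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols, xshape, k, stride, pad, oh, ow):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    dx = np.zeros((n, c, hp, wp))
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * oh:stride,
               j:j + stride * ow:stride] += d[:, :, :, :, i, j]
    if pad:
        dx = dx[:, :, pad:hp - pad, pad:wp - pad]
    return dx


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.b = np.zeros(cout)
        self.k, self.stride, self.pad = k, stride, pad
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._xshape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self._cols, self._oh, self._ow = cols, oh, ow
        out = cols @ self.W.T + self.b
        n = x.shape[0]
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, cout, oh, ow = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.dW[...] = dflat.T @ self._cols
        self.db[...] = dflat.sum(axis=0)
        dcols = dflat @ self.W
        return _col2im(dcols, self._xshape, self.k, self.stride, self.pad,
                       self._oh, self._ow)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)[None, :, None, None]
        self._xhat = (x - mean[None, :, None, None]) / self._std
        self._train = train
        return self.gamma[None, :, None, None] * self._xhat \
            + self.beta[None, :, None, None]

    def backward(self, dout):
        self.dgamma[...] = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        if not self._train:
            return dxhat / self._std
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        return (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
                - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3),
                                                         keepdims=True)
                ) / self._std


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def set_rng(self, rng):
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / nin), size=(nout, nin))
        self.b = np.zeros(nout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W


class ResidualBlock(Layer):
    """conv-bn-relu-conv-bn with identity (or 1x1 projection) skip."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(cout)
        self.proj: tuple[Conv2d, BatchNorm2d] | None = None
        if stride != 1 or cin != cout:
            self.proj = (Conv2d(cin, cout, 1, stride, 0, rng),
                         BatchNorm2d(cout))
        self.relu_out = ReLU()

    def _sublayers(self):
        layers = [self.conv1, self.bn1, self.conv2, self.bn2]
        if self.proj is not None:
            layers.extend(self.proj)
        return layers

    def params(self):
        return [p for l in self._sublayers() for p in l.params()]

    def grads(self):
        return [g for l in self._sublayers() for g in l.grads()]

    def forward(self, x, train):
        out = self.conv1.forward(x, train)
        out = self.bn1.forward(out, train)
        out = self.relu1.forward(out, train)
        out = self.conv2.forward(out, train)
        out = self.bn2.forward(out, train)
        if self.proj is not None:
            skip = self.proj[1].forward(self.proj[0].forward(x, train), train)
        else:
            skip = x
        return self.relu_out.forward(out + skip, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dmain = self.bn2.backward(d)
        dmain = self.conv2.backward(dmain)
        dmain = self.relu1.backward(dmain)
        dmain = self.bn1.backward(dmain)
        dmain = self.conv1.backward(dmain)
        if self.proj is not None:
            dskip = self.proj[0].backward(self.proj[1].backward(d))
        else:
            dskip = d
        return dmain + dskip


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def set_rng(self, rng):
        for l in self.layers:
            l.set_rng(rng)

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout

    # weight (de)serialisation -------------------------------------------
    def state(self) -> list[np.ndarray]:
        extra = []
        for l in self._all_layers():
            if isinstance(l, BatchNorm2d):
                extra.extend([l.running_mean, l.running_var])
        return [p.copy() for p in self.params()] + [e.copy() for e in extra]

    def load_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, s in zip(ps, state[:len(ps)]):
            p[...] = s
        extra = state[len(ps):]
        i = 0
        for l in self._all_layers():
            if isinstance(l, BatchNorm2d):
                l.running_mean[...] = extra[i]
                l.running_var[...] = extra[i + 1]
                i += 2

    def _all_layers(self):
        out = []
        for l in self.layers:
            if isinstance(l, ResidualBlock):
                out.extend([l.conv1, l.bn1, l.conv2, l.bn2])
                if l.proj is not None:
                    out.extend(l.proj)
            else:
                out.append(l)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))


class Adam:
    """Adam optimiser over a parameter/gradient list."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(logits: np.ndarray, labels: np.ndarray,
                           class_weights: np.ndarray | None = None
                           ) -> tuple[float, np.ndarray]:
    """Weighted softmax cross-entropy; returns (loss, dlogits).

    Per-sample weights are the class weight of the true label; the loss
    is the weighted mean (normalised by the summed weights, the usual
    convention), so its gradient stays well-scaled under imbalance.
    """
    n, k = logits.shape
    p = softmax(logits)
    w = np.ones(n) if class_weights is None else np.asarray(class_weights)[labels]
    wsum = w.sum()
    logp = np.log(np.clip(p[np.arange(n), labels], 1e-12, None))
    loss = float(-(w * logp).sum() / wsum)
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits
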