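"""Layers and optimizers for the node classifier.

All randomness (initialization, dropout masks) flows through the
``np.random.Generator`` handed to each layer; there is no global RNG state,
so a fixed seed reproduces training bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: parameter collection and train/eval mode."""

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

    def set_training(self, flag: bool):
        self.training = flag
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.set_training(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.set_training(flag)
        return self


def _activation(name: str):
    name = name.lower()
    if name == "elu":
        return lambda x: x.elu()
    if name == "relu":
        return lambda x: x.relu()
    if name == "tanh":
        return lambda x: x.tanh()
    raise ValueError(f"unknown activation {name!r}")


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str | None = None, bias: bool = True):
        super().__init__()
        # Glorot-uniform initialization
        limit = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Parameter(rng.uniform(-limit, limit, size=(in_dim, out_dim)))
        self.b = Parameter(np.zeros(out_dim)) if bias else None
        self._act = _activation(activation) if activation else None

    def parameters(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        if self.b is not None:
            out = out + self.b
        return self._act(out) if self._act else out


class BatchNorm(Module):
    """Feature-wise batch normalization with running statistics.

    Training mode normalizes by the statistics of the current forward pass
    (over all rows seen, i.e. all graph nodes in transductive use);
    inference mode uses the exponential running estimates.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered ** 2.0).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = centered * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.uniform(size=x.shape) < keep) / keep
        return x * mask


class DepthwiseConvLSTM(Module):
    """Convolutional-recurrent combiner for skip connections.

    Runs a depthwise (kernel-size-1 convolutional, i.e. per-feature) LSTM
    cell over the length-2 sequence [skip, transformed]; the final hidden
    state is the combined embedding.  Gate weights are per-feature vectors.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        scale = 0.5
        self.wx = Parameter(rng.uniform(-scale, scale, size=(4, dim)))
        self.wh = Parameter(rng.uniform(-scale, scale, size=(4, dim)))
        self.bias = Parameter(np.zeros((4, dim)))
        # forget-gate bias starts at 1 so both sequence steps contribute early
        self.bias.data[1] = 1.0

    def _step(self, x: Tensor, h: Tensor | None, c: Tensor | None):
        def gate(k, act):
            z = x * self.wx[k] + self.bias[k]
            if h is not None:
                z = z + h * self.wh[k]
            return act(z)

        i = gate(0, lambda t: t.sigmoid())
        f = gate(1, lambda t: t.sigmoid())
        g = gate(2, lambda t: t.tanh())
        o = gate(3, lambda t: t.sigmoid())
        c_new = g * i if c is None else f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def __call__(self, skip: Tensor, transformed: Tensor) -> Tensor:
        h, c = self._step(skip, None, None)
        h, _ = self._step(transformed, h, c)
        return h


class FFNBlock(Module):
    """Batch-norm -> dropout -> two dense+ELU layers, with a skip connection.

    The block input is combined with the transformed path either through the
    convolutional-recurrent cell (default) or by concatenation.  When the
    input width differs from the block width the skip path is linearly
    projected so the combination is well-defined.
    """

    def __init__(self, in_dim: int, hidden_units: tuple[int, int],
                 rng: np.random.Generator, dropout: float = 0.2,
                 activation: str = "elu", combination: str = "conv_recurrent"):
        super().__init__()
        h1, h2 = hidden_units
        self.bn = BatchNorm(in_dim)
        self.drop = Dropout(dropout, rng)
        self.fc1 = Dense(in_dim, h1, rng, activation=activation)
        self.fc2 = Dense(h1, h2, rng, activation=activation)
        self.proj = Dense(in_dim, h2, rng) if in_dim != h2 else None
        if combination == "conv_recurrent":
            self.combiner = DepthwiseConvLSTM(h2, rng)
        elif combination == "concat":
            self.combiner = None
        else:
            raise ValueError(f"unknown combination {combination!r}")
        self.combination = combination
        self.out_dim = h2 if combination == "conv_recurrent" else 2 * h2

    def __call__(self, x: Tensor) -> Tensor:
        out = self.fc2(self.fc1(self.drop(self.bn(x))))
        skip = self.proj(x) if self.proj is not None else x
        if self.combiner is not None:
            return self.combiner(skip, out)
        return concat([skip, out], axis=-1)


class GCNLayer(Module):
    """One message-passing step.

    h_u' = sigma(W_n h_u + W_nei * aggregate_{v in N(u)} h_v + b), followed
    by row L2 normalization of the updated embeddings.  Aggregation is the
    degree-normalized neighbor mean by default ("mean"), or the raw sum
    ("sum"); isolated nodes contribute a zero neighbor term either way.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str = "elu", aggregation: str = "mean",
                 normalize: bool = True):
        super().__init__()
        if aggregation not in ("mean", "sum"):
            raise ValueError(f"unknown aggregation {aggregation!r}")
        self.W_self = Dense(in_dim, out_dim, rng)
        self.W_nei = Dense(in_dim, out_dim, rng, bias=False)  # single bias b via W_self
        self.aggregation = aggregation
        self.normalize = normalize
        self._act = _activation(activation)

    @staticmethod
    def _check_adjacency(A: np.ndarray):
        from scipy import sparse
        if sparse.issparse(A):
            if (abs(A - A.T)).nnz != 0:
                raise ValueError("adjacency must be symmetric")
            return
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")

    def aggregate(self, h: Tensor, A) -> Tensor:
        from scipy import sparse
        if sparse.issparse(A):
            A = np.asarray(A.todense())
        Aop = np.asarray(A, dtype=float)
        if self.aggregation == "mean":
            deg = Aop.sum(axis=1, keepdims=True)
            Aop = Aop / np.maximum(deg, 1.0)
        return Tensor(Aop) @ h

    def __call__(self, h: Tensor, A) -> Tensor:
        self._check_adjacency(A)
        m = self.aggregate(h, A)
        out = self._act(self.W_self(h) + self.W_nei(m))
        if self.normalize:
            norm = ((out ** 2.0).sum(axis=-1, keepdims=True) + 1e-12) ** -0.5
            out = out * norm
        return out


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class Optimizer:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = lr
        self.t = 0

    def step(self):
        self.t += 1
        for p in self.params:
            if p.grad is not None:
                self._update(p)

    def _update(self, p):  # pragma: no cover - abstract
        raise NotImplementedError


class SGD(Optimizer):
    def _update(self, p):
        p.data -= self.lr * p.grad


class Adam(Optimizer):
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * self._direction(i, g, mhat, vhat)

    def _direction(self, i, g, mhat, vhat):
        return mhat / (np.sqrt(vhat) + self.eps)


class Nadam(Adam):
    """Adam with Nesterov momentum (Dozat's formulation)."""

    def _direction(self, i, g, mhat, vhat):
        nesterov = (self.b1 * mhat
                    + (1 - self.b1) * g / (1 - self.b1**self.t))
        return nesterov / (np.sqrt(vhat) + self.eps)


class Adamax(Adam):
    def __init__(self, params, lr=0.002, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr, beta1, beta2, eps)
        self.u = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.u[i] = np.maximum(self.b2 * self.u[i], np.abs(g))
            mhat = self.m[i] / (1 - self.b1**self.t)
            p.data -= self.lr * mhat / (self.u[i] + self.eps)


OPTIMIZERS = {"sgd": SGD, "adam": Adam, "adamax": Adamax, "nadam": Nadam}


def make_optimizer(name: str, params, lr: float) -> Optimizer:
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}") from None
    return cls(params, lr=lr)
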