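"""Compact reverse-mode autodiff and neural-network layer on top of NumPy.

Provides exactly what the domain-adversarial training loop needs: 2-D
convolutions, batch norm, pooling, linear layers, a gradient reversal op,
fused cross-entropy, and an Adam optimizer.  All arithmetic is float32 and
fully deterministic on one machine, which is what makes the training
reproducibility contracts of the package testable.
"""

from __future__ import annotations

import copy
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "grl",
    "Module",
    "Conv2d",
    "Linear",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Sequential",
    "Adam",
    "TinyBackbone",
    "ResidualBackbone",
    "cross_entropy_logits",
]

_F32 = np.float32


# ---------------------------------------------------------------------------
# Tensor and primitive ops
# ---------------------------------------------------------------------------

class Tensor:
    """A NumPy array plus a backward closure for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from a scalar tensor through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(_F32, copy=True)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    def backward(g):
        _accum(a, g * _F32(c))

    return _make(a.data * _F32(c), (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
    s = s.astype(_F32)

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the un-clamped region."""
    inside = (a.data > lo) & (a.data < hi)

    def backward(g):
        _accum(a, g * inside)

    return _make(np.clip(a.data, lo, hi), (a,), backward)


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    def backward(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        _accum(a, np.full_like(a.data, g / n))

    return _make(np.asarray(a.data.mean(), dtype=_F32), (a,), backward)


def grl(a: Tensor, lam: float) -> Tensor:
    """Gradient reversal: identity forward, gradient times -lam backward.

    The op that lets one optimizer jointly minimize the label loss and the
    discriminator loss while the feature extractor *maximizes* the latter,
    driving domain-invariant features.
    """
    if lam <= 0:
        raise ValueError(f"grl lambda must be positive, got {lam}")

    def backward(g):
        _accum(a, -_F32(lam) * g)

    return _make(a.data.copy(), (a,), backward)


# ---------------------------------------------------------------------------
# Convolution / pooling (im2col based)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    # xp: padded (N, C, H, W) -> (N, OH, OW, C*kh*kw)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # N, C, OH, OW, kh, kw
    n, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, square kernel."""
    n, c, h, wd = x.data.shape
    cout, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(cout, -1)  # cout x (cin*kh*kw)
    out = cols.reshape(-1, c * kh * kw) @ wmat.T
    out = out.reshape(n, oh, ow, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)  # (N*OH*OW) x cout
        if w.requires_grad:
            gw = gmat.T @ cols.reshape(-1, c * kh * kw)
            _accum(w, gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += gcols[..., i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            _accum(x, gxp)

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 2, stride: int = 2, padding: int = 0) -> Tensor:
    n, c, h, w = x.data.shape
    if padding:
        xp = np.pad(
            x.data,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    else:
        xp = x.data
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    n_, c_, oh, ow = win.shape[:4]
    flat = win.reshape(n_, c_, oh, ow, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        onehot = np.zeros_like(flat)
        np.put_along_axis(onehot, arg[..., None], g[..., None], axis=-1)
        onehot = onehot.reshape(n_, c_, oh, ow, kernel, kernel)
        for i in range(kernel):
            for j in range(kernel):
                gxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += onehot[..., i, j]
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        _accum(x, gxp)

    return _make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.data.shape

    def backward(g):
        _accum(x, np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return _make(x.data.mean(axis=(2, 3)), (x,), backward)


def adaptive_avg_pool2d(x: Tensor, out_hw: int) -> Tensor:
    """Average-pool to an out_hw x out_hw grid (spatial dims must divide)."""
    n, c, h, w = x.data.shape
    if h <= out_hw and w <= out_hw:
        return x
    if h % out_hw or w % out_hw:
        raise ValueError(f"adaptive pool: {h}x{w} not divisible into {out_hw}x{out_hw}")
    fh, fw = h // out_hw, w // out_hw
    r = x.data.reshape(n, c, out_hw, fh, out_hw, fw)
    out = r.mean(axis=(3, 5))

    def backward(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None] / (fh * fw), (n, c, out_hw, fh, out_hw, fw)
        ).reshape(x.data.shape)
        _accum(x, gx)

    return _make(out, (x,), backward)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer labels under softmax(logits)."""
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        _accum(logits, g * p / n)

    return _make(np.asarray(loss, dtype=_F32), (logits,), backward)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Minimal layer container with parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def _modules(self) -> Iterable["Module"]:
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def train(self) -> None:
        self.training = True
        for m in self._modules():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._modules():
            m.eval()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for m in self._modules():
            state.extend(m._extra_state())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p.data = s.copy()
        rest = state[len(params):]
        for m in self._modules():
            rest = m._load_extra_state(rest)

    def _extra_state(self) -> list[np.ndarray]:
        return []

    def _load_extra_state(self, state: list[np.ndarray]) -> list[np.ndarray]:
        return state

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, kernel, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / nin)
        self.weight = Tensor(rng.normal(0.0, std, (nin, nout)), requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(ch), requires_grad=True)
        self.beta = Tensor(np.zeros(ch), requires_grad=True)
        self.running_mean = np.zeros(ch, dtype=_F32)
        self.running_var = np.ones(ch, dtype=_F32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        training = self.training
        gamma, beta = self.gamma, self.beta
        m = n * h * w

        def backward(g):
            _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accum(beta, g.sum(axis=(0, 2, 3)))
            if not x.requires_grad:
                return
            gi = g * gamma.data[None, :, None, None]
            if training:
                gx = (inv[None, :, None, None] / m) * (
                    m * gi
                    - gi.sum(axis=(0, 2, 3), keepdims=True)
                    - xhat * (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
                )
            else:
                gx = gi * inv[None, :, None, None]
            _accum(x, gx)

        return _make(out, (x, gamma, beta), backward)

    def _extra_state(self) -> list[np.ndarray]:
        return [self.running_mean.copy(), self.running_var.copy()]

    def _load_extra_state(self, state: list[np.ndarray]) -> list[np.ndarray]:
        self.running_mean = state[0].copy()
        self.running_var = state[1].copy()
        return state[2:]


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

class TinyBackbone(Module):
    """Four stride-2 conv blocks, 8 channels each: the fast test backbone.

    On 64x64 input the block outputs have spatial sizes 32, 16, 8, 4.
    Embedding dimension (channels of the last block) is 8.
    """

    n_blocks = 4
    embed_dim = 8

    def __init__(self, channels: int = 8, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.embed_dim = channels
        self.block_channels = [channels] * 4
        self.block_strides = [2, 4, 8, 16]  # cumulative downsampling per block
        cins = [3] + [channels] * 3
        self.blocks = [
            Sequential(Conv2d(cin, channels, 3, stride=2, padding=1, rng=rng), ReLU())
            for cin in cins
        ]

    def forward_blocks(self, x: Tensor) -> list[Tensor]:
        outs = []
        for block in self.blocks:
            x = block(x)
            outs.append(x)
        return outs


class _BasicBlock(Module):
    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cout)
        self.down: Module | None = None
        if stride != 1 or cin != cout:
            self.down = Sequential(
                Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng), BatchNorm2d(cout)
            )

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(relu(self.bn1(self.conv1(x)))))
        identity = self.down(x) if self.down is not None else x
        return relu(add(out, identity))


class ResidualBackbone(Module):
    """18-layer residual CNN (basic blocks, stages of 2, channels 64..512).

    Block indexing used throughout the package: block 1 is the stem
    (7x7/2 conv + 3x3/2 max pool), blocks 2-5 are the four residual stages.
    On 512x512 input, block 4 (third stage) yields a 256-channel 32x32 map.
    """

    n_blocks = 5
    embed_dim = 512

    def __init__(self, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.block_channels = [64, 64, 128, 256, 512]
        self.block_strides = [4, 4, 8, 16, 32]  # cumulative downsampling per block
        self.stem = Sequential(
            Conv2d(3, 64, 7, stride=2, padding=3, bias=False, rng=rng),
            BatchNorm2d(64),
            ReLU(),
            MaxPool2d(3, 2, 1),
        )
        chans = [64, 128, 256, 512]
        strides = [1, 2, 2, 2]
        self.stages = []
        cin = 64
        for cout, s in zip(chans, strides):
            self.stages.append(
                Sequential(_BasicBlock(cin, cout, s, rng), _BasicBlock(cout, cout, 1, rng))
            )
            cin = cout

    def forward_blocks(self, x: Tensor) -> list[Tensor]:
        outs = [self.stem(x)]
        for stage in self.stages:
            outs.append(stage(outs[-1]))
        return outs


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.lr == 0:
            return
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def clone_module(module: Module) -> Module:
    """Deep copy of a module (parameters and buffers included)."""
    return copy.deepcopy(module)
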