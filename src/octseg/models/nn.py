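"""Minimal neural-network layer library on top of HIPS autograd.

All layers are expressed as pure functions of a parameter pytree (nested
dicts/lists of float32 numpy arrays) so that :func:`autograd.value_and_grad`
can differentiate a whole segmentation network end to end on the CPU.

Conventions
-----------
* Feature maps are ``(N, C, H, W)`` float32 arrays.
* ``Module.init(rng)`` returns the parameter pytree; ``Module.apply(params,
  x, train=...)`` is the forward pass and must not mutate ``params``.
* ``Module.macs(in_shape)`` returns ``(macs, out_shape)`` where MACs count
  multiply-accumulates of convolutions, transposed convolutions, linear
  projections and attention matrix products only — normalisations,
  activations and pooling are excluded.
* BatchNorm keeps its running statistics as plain-numpy buffers on the
  module instance (outside the autodiff graph); everything else is
  stateless.
"""

from __future__ import annotations

import math

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

DTYPE = np.float32


# ---------------------------------------------------------------------------
# pytree helpers


def tree_flatten(tree, prefix=""):
    """Yield (path, leaf-array) pairs of a nested dict/list parameter tree."""
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_flatten(tree[k], f"{prefix}/{k}")
    elif isinstance(tree, (list, tuple)):
        for i, v in enumerate(tree):
            yield from tree_flatten(v, f"{prefix}/{i}")
    elif tree is None:
        return
    else:
        yield prefix, tree


def tree_size(tree) -> int:
    return int(sum(leaf.size for _, leaf in tree_flatten(tree)))


def tree_map(fn, *trees):
    t0 = trees[0]
    if isinstance(t0, dict):
        return {k: tree_map(fn, *[t[k] for t in trees]) for k in t0}
    if isinstance(t0, (list, tuple)):
        return [tree_map(fn, *parts) for parts in zip(*trees)]
    if t0 is None:
        return None
    return fn(*trees)


# ---------------------------------------------------------------------------
# activations


def relu(x):
    return anp.maximum(x, 0.0)


def leaky_relu(x, slope=0.01):
    return anp.where(x >= 0, x, slope * x)


def gelu(x):
    # tanh approximation, adequate at float32
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + anp.tanh(c * (x + 0.044715 * x**3)))


def softmax(x, axis=-1):
    m = anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x - m)
    return e / anp.sum(e, axis=axis, keepdims=True)


def log_softmax(x, axis=-1):
    m = anp.max(x, axis=axis, keepdims=True)
    s = x - m
    return s - anp.log(anp.sum(anp.exp(s), axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# base class


class Module:
    def init(self, rng: np.random.Generator):
        return {}

    def apply(self, params, x, *, train=False):
        raise NotImplementedError

    def param_count(self) -> int:
        raise NotImplementedError

    def macs(self, in_shape):
        raise NotImplementedError

    # convenience
    def __call__(self, params, x, *, train=False):
        return self.apply(params, x, train=train)


class Identity(Module):
    def init(self, rng):
        return {}

    def apply(self, params, x, *, train=False):
        return x

    def param_count(self):
        return 0

    def macs(self, in_shape):
        return 0, in_shape


class Lambda(Module):
    """Parameter-free elementwise op (activation); zero MACs by convention."""

    def __init__(self, fn):
        self.fn = fn

    def init(self, rng):
        return {}

    def apply(self, params, x, *, train=False):
        return self.fn(x)

    def param_count(self):
        return 0

    def macs(self, in_shape):
        return 0, in_shape


class Sequential(Module):
    def __init__(self, *modules):
        self.modules = list(modules)

    def init(self, rng):
        return [m.init(rng) for m in self.modules]

    def apply(self, params, x, *, train=False):
        for m, p in zip(self.modules, params):
            x = m.apply(p, x, train=train)
        return x

    def param_count(self):
        return sum(m.param_count() for m in self.modules)

    def macs(self, in_shape):
        total = 0
        for m in self.modules:
            c, in_shape = m.macs(in_shape)
            total += c
        return total, in_shape


# ---------------------------------------------------------------------------
# convolutions


class Conv2d(Module):
    """2D convolution with square kernel, 'same'-style integer padding.

    Implemented as k*k slice-gathers followed by a single tensordot so the
    heavy lifting is one BLAS matmul (autograd-friendly, no as_strided).
    """

    def __init__(self, cin, cout, k, stride=1, padding=None, bias=True):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.padding = (k - 1) // 2 if padding is None else padding
        self.bias = bias

    def init(self, rng):
        fan_in = self.cin * self.k * self.k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(self.cout, self.cin, self.k, self.k))
        p = {"w": w.astype(DTYPE)}
        if self.bias:
            p["b"] = np.zeros(self.cout, dtype=DTYPE)
        return p

    def out_hw(self, h, w):
        k, s, pd = self.k, self.stride, self.padding
        return (h + 2 * pd - k) // s + 1, (w + 2 * pd - k) // s + 1

    def apply(self, params, x, *, train=False):
        k, s, pd = self.k, self.stride, self.padding
        n, cin, h, w = x.shape
        if pd:
            x = anp.pad(x, ((0, 0), (0, 0), (pd, pd), (pd, pd)), mode="constant")
        ho, wo = self.out_hw(h, w)
        cols = []
        for u in range(k):
            for v in range(k):
                cols.append(x[:, :, u : u + s * ho : s, v : v + s * wo : s])
        patches = anp.stack(cols, axis=0)  # (k*k, N, Cin, Ho, Wo)
        wmat = anp.reshape(params["w"], (self.cout, self.cin * k * k))
        pmat = anp.reshape(
            anp.transpose(patches, (1, 3, 4, 2, 0)), (n * ho * wo, cin * k * k)
        )
        # patch layout is (Cin, k*k); weight reshape is (Cout, Cin*k*k) with
        # the same (Cin, k, k) ordering, so a plain matmul matches.
        y = anp.dot(pmat, wmat.T)
        if self.bias:
            y = y + params["b"]
        y = anp.transpose(anp.reshape(y, (n, ho, wo, self.cout)), (0, 3, 1, 2))
        return y

    def param_count(self):
        return self.cout * self.cin * self.k * self.k + (self.cout if self.bias else 0)

    def macs(self, in_shape):
        c, h, w = in_shape
        ho, wo = self.out_hw(h, w)
        return self.k * self.k * self.cin * self.cout * ho * wo, (self.cout, ho, wo)


class ConvTranspose2d(Module):
    """Transposed convolution with kernel == stride (non-overlapping taps)."""

    def __init__(self, cin, cout, k=2, bias=False):
        self.cin, self.cout, self.k = cin, cout, k

    def init(self, rng):
        fan_in = self.cin
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(self.k, self.k, self.cin, self.cout))
        return {"w": w.astype(DTYPE)}

    def apply(self, params, x, *, train=False):
        n, cin, h, w = x.shape
        k = self.k
        # (N,Cin,H,W) x (k,k,Cin,Cout) -> (k,k,N,H,W,Cout)
        y = anp.tensordot(params["w"], x, axes=[[2], [1]])  # (k,k,Cout,N,H,W)
        y = anp.transpose(y, (3, 2, 4, 0, 5, 1))  # (N,Cout,H,ku,W,kv)
        return anp.reshape(y, (n, self.cout, h * k, w * k))

    def param_count(self):
        return self.k * self.k * self.cin * self.cout

    def macs(self, in_shape):
        c, h, w = in_shape
        return self.k * self.k * self.cin * self.cout * h * w, (self.cout, h * self.k, w * self.k)


class Linear(Module):
    def __init__(self, cin, cout, bias=True):
        self.cin, self.cout, self.bias = cin, cout, bias

    def init(self, rng):
        lim = math.sqrt(6.0 / (self.cin + self.cout))
        p = {"w": rng.uniform(-lim, lim, size=(self.cout, self.cin)).astype(DTYPE)}
        if self.bias:
            p["b"] = np.zeros(self.cout, dtype=DTYPE)
        return p

    def apply(self, params, x, *, train=False):
        y = anp.dot(x, params["w"].T)
        if self.bias:
            y = y + params["b"]
        return y

    def param_count(self):
        return self.cin * self.cout + (self.cout if self.bias else 0)

    def macs(self, in_shape):
        # in_shape: (..., cin) -> treat leading dims as token count
        n_tok = int(np.prod(in_shape[:-1])) if len(in_shape) > 1 else 1
        return n_tok * self.cin * self.cout, tuple(in_shape[:-1]) + (self.cout,)


# ---------------------------------------------------------------------------
# normalisation


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        self.dim, self.eps = dim, eps

    def init(self, rng):
        return {"g": np.ones(self.dim, dtype=DTYPE), "b": np.zeros(self.dim, dtype=DTYPE)}

    def apply(self, params, x, *, train=False):
        mu = anp.mean(x, axis=-1, keepdims=True)
        var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
        return (x - mu) / anp.sqrt(var + self.eps) * params["g"] + params["b"]

    def param_count(self):
        return 2 * self.dim

    def macs(self, in_shape):
        return 0, in_shape


class InstanceNorm2d(Module):
    def __init__(self, c, eps=1e-5, affine=True):
        self.c, self.eps, self.affine = c, eps, affine

    def init(self, rng):
        if not self.affine:
            return {}
        return {"g": np.ones(self.c, dtype=DTYPE), "b": np.zeros(self.c, dtype=DTYPE)}

    def apply(self, params, x, *, train=False):
        mu = anp.mean(x, axis=(2, 3), keepdims=True)
        var = anp.mean((x - mu) ** 2, axis=(2, 3), keepdims=True)
        y = (x - mu) / anp.sqrt(var + self.eps)
        if self.affine:
            y = y * params["g"][None, :, None, None] + params["b"][None, :, None, None]
        return y

    def param_count(self):
        return 2 * self.c if self.affine else 0

    def macs(self, in_shape):
        return 0, in_shape


class BatchNorm2d(Module):
    """Batch norm with running statistics held outside the autodiff graph."""

    def __init__(self, c, eps=1e-5, momentum=0.1):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def init(self, rng):
        return {"g": np.ones(self.c, dtype=DTYPE), "b": np.zeros(self.c, dtype=DTYPE)}

    def apply(self, params, x, *, train=False):
        if train:
            mu = anp.mean(x, axis=(0, 2, 3))
            var = anp.mean((x - mu[None, :, None, None]) ** 2, axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * np.asarray(getval(mu))
            self.running_var = (1 - m) * self.running_var + m * np.asarray(getval(var))
        else:
            mu, var = self.running_mean, self.running_var
        y = (x - mu[None, :, None, None]) / anp.sqrt(var[None, :, None, None] + self.eps)
        return y * params["g"][None, :, None, None] + params["b"][None, :, None, None]

    def param_count(self):
        return 2 * self.c

    def macs(self, in_shape):
        return 0, in_shape


# ---------------------------------------------------------------------------
# resampling


class MaxPool2d(Module):
    def __init__(self, k):
        self.k = k

    def init(self, rng):
        return {}

    def apply(self, params, x, *, train=False):
        n, c, h, w = x.shape
        k = self.k
        y = anp.reshape(x, (n, c, h // k, k, w // k, k))
        return anp.max(anp.max(y, axis=5), axis=3)

    def param_count(self):
        return 0

    def macs(self, in_shape):
        c, h, w = in_shape
        return 0, (c, h // self.k, w // self.k)


def upsample2x_bilinear(x):
    """Factor-2 bilinear upsampling (half-pixel centres, edges clamped).

    Matches align_corners=False bilinear interpolation: output samples sit at
    offsets -0.25/+0.25 of the input grid, i.e. weights (0.75, 0.25) towards
    the nearer neighbour.
    """
    for axis in (2, 3):
        if axis == 2:
            below = anp.concatenate([x[:, :, :1], x[:, :, :-1]], axis=2)
            above = anp.concatenate([x[:, :, 1:], x[:, :, -1:]], axis=2)
        else:
            below = anp.concatenate([x[:, :, :, :1], x[:, :, :, :-1]], axis=3)
            above = anp.concatenate([x[:, :, :, 1:], x[:, :, :, -1:]], axis=3)
        a = 0.75 * x + 0.25 * below  # sample at -0.25
        b = 0.75 * x + 0.25 * above  # sample at +0.25
        y = anp.stack([a, b], axis=axis + 1)
        shp = list(x.shape)
        shp[axis] = 2 * x.shape[axis]
        x = anp.reshape(y, shp)
    return x


class UpsampleBilinear(Module):
    """Bilinear upsampling by a power-of-two factor (repeated 2x passes)."""

    def __init__(self, factor):
        assert factor >= 1 and (factor & (factor - 1)) == 0, "factor must be a power of 2"
        self.factor = factor

    def init(self, rng):
        return {}

    def apply(self, params, x, *, train=False):
        f = self.factor
        while f > 1:
            x = upsample2x_bilinear(x)
            f //= 2
        return x

    def param_count(self):
        return 0

    def macs(self, in_shape):
        c, h, w = in_shape
        return 0, (c, h * self.factor, w * self.factor)
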