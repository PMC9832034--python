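"""2D shifted-window (Swin) transformer encoder.

Tokens are kept in ``(N, H, W, C)`` layout between blocks.  Window attention
uses a learned relative position bias added to the scaled query-key scores;
alternating blocks shift the window grid by half a window (cyclic roll) with
the standard region mask so that tokens wrapped across the image border, or
lying in zero padding, never attend to each other.
"""

from __future__ import annotations

import math
from functools import lru_cache

import autograd.numpy as anp
import numpy as np

from .nn import DTYPE, LayerNorm, Linear, Module, Sequential, gelu, softmax

NEG = -1e4  # attention mask fill; large enough at float32 without overflow


@lru_cache(maxsize=None)
def relative_position_index(ws: int) -> np.ndarray:
    """(ws^2, ws^2) index into the (2*ws-1)^2 relative-position bias table."""
    coords = np.stack(np.meshgrid(np.arange(ws), np.arange(ws), indexing="ij"))
    flat = coords.reshape(2, -1)
    rel = flat[:, :, None] - flat[:, None, :]  # (2, ws^2, ws^2)
    rel = rel + (ws - 1)
    return (rel[0] * (2 * ws - 1) + rel[1]).astype(np.int64)


@lru_cache(maxsize=None)
def shift_attention_mask(h: int, w: int, hp: int, wp: int, ws: int, shift: int) -> np.ndarray | None:
    """Additive (nW, ws^2, ws^2) mask for a (possibly shifted) window grid.

    ``h``/``w`` are the real token-grid sizes, ``hp``/``wp`` the zero-padded
    sizes (multiples of ``ws``).  Region ids follow the original Swin
    construction; padded cells are marked with a sentinel id so real tokens
    never attend into padding (padding may attend to itself, which keeps
    every softmax row finite and is cropped away afterwards).
    """
    img_mask = np.zeros((hp, wp), dtype=np.int64)
    cnt = 1
    hs = (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)) if shift else (slice(None),)
    wsl = (slice(0, -ws), slice(-ws, -shift), slice(-shift, None)) if shift else (slice(None),)
    for hsl in hs:
        for wsl_ in wsl:
            img_mask[hsl, wsl_] = cnt
            cnt += 1
    if hp != h or wp != w:
        pad = np.zeros((hp, wp), dtype=bool)
        pad[h:, :] = True
        pad[:, w:] = True
        if shift:  # padding travels with the cyclic roll
            pad = np.roll(pad, (-shift, -shift), axis=(0, 1))
        img_mask[pad] = 0  # sentinel region
    win = window_partition_np(img_mask[:, :, None], ws)[..., 0]  # (nW, ws*ws)
    diff = win[:, :, None] - win[:, None, :]
    mask = np.where(diff != 0, NEG, 0.0).astype(DTYPE)
    if not mask.any():
        return None
    return mask


def window_partition_np(x: np.ndarray, ws: int) -> np.ndarray:
    h, w, c = x.shape
    x = x.reshape(h // ws, ws, w // ws, ws, c)
    return x.transpose(0, 2, 1, 3, 4).reshape(-1, ws * ws, c)


def window_partition(x, ws: int):
    """(N, H, W, C) -> (N * nW, ws*ws, C); H, W must be multiples of ws."""
    n, h, w, c = x.shape
    x = anp.reshape(x, (n, h // ws, ws, w // ws, ws, c))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    return anp.reshape(x, (n * (h // ws) * (w // ws), ws * ws, c))


def window_reverse(x, ws: int, n: int, h: int, w: int):
    c = x.shape[-1]
    x = anp.reshape(x, (n, h // ws, w // ws, ws, ws, c))
    x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
    return anp.reshape(x, (n, h, w, c))


class WindowAttention(Module):
    def __init__(self, dim, ws, heads, qkv_bias=True):
        self.dim, self.ws, self.heads = dim, ws, heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, bias=qkv_bias)
        self.proj = Linear(dim, dim)

    def init(self, rng):
        table = rng.normal(0.0, 0.02, size=((2 * self.ws - 1) ** 2, self.heads))
        return {
            "qkv": self.qkv.init(rng),
            "proj": self.proj.init(rng),
            "rel_bias": table.astype(DTYPE),
        }

    def apply(self, params, x, *, train=False, mask=None):
        b, n_tok, c = x.shape
        h, d = self.heads, self.head_dim
        qkv = self.qkv.apply(params["qkv"], x)  # (B, N, 3C)
        qkv = anp.reshape(qkv, (b, n_tok, 3, h, d))
        qkv = anp.transpose(qkv, (2, 0, 3, 1, 4))  # (3, B, h, N, d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = anp.matmul(q, anp.transpose(k, (0, 1, 3, 2))) / math.sqrt(d)
        idx = relative_position_index(self.ws)
        bias = params["rel_bias"][idx.ravel()]  # (N*N, heads)
        bias = anp.transpose(anp.reshape(bias, (n_tok, n_tok, h)), (2, 0, 1))
        attn = attn + bias[None]
        if mask is not None:
            n_w = mask.shape[0]
            attn = anp.reshape(attn, (b // n_w, n_w, h, n_tok, n_tok))
            attn = attn + mask[None, :, None, :, :]
            attn = anp.reshape(attn, (b, h, n_tok, n_tok))
        attn = softmax(attn, axis=-1)
        y = anp.matmul(attn, v)  # (B, h, N, d)
        y = anp.reshape(anp.transpose(y, (0, 2, 1, 3)), (b, n_tok, c))
        return self.proj.apply(params["proj"], y)

    def param_count(self):
        return (
            self.qkv.param_count()
            + self.proj.param_count()
            + (2 * self.ws - 1) ** 2 * self.heads
        )

    def macs_tokens(self, n_windows, n_tok):
        qkv = n_windows * n_tok * self.dim * 3 * self.dim
        attn = 2 * n_windows * n_tok * n_tok * self.dim  # q.kT and attn.v
        proj = n_windows * n_tok * self.dim * self.dim
        return qkv + attn + proj


class SwinBlock(Module):
    def __init__(self, dim, heads, ws, shift, mlp_ratio=4.0):
        self.dim, self.ws, self.shift = dim, ws, shift
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, ws, heads)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden)
        self.fc2 = Linear(hidden, dim)

    def init(self, rng):
        return {
            "norm1": self.norm1.init(rng),
            "attn": self.attn.init(rng),
            "norm2": self.norm2.init(rng),
            "fc1": self.fc1.init(rng),
            "fc2": self.fc2.init(rng),
        }

    def _grid(self, h, w):
        """Effective shift and zero-padded grid size for this resolution."""
        ws = self.ws
        shift = self.shift if (self.shift and min(h, w) > ws) else 0
        hp = int(math.ceil(h / ws)) * ws
        wp = int(math.ceil(w / ws)) * ws
        return ws, shift, hp, wp

    def apply(self, params, x, *, train=False):
        n, h, w, c = x.shape
        ws, shift, hp, wp = self._grid(h, w)
        y = self.norm1.apply(params["norm1"], x)
        if hp != h or wp != w:
            y = anp.pad(y, ((0, 0), (0, hp - h), (0, wp - w), (0, 0)), mode="constant")
        if shift:
            # per-axis rolls: autograd's roll VJP handles scalar shifts only
            y = anp.roll(anp.roll(y, -shift, axis=1), -shift, axis=2)
        mask = (
            shift_attention_mask(h, w, hp, wp, ws, shift)
            if (shift or hp != h or wp != w)
            else None
        )
        wins = window_partition(y, ws)
        wins = self.attn.apply(params["attn"], wins, mask=mask)
        y = window_reverse(wins, ws, n, hp, wp)
        if shift:
            y = anp.roll(anp.roll(y, shift, axis=1), shift, axis=2)
        if hp != h or wp != w:
            y = y[:, :h, :w, :]
        x = x + y
        z = self.norm2.apply(params["norm2"], x)
        z = self.fc2.apply(params["fc2"], gelu(self.fc1.apply(params["fc1"], z)))
        return x + z

    def param_count(self):
        return (
            self.norm1.param_count()
            + self.attn.param_count()
            + self.norm2.param_count()
            + self.fc1.param_count()
            + self.fc2.param_count()
        )

    def macs(self, in_shape):
        h, w, c = in_shape
        ws, shift, hp, wp = self._grid(h, w)
        n_windows = (hp // ws) * (wp // ws)
        n_tok = ws * ws
        total = self.attn.macs_tokens(n_windows, n_tok)
        total += self.fc1.macs((h * w, c))[0] + self.fc2.macs((h * w, self.fc1.cout))[0]
        return total, in_shape


class PatchMerging(Module):
    """Concatenate 2x2 neighbouring tokens, LayerNorm, project 4C -> 2C."""

    def __init__(self, dim):
        self.dim = dim
        self.norm = LayerNorm(4 * dim)
        self.reduction = Linear(4 * dim, 2 * dim, bias=False)

    def init(self, rng):
        return {"norm": self.norm.init(rng), "reduction": self.reduction.init(rng)}

    def apply(self, params, x, *, train=False):
        n, h, w, c = x.shape
        x = anp.reshape(x, (n, h // 2, 2, w // 2, 2, c))
        x = anp.transpose(x, (0, 1, 3, 2, 4, 5))
        x = anp.reshape(x, (n, h // 2, w // 2, 4 * c))
        x = self.norm.apply(params["norm"], x)
        return self.reduction.apply(params["reduction"], x)

    def param_count(self):
        return self.norm.param_count() + self.reduction.param_count()

    def macs(self, in_shape):
        h, w, c = in_shape
        m = (h // 2) * (w // 2) * 4 * c * 2 * c
        return m, (h // 2, w // 2, 2 * c)


class SwinStage(Module):
    def __init__(self, dim, depth, heads, ws, mlp_ratio=4.0, downsample=True):
        self.blocks = [
            SwinBlock(dim, heads, ws, shift=(ws // 2 if i % 2 else 0), mlp_ratio=mlp_ratio)
            for i in range(depth)
        ]
        self.downsample = PatchMerging(dim) if downsample else None

    def init(self, rng):
        p = {"blocks": [b.init(rng) for b in self.blocks]}
        if self.downsample is not None:
            p["downsample"] = self.downsample.init(rng)
        return p

    def apply(self, params, x, *, train=False):
        for b, bp in zip(self.blocks, params["blocks"]):
            x = b.apply(bp, x, train=train)
        if self.downsample is not None:
            x = self.downsample.apply(params["downsample"], x, train=train)
        return x

    def param_count(self):
        n = sum(b.param_count() for b in self.blocks)
        if self.downsample is not None:
            n += self.downsample.param_count()
        return n

    def macs(self, in_shape):
        total = 0
        for b in self.blocks:
            c, in_shape = b.macs(in_shape)
            total += c
        if self.downsample is not None:
            c, in_shape = self.downsample.macs(in_shape)
            total += c
        return total, in_shape
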