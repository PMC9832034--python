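"""2D Swin-UNETR: shifted-window transformer encoder + residual CNN decoder.

The encoder embeds the B-scan into 2x2 patches and runs four Swin stages
(patch merging after each), so the patch footprint grows 2-4-8-16-32 pixels
and the embedding width doubles per stage.  The decoder has five stages; at
each one a residual block (two 3x3 convolutions with instance normalisation)
processes the skip, the upsampled coarser features are concatenated, a
second residual block fuses them, and a 2x transposed convolution hands the
result to the next stage.  A final 1x1 convolution produces per-class
logits at the input resolution.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from .nn import Conv2d, ConvTranspose2d, InstanceNorm2d, Module, leaky_relu
from .swin import SwinStage


def _nchw_to_tokens(x):
    return anp.transpose(x, (0, 2, 3, 1))


def _tokens_to_nchw(x):
    return anp.transpose(x, (0, 3, 1, 2))


class ResBlock(Module):
    """Two 3x3 conv + instance norm with a (projected) residual connection."""

    def __init__(self, cin, cout):
        self.cin, self.cout = cin, cout
        self.conv1 = Conv2d(cin, cout, 3, bias=False)
        self.norm1 = InstanceNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, bias=False)
        self.norm2 = InstanceNorm2d(cout)
        if cin != cout:
            self.conv3 = Conv2d(cin, cout, 1, bias=False)
            self.norm3 = InstanceNorm2d(cout)
        else:
            self.conv3 = None

    def init(self, rng):
        p = {
            "conv1": self.conv1.init(rng),
            "norm1": self.norm1.init(rng),
            "conv2": self.conv2.init(rng),
            "norm2": self.norm2.init(rng),
        }
        if self.conv3 is not None:
            p["conv3"] = self.conv3.init(rng)
            p["norm3"] = self.norm3.init(rng)
        return p

    def apply(self, params, x, *, train=False):
        y = self.conv1.apply(params["conv1"], x)
        y = leaky_relu(self.norm1.apply(params["norm1"], y))
        y = self.conv2.apply(params["conv2"], y)
        y = self.norm2.apply(params["norm2"], y)
        if self.conv3 is not None:
            x = self.norm3.apply(params["norm3"], self.conv3.apply(params["conv3"], x))
        return leaky_relu(x + y)

    def param_count(self):
        n = (
            self.conv1.param_count()
            + self.norm1.param_count()
            + self.conv2.param_count()
            + self.norm2.param_count()
        )
        if self.conv3 is not None:
            n += self.conv3.param_count() + self.norm3.param_count()
        return n

    def macs(self, in_shape):
        total, shape = self.conv1.macs(in_shape)
        c2, shape = self.conv2.macs(shape)
        total += c2
        if self.conv3 is not None:
            total += self.conv3.macs(in_shape)[0]
        return total, shape


class UpBlock(Module):
    """Transposed-conv upsampling followed by a residual fusion block."""

    def __init__(self, cin, cout):
        self.up = ConvTranspose2d(cin, cout, 2)
        self.res = ResBlock(2 * cout, cout)

    def init(self, rng):
        return {"up": self.up.init(rng), "res": self.res.init(rng)}

    def apply(self, params, x, skip, *, train=False):
        y = self.up.apply(params["up"], x)
        y = anp.concatenate([y, skip], axis=1)
        return self.res.apply(params["res"], y, train=train)

    def param_count(self):
        return self.up.param_count() + self.res.param_count()

    def macs(self, in_shape):
        m_up, up_shape = self.up.macs(in_shape)
        cat_shape = (2 * up_shape[0], up_shape[1], up_shape[2])
        m_res, out_shape = self.res.macs(cat_shape)
        return m_up + m_res, out_shape


class SwinUNETR(Module):
    def __init__(self, config):
        c = config
        fs = c.feature_size
        self.config = c
        self.patch_embed = Conv2d(c.in_channels, fs, c.patch_size, stride=c.patch_size, padding=0)
        dims = [fs, 2 * fs, 4 * fs, 8 * fs]
        self.stages = [
            SwinStage(dims[i], c.stage_depths[i], c.num_heads[i], c.window_size,
                      mlp_ratio=c.mlp_ratio, downsample=True)
            for i in range(4)
        ]
        self.encoder1 = ResBlock(c.in_channels, fs)
        self.encoder2 = ResBlock(fs, fs)
        self.encoder3 = ResBlock(2 * fs, 2 * fs)
        self.encoder4 = ResBlock(4 * fs, 4 * fs)
        self.encoder10 = ResBlock(16 * fs, 16 * fs)
        self.decoder5 = UpBlock(16 * fs, 8 * fs)
        self.decoder4 = UpBlock(8 * fs, 4 * fs)
        self.decoder3 = UpBlock(4 * fs, 2 * fs)
        self.decoder2 = UpBlock(2 * fs, fs)
        self.decoder1 = UpBlock(fs, fs)
        self.out = Conv2d(fs, c.num_classes, 1)
        self._named = {
            "patch_embed": self.patch_embed,
            "encoder1": self.encoder1,
            "encoder2": self.encoder2,
            "encoder3": self.encoder3,
            "encoder4": self.encoder4,
            "encoder10": self.encoder10,
            "decoder5": self.decoder5,
            "decoder4": self.decoder4,
            "decoder3": self.decoder3,
            "decoder2": self.decoder2,
            "decoder1": self.decoder1,
            "out": self.out,
        }

    def init(self, rng):
        p = {name: m.init(rng) for name, m in self._named.items()}
        p["stages"] = [s.init(rng) for s in self.stages]
        return p

    def hidden_states(self, params, x, *, train=False):
        h0 = self.patch_embed.apply(params["patch_embed"], x)
        states = [h0]
        t = _nchw_to_tokens(h0)
        for stage, sp in zip(self.stages, params["stages"]):
            t = stage.apply(sp, t, train=train)
            states.append(_tokens_to_nchw(t))
        return states  # [fs@/2, 2fs@/4, 4fs@/8, 8fs@/16, 16fs@/32]

    def apply(self, params, x, *, train=False):
        h0, h1, h2, h3, h4 = self.hidden_states(params, x, train=train)
        e1 = self.encoder1.apply(params["encoder1"], x, train=train)
        e2 = self.encoder2.apply(params["encoder2"], h0, train=train)
        e3 = self.encoder3.apply(params["encoder3"], h1, train=train)
        e4 = self.encoder4.apply(params["encoder4"], h2, train=train)
        b = self.encoder10.apply(params["encoder10"], h4, train=train)
        d = self.decoder5.apply(params["decoder5"], b, h3, train=train)
        d = self.decoder4.apply(params["decoder4"], d, e4, train=train)
        d = self.decoder3.apply(params["decoder3"], d, e3, train=train)
        d = self.decoder2.apply(params["decoder2"], d, e2, train=train)
        d = self.decoder1.apply(params["decoder1"], d, e1, train=train)
        return self.out.apply(params["out"], d)

    def param_count(self):
        n = sum(m.param_count() for m in self._named.values())
        return n + sum(s.param_count() for s in self.stages)

    def macs(self, in_shape):
        cch, h, w = in_shape
        fs = self.config.feature_size
        total, shape = self.patch_embed.macs(in_shape)
        tok_shape = (shape[1], shape[2], shape[0])
        state_shapes = [shape]
        for stage in self.stages:
            m, tok_shape = stage.macs(tok_shape)
            total += m
            state_shapes.append((tok_shape[2], tok_shape[0], tok_shape[1]))
        h0s, h1s, h2s, h3s, h4s = state_shapes
        for blk, shp in [
            (self.encoder1, in_shape),
            (self.encoder2, h0s),
            (self.encoder3, h1s),
            (self.encoder4, h2s),
            (self.encoder10, h4s),
        ]:
            total += blk.macs(shp)[0]
        d_shape = (16 * fs, h4s[1], h4s[2])
        for dec in [self.decoder5, self.decoder4, self.decoder3, self.decoder2, self.decoder1]:
            m, d_shape = dec.macs(d_shape)
            total += m
        total += self.out.macs(d_shape)[0]
        return total, (self.config.num_classes, h, w)
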