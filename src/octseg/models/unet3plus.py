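"""U-Net3+: U-Net encoder with full-scale skip connections.

Every decoder stage aggregates features from *all* five scales: encoder maps
are max-pooled down (or passed directly), coarser decoder maps and the
bottleneck are bilinearly upsampled.  Each of the five sources runs through
its own 3x3 convolution with 64 kernels (+BN+ReLU); the concatenation
(5 x 64 = 320 channels) is fused by a 3x3 convolution with 320 kernels,
batch normalisation and ReLU, so every decoder stage carries 320 channels.
Optional deep-supervision heads emit per-stage logits (off by default).
"""

from __future__ import annotations

import autograd.numpy as anp

from .nn import (
    BatchNorm2d,
    Conv2d,
    Lambda,
    MaxPool2d,
    Module,
    Sequential,
    UpsampleBilinear,
    relu,
)

CAT_CHANNELS = 64
N_SCALES = 5
FUSED_CHANNELS = CAT_CHANNELS * N_SCALES  # 320


def conv_bn_relu(cin, cout):
    return Sequential(Conv2d(cin, cout, 3, bias=False), BatchNorm2d(cout), Lambda(relu))


def enc_block(cin, cout):
    return Sequential(
        Conv2d(cin, cout, 3, bias=False), BatchNorm2d(cout), Lambda(relu),
        Conv2d(cout, cout, 3, bias=False), BatchNorm2d(cout), Lambda(relu),
    )


class UNet3Plus(Module):
    def __init__(self, config):
        self.config = config
        w = config.base_width
        self.widths = [w, 2 * w, 4 * w, 8 * w, 16 * w]
        self.deep_supervision = getattr(config, "deep_supervision", False)
        cin = config.in_channels
        self.enc = []
        for cw in self.widths:
            self.enc.append(enc_block(cin, cw))
            cin = cw
        self.pool = MaxPool2d(2)
        # decoder stages s=4 (coarsest) .. 1 (full resolution after final ups)
        # sources for stage s: enc scales 1..s (pool factor 2^(s-j)),
        # decoder stages s+1..4 and the bottleneck (upsampled).
        self.branches = {}  # (stage, source) -> Sequential
        for s in range(4, 0, -1):
            for j in range(1, 6):
                if j <= s:
                    cin_j = self.widths[j - 1]
                    pre = MaxPool2d(2 ** (s - j)) if s != j else None
                else:
                    cin_j = FUSED_CHANNELS if j < 5 else self.widths[4]
                    pre = UpsampleBilinear(2 ** (j - s)) if j < 5 else UpsampleBilinear(2 ** (5 - s))
                self.branches[(s, j)] = (pre, conv_bn_relu(cin_j, CAT_CHANNELS))
        self.fusion = {s: conv_bn_relu(FUSED_CHANNELS, FUSED_CHANNELS) for s in range(4, 0, -1)}
        self.out = Conv2d(FUSED_CHANNELS, config.num_classes, 1)
        if self.deep_supervision:
            self.ds_heads = {s: Conv2d(FUSED_CHANNELS, config.num_classes, 3) for s in (2, 3, 4)}
        else:
            self.ds_heads = {}

    def init(self, rng):
        p = {
            "enc": [m.init(rng) for m in self.enc],
            "branches": {f"{s}_{j}": blk.init(rng) for (s, j), (_, blk) in sorted(self.branches.items())},
            "fusion": {str(s): m.init(rng) for s, m in self.fusion.items()},
            "out": self.out.init(rng),
        }
        if self.ds_heads:
            p["ds"] = {str(s): m.init(rng) for s, m in self.ds_heads.items()}
        return p

    def apply(self, params, x, *, train=False, return_aux=False):
        e = []
        for i, (m, mp) in enumerate(zip(self.enc, params["enc"])):
            x = m.apply(mp, x, train=train)
            e.append(x)
            if i < 4:
                x = self.pool.apply(None, x)
        d = {5: e[4]}  # bottleneck acts as the coarsest "decoder" source
        for s in range(4, 0, -1):
            feats = []
            for j in range(1, 6):
                pre, blk = self.branches[(s, j)]
                src = e[j - 1] if j <= s else d[j] if j < 5 else e[4]
                if pre is not None:
                    src = pre.apply(None, src)
                feats.append(blk.apply(params["branches"][f"{s}_{j}"], src, train=train))
            cat = anp.concatenate(feats, axis=1)
            d[s] = self.fusion[s].apply(params["fusion"][str(s)], cat, train=train)
        logits = self.out.apply(params["out"], d[1])
        if return_aux and self.ds_heads:
            aux = {s: self.ds_heads[s].apply(params["ds"][str(s)], d[s]) for s in self.ds_heads}
            return logits, aux
        return logits

    def param_count(self):
        n = sum(m.param_count() for m in self.enc)
        n += sum(blk.param_count() for _, blk in self.branches.values())
        n += sum(m.param_count() for m in self.fusion.values())
        n += self.out.param_count()
        n += sum(m.param_count() for m in self.ds_heads.values())
        return n

    def macs(self, in_shape):
        total = 0
        shape = in_shape
        enc_shapes = []
        for i, m in enumerate(self.enc):
            cm, shape = m.macs(shape)
            total += cm
            enc_shapes.append(shape)
            if i < 4:
                shape = (shape[0], shape[1] // 2, shape[2] // 2)
        res = {j + 1: enc_shapes[j] for j in range(5)}
        dec_shape = {}
        for s in range(4, 0, -1):
            hw = (enc_shapes[s - 1][1], enc_shapes[s - 1][2])
            for j in range(1, 6):
                _, blk = self.branches[(s, j)]
                cin = blk.modules[0].cin
                cm, _ = blk.macs((cin, hw[0], hw[1]))
                total += cm
            cm, out_shape = self.fusion[s].macs((FUSED_CHANNELS, hw[0], hw[1]))
            total += cm
            dec_shape[s] = out_shape
        cm, out_shape = self.out.macs(dec_shape[1])
        total += cm
        for s, head in self.ds_heads.items():
            total += head.macs(dec_shape[s])[0]
        return total, out_shape
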