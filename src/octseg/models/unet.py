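"""Classic 2D U-Net: 5-level contracting/expansive paths with skip concats.

Encoder widths default to 64-128-256-512-1024; each level is two 3x3
convolutions with ReLU, levels are joined by 2x2 max-pooling on the way
down and 2x2 transposed convolutions on the way up.
"""

from __future__ import annotations

import autograd.numpy as anp

from .nn import Conv2d, ConvTranspose2d, Lambda, MaxPool2d, Module, Sequential, relu


def conv_block(cin, cout):
    return Sequential(
        Conv2d(cin, cout, 3), Lambda(relu), Conv2d(cout, cout, 3), Lambda(relu)
    )


class UNet(Module):
    def __init__(self, config):
        self.config = config
        w = config.base_width
        self.widths = [w, 2 * w, 4 * w, 8 * w, 16 * w]
        cin = config.in_channels
        self.enc = []
        for cw in self.widths:
            self.enc.append(conv_block(cin, cw))
            cin = cw
        self.pool = MaxPool2d(2)
        self.ups = [
            ConvTranspose2d(self.widths[i + 1], self.widths[i], 2) for i in range(3, -1, -1)
        ]
        self.dec = [conv_block(2 * self.widths[i], self.widths[i]) for i in range(3, -1, -1)]
        self.out = Conv2d(self.widths[0], config.num_classes, 1)

    def init(self, rng):
        return {
            "enc": [m.init(rng) for m in self.enc],
            "ups": [m.init(rng) for m in self.ups],
            "dec": [m.init(rng) for m in self.dec],
            "out": self.out.init(rng),
        }

    def apply(self, params, x, *, train=False):
        skips = []
        for i, (m, p) in enumerate(zip(self.enc, params["enc"])):
            x = m.apply(p, x, train=train)
            if i < 4:
                skips.append(x)
                x = self.pool.apply(None, x)
        for up, upp, dec, decp, skip in zip(
            self.ups, params["ups"], self.dec, params["dec"], reversed(skips)
        ):
            x = up.apply(upp, x)
            x = anp.concatenate([x, skip], axis=1)
            x = dec.apply(decp, x, train=train)
        return self.out.apply(params["out"], x)

    def param_count(self):
        n = sum(m.param_count() for m in self.enc)
        n += sum(m.param_count() for m in self.ups)
        n += sum(m.param_count() for m in self.dec)
        return n + self.out.param_count()

    def macs(self, in_shape):
        total = 0
        c, h, w = in_shape
        shape = in_shape
        skip_shapes = []
        for i, m in enumerate(self.enc):
            cm, shape = m.macs(shape)
            total += cm
            if i < 4:
                skip_shapes.append(shape)
                shape = (shape[0], shape[1] // 2, shape[2] // 2)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skip_shapes)):
            cm, shape = up.macs(shape)
            total += cm
            shape = (shape[0] + skip[0], shape[1], shape[2])
            cm, shape = dec.macs(shape)
            total += cm
        cm, shape = self.out.macs(shape)
        return total + cm, shape
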