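"""Model configuration, construction and capacity/efficiency accounting."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .swin_unetr import SwinUNETR
from .unet import UNet
from .unet3plus import UNet3Plus

FAMILIES = ("swin_unetr", "unet", "unet3plus")


@dataclass
class ModelConfig:
    """Architecture family plus the capacity hyper-parameters that matter.

    ``feature_size`` is the embedding width at the first Swin stage (24 for
    the default model, 48 for the high-capacity variant) and is doubled at
    every encoder stage; ``base_width`` plays the analogous role for the
    CNNs (64 wide at the first level, up to 1024 at the bottleneck).
    """

    family: str = "swin_unetr"
    in_channels: int = 1
    num_classes: int = 4
    input_size: int = 224
    feature_size: int = 24
    stage_depths: tuple = (2, 2, 6, 2)
    window_size: int = 7
    num_heads: tuple = (3, 6, 12, 24)
    mlp_ratio: float = 4.0
    patch_size: int = 2
    base_width: int = 64
    deep_supervision: bool = False
    name: str = ""

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if len(self.stage_depths) != 4 or len(self.num_heads) != 4:
            raise ValueError("stage_depths and num_heads must have 4 entries")
        if self.family == "swin_unetr":
            for i, h in enumerate(self.num_heads):
                if (self.feature_size * 2**i) % h:
                    raise ValueError(
                        f"stage {i} width {self.feature_size * 2**i} not divisible by "
                        f"num_heads[{i}]={h}"
                    )
        factor = self.patch_size * 2**4
        if self.input_size % factor:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by patch_size*2^4 = {factor}"
            )
        if self.family == "swin_unetr" and self.input_size < 2 * factor:
            # a 1x1 bottleneck degenerates under instance normalisation
            raise ValueError(f"swin_unetr needs input_size >= {2 * factor}")
        if not self.name:
            self.name = (
                f"{self.family}-{self.feature_size}" if self.family == "swin_unetr" else self.family
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("stage_depths", "num_heads"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class Model:
    """A built network together with its (mutable) parameter pytree."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        if config.family == "swin_unetr":
            self.net = SwinUNETR(config)
        elif config.family == "unet":
            self.net = UNet(config)
        else:
            self.net = UNet3Plus(config)
        self.params = self.net.init(np.random.default_rng(seed))

    def apply(self, x, params=None, *, train=False):
        p = self.params if params is None else params
        return self.net.apply(p, x, train=train)

    def predict(self, x) -> np.ndarray:
        """Class-index prediction for a (N, C, H, W) batch."""
        logits = np.asarray(self.apply(x, train=False))
        return np.argmax(logits, axis=1).astype(np.uint8)

    # --- capacity accounting -------------------------------------------
    def parameter_count(self) -> int:
        return nn.tree_size(self.params)

    def macs(self, input_size: int | None = None) -> int:
        s = input_size or self.config.input_size
        return int(self.net.macs((self.config.in_channels, s, s))[0])

    # --- checkpoints ----------------------------------------------------
    def save(self, path):
        path = Path(path)
        flat = dict(nn.tree_flatten(self.params))
        buffers = {
            f"__buffer__{i:04d}_{name}": arr
            for i, (name, arr) in enumerate(self._iter_buffers())
        }
        np.savez(path, __config__=np.frombuffer(self.config.to_json().encode(), dtype=np.uint8),
                 **flat, **buffers)

    def _iter_buffers(self):
        stack = [self.net]
        while stack:
            m = stack.pop()
            if isinstance(m, nn.BatchNorm2d):
                yield "running_mean", m.running_mean
                yield "running_var", m.running_var
            for v in vars(m).values():
                if isinstance(v, nn.Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(u for u in v if isinstance(u, nn.Module))
                elif isinstance(v, dict):
                    for u in v.values():
                        if isinstance(u, nn.Module):
                            stack.append(u)
                        elif isinstance(u, tuple):
                            stack.extend(w for w in u if isinstance(w, nn.Module))

    @classmethod
    def load(cls, path) -> "Model":
        data = np.load(path)
        cfg = ModelConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        model = cls(cfg)
        flat = dict(nn.tree_flatten(model.params))
        for key in flat:
            flat[key][...] = data[key]
        bufs = [(k, data[k]) for k in data.files if k.startswith("__buffer__")]
        own = list(model._iter_buffers())
        for (_, src), (_, dst) in zip(sorted(bufs), own):
            dst[...] = src
        return model


def build_model(config: ModelConfig, seed: int = 0) -> Model:
    return Model(config, seed=seed)


def count_parameters(model: Model) -> int:
    """Total element count of all trainable tensors."""
    return model.parameter_count()


def count_macs(model: Model, input_size: int | None = None) -> int:
    """Multiply-accumulates of convolutions, transposed convolutions,
    linear projections and attention matrix products at the given input
    size; normalisations and activations are excluded."""
    return model.macs(input_size)


@dataclass
class ArchitectureSummary:
    name: str
    n_params: int
    macs: int

    def to_row(self) -> dict:
        return {"method": self.name, "n_params": self.n_params, "macs": self.macs}


def summarize(model: Model, input_size: int | None = None) -> ArchitectureSummary:
    return ArchitectureSummary(
        name=model.config.name,
        n_params=count_parameters(model),
        macs=count_macs(model, input_size),
    )


def default_method_configs(input_size: int = 224) -> list[ModelConfig]:
    """The four method variants compared in the study."""
    return [
        ModelConfig(family="unet", input_size=input_size),
        ModelConfig(family="unet3plus", input_size=input_size),
        ModelConfig(family="swin_unetr", feature_size=24, input_size=input_size),
        ModelConfig(family="swin_unetr", feature_size=48, input_size=input_size),
    ]
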