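"""The EF regression network: a 3D ResNet-18 backbone whose second residual
block in stages conv3 and conv5 is a Residual Transformer Module (RTM).

Backbone (input B x 1 x T0 x 112 x 112):

    conv1  3x7x7, 64, stride 1x2x2            -> T0   x 56 x 56
    conv2  2 basic blocks, 64                  -> T0   x 56 x 56
    conv3  downsample block 128 + RTM          -> T0/2 x 28 x 28
    conv4  2 basic blocks, 256 (first strides) -> T0/4 x 14 x 14
    conv5  downsample block 512 + RTM          -> T0/8 x  7 x  7
    GAP -> FC 512 -> 1 (EF in percent)

A basic block is conv-BN-ReLU-conv-BN plus an (optionally projected)
shortcut with ReLU after the addition; convolutions carry no bias (the BN
affine pair supplies the shift).  The RTM follows

    y = BN(MHSA(ReLU(BN(Conv(x))) + x))

with a single 3x3x3 stride-1 convolution before the attention and no ReLU
after the final BN.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .attention import MHSA3d
from .nn import (
    BatchNorm3d,
    Conv3d,
    GlobalAvgPool3d,
    Linear,
    Module,
    ReLU,
    Sequential,
    count_parameters,
)

STAGE_NAMES = ("conv2", "conv3", "conv4", "conv5")


@dataclass(frozen=True)
class ModelConfig:
    clip_len: int = 16
    height: int = 112
    width: int = 112
    in_channels: int = 1
    stem_channels: int = 64
    stage_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    rtm_stages: tuple[str, ...] = ("conv3", "conv5")
    n_heads: int = 4
    rpe_init_std: float = 0.02
    head_bias_init: float = 50.0  # EF midpoint on the percent scale
    seed: int = 0

    def __post_init__(self):
        if self.clip_len % 8:
            raise ValueError(f"clip_len must be divisible by 8, got {self.clip_len}")
        for name, v in (("height", self.height), ("width", self.width)):
            if v % 16:
                raise ValueError(f"{name} must be divisible by 16, got {v}")
        unknown = set(self.rtm_stages) - {"conv3", "conv5"}
        if unknown:
            raise ValueError(f"rtm_stages may only contain conv3/conv5, got {unknown}")
        for stage in self.rtm_stages:
            c = self.stage_channels[STAGE_NAMES.index(stage)]
            if c % self.n_heads:
                raise ValueError(
                    f"{stage} channels {c} not divisible by n_heads {self.n_heads}"
                )

    def stage_grid(self, stage: str) -> tuple[int, int, int]:
        """Feature-map (T, H, W) at the output of a stage."""
        factor = {"conv2": 1, "conv3": 2, "conv4": 4, "conv5": 8}[stage]
        return (
            self.clip_len // factor,
            self.height // (2 * factor),
            self.width // (2 * factor),
        )


class BasicBlock(Module):
    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        self.conv1 = Conv3d(cin, cout, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm3d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(cout, cout, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm3d(cout)
        if cin != cout or stride != 1:
            self.proj = Conv3d(cin, cout, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm3d(cout)
        else:
            self.proj = None
            self.proj_bn = None
        self.relu_out = ReLU()

    def forward(self, x):
        y = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        shortcut = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return self.relu_out(y + shortcut)

    def backward(self, dy):
        dsum = self.relu_out.backward(dy)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(dsum))))
        )
        if self.proj is not None:
            dshort = self.proj.backward(self.proj_bn.backward(dsum))
        else:
            dshort = dsum
        return dmain + dshort


class RTMBlock(Module):
    """Residual Transformer Module: y = BN(MHSA(ReLU(BN(Conv(x))) + x))."""

    def __init__(self, channels, grid, n_heads, rpe_init_std, rng):
        super().__init__()
        self.conv = Conv3d(channels, channels, 3, stride=1, padding=1, rng=rng)
        self.bn_in = BatchNorm3d(channels)
        self.relu = ReLU()
        self.mhsa = MHSA3d(
            channels, *grid, n_heads=n_heads, rpe_init_std=rpe_init_std, rng=rng
        )
        self.bn_out = BatchNorm3d(channels)

    def forward(self, x):
        pre = self.relu(self.bn_in(self.conv(x))) + x
        return self.bn_out(self.mhsa(pre))

    def backward(self, dy):
        dpre = self.mhsa.backward(self.bn_out.backward(dy))
        dmain = self.conv.backward(self.bn_in.backward(self.relu.backward(dpre)))
        return dmain + dpre


class EFNet(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.stage_channels

        self.stem = Sequential(
            Conv3d(
                config.in_channels, config.stem_channels, (3, 7, 7),
                stride=(1, 2, 2), padding=(1, 3, 3), rng=rng,
            ),
            BatchNorm3d(config.stem_channels),
            ReLU(),
        )
        self.stages = []
        cin = config.stem_channels
        for name, cout in zip(STAGE_NAMES, c):
            stride = 1 if name == "conv2" else 2
            blocks = [BasicBlock(cin, cout, stride, rng)]
            if name in config.rtm_stages:
                blocks.append(
                    RTMBlock(
                        cout, config.stage_grid(name), config.n_heads,
                        config.rpe_init_std, rng,
                    )
                )
            else:
                blocks.append(BasicBlock(cout, cout, 1, rng))
            self.stages.append(Sequential(*blocks))
            cin = cout
        self.gap = GlobalAvgPool3d()
        self.fc = Linear(c[-1], 1, rng=rng, bias_init=config.head_bias_init)

    def forward_features(self, x) -> dict[str, np.ndarray]:
        """Stage-by-stage feature maps, keyed conv1..conv5 (for shape checks)."""
        feats = {"conv1": self.stem(x)}
        h = feats["conv1"]
        for name, stage in zip(STAGE_NAMES, self.stages):
            h = stage(h)
            feats[name] = h
        return feats

    def forward(self, x):
        h = self.stem(x)
        for stage in self.stages:
            h = stage(h)
        return self.fc(self.gap(h))

    def backward(self, dy):
        dh = self.gap.backward(self.fc.backward(dy))
        for stage in reversed(self.stages):
            dh = stage.backward(dh)
        return self.stem.backward(dh)


def build_efnet(config: ModelConfig) -> EFNet:
    return EFNet(config)


def build_baseline(config: ModelConfig | None = None) -> EFNet:
    """The plain 3D ResNet-18 regressor (no RTM substitution)."""
    config = config or ModelConfig()
    return EFNet(
        ModelConfig(**{**asdict(config), "rtm_stages": ()})
    )


def save_checkpoint(path: str | Path, model: EFNet) -> None:
    """Write parameters + running stats + config as an npz with fixed timestamps.

    Writing the zip members by hand keeps the bytes identical across runs
    with the same seed (np.savez embeds wall-clock timestamps).
    """
    entries = dict(model.state_dict())
    for i, stage in enumerate(model.stages):
        for name, mod in _named_bn(stage, f"stages.{i}."):
            entries[f"{name}.running_mean"] = mod.running_mean
            entries[f"{name}.running_var"] = mod.running_var
    for name, mod in _named_bn(model.stem, "stem."):
        entries[f"{name}.running_mean"] = mod.running_mean
        entries[f"{name}.running_var"] = mod.running_var

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        for name in sorted(entries):
            buf = io.BytesIO()
            np.save(buf, entries[name])
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())
        cfg = json.dumps(asdict(model.config), sort_keys=True).encode()
        info = zipfile.ZipInfo("config.json", date_time=(1980, 1, 1, 0, 0, 0))
        zf.writestr(info, cfg)


def load_checkpoint(path: str | Path) -> EFNet:
    with zipfile.ZipFile(path) as zf:
        cfg = json.loads(zf.read("config.json"))
        arrays = {}
        for name in zf.namelist():
            if name.endswith(".npy"):
                arrays[name[:-4]] = np.load(io.BytesIO(zf.read(name)))
    cfg["stage_channels"] = tuple(cfg["stage_channels"])
    cfg["rtm_stages"] = tuple(cfg["rtm_stages"])
    model = EFNet(ModelConfig(**cfg))
    state = {k: v for k, v in arrays.items() if not k.endswith(("running_mean", "running_var"))}
    model.load_state_dict(state)
    for scope, prefix in [(model.stem, "stem.")] + [
        (stage, f"stages.{i}.") for i, stage in enumerate(model.stages)
    ]:
        for name, mod in _named_bn(scope, prefix):
            mod.running_mean[...] = arrays[f"{name}.running_mean"]
            mod.running_var[...] = arrays[f"{name}.running_var"]
    return model


def _named_bn(module: Module, prefix: str):
    """(name, BatchNorm3d) pairs, mirroring named_parameters paths."""
    for name, attr in vars(module).items():
        if isinstance(attr, BatchNorm3d):
            yield f"{prefix}{name}", attr
        elif isinstance(attr, Module):
            yield from _named_bn(attr, f"{prefix}{name}.")
        elif isinstance(attr, (list, tuple)):
            for i, item in enumerate(attr):
                if isinstance(item, BatchNorm3d):
                    yield f"{prefix}{name}.{i}", item
                elif isinstance(item, Module):
                    yield from _named_bn(item, f"{prefix}{name}.{i}.")


__all__ = [
    "ModelConfig",
    "EFNet",
    "BasicBlock",
    "RTMBlock",
    "build_efnet",
    "build_baseline",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]
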