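"""The detector network.

A Darknet-53-style backbone (stem + 5 stride-2 stages with residual blocks
Res1/Res2/Res8/Res8/Res4), an FPN-style top-down neck, and per-scale heads
emitting ``anchors_per_scale * (5 + num_classes)`` channels.

Two variants share the identical backbone (same parameter names):

* ``baseline`` — heads at strides 32/16/8 (13x13, 26x26, 52x52 at input 416);
* ``improved`` — the top-down path starts at the stride-16 feature and fuses
  down through stride 8 to the shallow stride-4 feature, heads at strides
  16/8/4 (26x26, 52x52, 104x104); the stride-32 map feeds no head.

``width_mult`` scales every channel count (rounded to multiples of 8, minimum
8) so desk-scale models stay valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .anchors import AnchorSet, DEFAULT_ANCHORS

__all__ = ["DetectorConfig", "Detector", "build_detector",
           "save_checkpoint", "load_checkpoint"]

LEAKY_SLOPE = 0.1  # darknet convention

#: residual-block counts of the five backbone stages
STAGE_PLAN = (1, 2, 8, 8, 4)
BASE_WIDTHS = (32, 64, 128, 256, 512, 1024)  # stem + 5 stages


@dataclass
class DetectorConfig:
    variant: str = "improved"            # {"baseline", "improved"}
    input_size: int = 416
    num_classes: int = 1
    anchors: AnchorSet = field(default_factory=lambda: DEFAULT_ANCHORS)
    width_mult: float = 1.0

    def __post_init__(self):
        if self.variant not in ("baseline", "improved"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.input_size % 32 != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 32")
        if not (0 < self.width_mult <= 1):
            raise ValueError("width_mult must be in (0, 1]")

    @property
    def anchors_per_scale(self) -> int:
        return self.anchors.anchors_per_scale

    @property
    def head_channels(self) -> int:
        return self.anchors_per_scale * (5 + self.num_classes)

    @property
    def strides(self) -> tuple[int, int, int]:
        """Head strides ordered coarsest to finest."""
        return (32, 16, 8) if self.variant == "baseline" else (16, 8, 4)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anchors"] = {"anchors": self.anchors.anchors,
                        "scale_groups": self.anchors.scale_groups}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        a = d["anchors"]
        d["anchors"] = AnchorSet(anchors=[tuple(x) for x in a["anchors"]],
                                 scale_groups=a["scale_groups"])
        return cls(**d)


def _c(ch: int, width_mult: float) -> int:
    return max(8, int(round(ch * width_mult / 8)) * 8)


class CBL(ad.Module):
    """conv2d + batch normalization + leaky ReLU."""

    def __init__(self, cin, cout, k, stride=1, rng=None):
        super().__init__()
        self.conv = ad.Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng)
        self.bn = ad.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).leaky_relu(LEAKY_SLOPE)


class Residual(ad.Module):
    """1x1 squeeze + 3x3 expand + identity add."""

    def __init__(self, ch, rng=None):
        super().__init__()
        mid = max(8, ch // 2)
        self.squeeze = CBL(ch, mid, 1, rng=rng)
        self.expand = CBL(mid, ch, 3, rng=rng)

    def forward(self, x):
        return x + self.expand(self.squeeze(x))


class Backbone(ad.Module):
    """Stem + 5 subsampling stages; returns features at strides 4..32."""

    def __init__(self, width_mult=1.0, rng=None):
        super().__init__()
        w = [_c(c, width_mult) for c in BASE_WIDTHS]
        self.stem = CBL(3, w[0], 3, rng=rng)
        self.stages = ad.ModuleList()
        cin = w[0]
        for cout, n_blocks in zip(w[1:], STAGE_PLAN):
            stage = ad.ModuleList([CBL(cin, cout, 3, stride=2, rng=rng)])
            for _ in range(n_blocks):
                stage.append(Residual(cout, rng=rng))
            self.stages.append(stage)
            cin = cout
        self.widths = w

    def forward(self, x):
        x = self.stem(x)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats  # strides 2, 4, 8, 16, 32


class ConvSet(ad.Module):
    """The five alternating 1x1/3x3 CBL blocks of a neck stage."""

    def __init__(self, cin, cmid, rng=None):
        super().__init__()
        self.blocks = ad.ModuleList([
            CBL(cin, cmid, 1, rng=rng),
            CBL(cmid, cmid * 2, 3, rng=rng),
            CBL(cmid * 2, cmid, 1, rng=rng),
            CBL(cmid, cmid * 2, 3, rng=rng),
            CBL(cmid * 2, cmid, 1, rng=rng),
        ])

    def forward(self, x):
        return self.blocks(x)


class Head(ad.Module):
    """3x3 CBL expansion + linear 1x1 projection to the prediction channels."""

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        self.expand = CBL(cin, cin * 2, 3, rng=rng)
        self.project = ad.Conv2d(cin * 2, cout, 1, bias=True, rng=rng)

    def forward(self, x):
        return self.project(self.expand(x))


class Detector(ad.Module):
    """Full detector; ``forward`` returns raw grids ordered coarsest->finest."""

    def __init__(self, config: DetectorConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        wm = config.width_mult
        self.backbone = Backbone(wm, rng=rng)
        w = self.backbone.widths  # stem + stage widths
        out_ch = config.head_channels

        if config.variant == "baseline":
            # top-down from stride 32 over features (C5, C4, C3)
            feat_ch = (w[5], w[4], w[3])
            mids = (_c(512, wm), _c(256, wm), _c(128, wm))
        else:
            # top-down from stride 16 over (C4, C3, C2); widths mirror the
            # 52x52 path halved for the new shallow stage
            feat_ch = (w[4], w[3], w[2])
            mids = (_c(256, wm), _c(128, wm), _c(64, wm))

        self.convsets = ad.ModuleList()
        self.laterals = ad.ModuleList()
        self.heads = ad.ModuleList()
        cin = feat_ch[0]
        for i, (fc, mid) in enumerate(zip(feat_ch, mids)):
            if i == 0:
                self.convsets.append(ConvSet(fc, mid, rng=rng))
            else:
                lat = CBL(mids[i - 1], mid, 1, rng=rng)
                self.laterals.append(lat)
                self.convsets.append(ConvSet(fc + mid, mid, rng=rng))
            self.heads.append(Head(mid, out_ch, rng=rng))

    def forward(self, x) -> list[ad.Tensor]:
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(np.ascontiguousarray(x, dtype=np.float32))
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(f"input spatial size {h}x{w} must be divisible by 32")
        feats = self.backbone(x)  # strides 2,4,8,16,32
        if self.config.variant == "baseline":
            pyramid = [feats[4], feats[3], feats[2]]
        else:
            pyramid = [feats[3], feats[2], feats[1]]
        outputs = []
        carry = None
        for i, feat in enumerate(pyramid):
            if i == 0:
                fused = feat
            else:
                up = ad.upsample2x(self.laterals[i - 1](carry))
                fused = ad.concat([up, feat], axis=1)
            carry = self.convsets[i](fused)
            outputs.append(self.heads[i](carry))
        return outputs  # coarsest -> finest


def build_detector(config: DetectorConfig,
                   seed: int = 0) -> Detector:
    """Construct a detector with seeded weight initialization."""
    return Detector(config, rng=np.random.default_rng(seed))


def save_checkpoint(model: Detector, path: str | Path) -> None:
    """Single-file checkpoint: weights + the DetectorConfig that built them."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> Detector:
    with np.load(Path(path)) as data:
        state = {k: data[k] for k in data.files}
    cfg_json = state.pop("__config__").tobytes().decode()
    config = DetectorConfig.from_dict(json.loads(cfg_json))
    model = build_detector(config)
    model.load_state_dict(state)
    return model
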