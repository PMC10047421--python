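"""Composite attention residual U-net for thin-lesion segmentation.

The architecture is a U-net whose encoder stages are ResNet34-style
residual blocks, with two optional additions:

* a hybrid dense dilated convolution (HDDC) bottleneck — parallel
  branches of cascaded 3x3 dilated convolutions sharing a common trunk,
  each tapped through a 1x1 projection and superimposed — which enlarges
  the receptive field at the deepest stage without striding;
* a combined attention module (CAM) on every skip connection — per-channel
  average pooling along height and width of both the skip (low-level) and
  upsampled decoder (high-level) features, a shared bottleneck transform,
  and sigmoid gates per row and per column that modulate the low-level
  features before they are added to the high-level ones.

Both additions are controlled by flags so the plain residual U-net
baseline is recoverable with a strictly nested parameter set.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from . import nn
from .nn import Tensor

DOWNSAMPLE_FACTOR = 32  # stem /2, pool /2, three strided stages /8


@dataclasses.dataclass
class ModelConfig:
    """Architecture hyperparameters.

    encoder: channel counts (stem, stage1..stage4); ResNet34-like default.
    blocks: residual blocks per stage; (3, 4, 6, 3) matches ResNet34.
    cam_reduction_r: channel compression ratio of the attention bottleneck.
    hddc_rates: dilation rates of the cascaded bottleneck convolutions.
    hddc_merge: 'sum' projects each branch then adds; 'concat' stacks
        branches and projects once.
    pad_mode: 'error' rejects inputs not divisible by 32; 'pad' reflect-pads
        and crops the output back.
    """

    in_channels: int = 1
    n_classes: int = 1
    encoder: tuple = (64, 64, 128, 256, 512)
    blocks: tuple = (3, 4, 6, 3)
    cam_reduction_r: int = 16
    hddc_rates: tuple = (1, 3, 5)
    use_hddc: bool = True
    use_cam: bool = True
    hddc_merge: str = "sum"
    pad_mode: str = "error"

    def __post_init__(self):
        self.encoder = tuple(int(c) for c in self.encoder)
        self.blocks = tuple(int(b) for b in self.blocks)
        self.hddc_rates = tuple(int(r) for r in self.hddc_rates)
        if len(self.encoder) != 5 or any(c < 1 for c in self.encoder):
            raise ValueError("encoder must list 5 positive channel counts")
        if len(self.blocks) != 4 or any(b < 1 for b in self.blocks):
            raise ValueError("blocks must list 4 positive counts")
        if self.cam_reduction_r < 1:
            raise ValueError("cam_reduction_r must be >= 1")
        if self.use_cam and min(self.encoder) // self.cam_reduction_r < 1:
            raise ValueError(
                f"cam_reduction_r={self.cam_reduction_r} collapses "
                f"{min(self.encoder)} channels below 1"
            )
        if any(r < 1 for r in self.hddc_rates):
            raise ValueError("hddc_rates must be strictly positive")
        if self.hddc_merge not in ("sum", "concat"):
            raise ValueError("hddc_merge must be 'sum' or 'concat'")
        if self.pad_mode not in ("error", "pad"):
            raise ValueError("pad_mode must be 'error' or 'pad'")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        return cls(**d)

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale variant used throughout the test suite."""
        defaults = dict(encoder=(8, 8, 16, 32, 64), blocks=(1, 1, 1, 1),
                        cam_reduction_r=4)
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# directional pooling / CAM


def directional_pool(x):
    """Average each channel along width and along height.

    Returns (z_h, z_w): z_h[..., c, h] is the mean of row h, z_w[..., c, w]
    the mean of column w.  Accepts a Tensor or ndarray, 3D (C,H,W) or 4D
    (N,C,H,W); the trailing spatial axis conventions are row-major.
    """
    if isinstance(x, Tensor):
        return x.mean(axis=x.ndim - 1), x.mean(axis=x.ndim - 2)
    x = np.asarray(x)
    return x.mean(axis=-1), x.mean(axis=-2)


class CamFuse(nn.Module):
    """Skip fusion via dual-direction attention.

    Output: x_l * f_h (per row) * f_w (per column) + x_t, where the gates
    come from pooled profiles of both inputs passed through a shared
    C -> C/r bottleneck (BN + ReLU) and per-direction 1x1 convolutions
    with sigmoid.
    """

    def __init__(self, channels: int, r: int, rng):
        super().__init__()
        if channels // r < 1:
            raise ValueError(f"channels/r = {channels}/{r} < 1")
        mid = channels // r
        self.squeeze = nn.Conv2d(channels, mid, 1, rng)
        self.bn = nn.BatchNorm2d(mid)
        self.gate_h = nn.Conv2d(mid, channels, 1, rng)
        self.gate_w = nn.Conv2d(mid, channels, 1, rng)
        # open the gates at init (sigmoid(2)^2 ~ 0.77) so the fused skip
        # starts close to plain addition and attention is learned on top
        self.gate_h.bias.data[:] = 2.0
        self.gate_w.bias.data[:] = 2.0

    def forward(self, x_l: Tensor, x_t: Tensor) -> Tensor:
        if x_l.shape != x_t.shape:
            raise ValueError(f"shape mismatch: {x_l.shape} vs {x_t.shape}")
        n, c, h, w = x_l.shape
        zl_h, zl_w = directional_pool(x_l)
        zt_h, zt_w = directional_pool(x_t)
        profile = nn.concat([zl_h + zt_h, zl_w + zt_w], axis=2)  # (n,c,h+w)
        y = profile.reshape(n, c, h + w, 1)
        y = self.bn(self.squeeze(y)).relu()
        f_h = self.gate_h(y[:, :, :h, :]).sigmoid()            # (n,c,h,1)
        f_w = self.gate_w(y[:, :, h:, :]).sigmoid()            # (n,c,w,1)
        f_w = f_w.reshape(n, c, 1, w)
        return x_l * f_h * f_w + x_t

    def attention_weights(self, x_l, x_t):
        """Gates (f_h, f_w) as arrays, for inspection and tests."""
        x_l = x_l if isinstance(x_l, Tensor) else Tensor(x_l)
        x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
        n, c, h, w = x_l.shape
        zl_h, zl_w = directional_pool(x_l)
        zt_h, zt_w = directional_pool(x_t)
        profile = nn.concat([zl_h + zt_h, zl_w + zt_w], axis=2)
        y = self.bn(self.squeeze(profile.reshape(n, c, h + w, 1))).relu()
        f_h = self.gate_h(y[:, :, :h, :]).sigmoid().data[..., 0]
        f_w = self.gate_w(y[:, :, h:, :]).sigmoid().data[..., 0]
        return f_h, f_w


def cam_fuse(x_l, x_t, r: int = 16, rng=None, module: CamFuse | None = None):
    """Functional wrapper around :class:`CamFuse` (fresh parameters if no
    module is given)."""
    x_l = x_l if isinstance(x_l, Tensor) else Tensor(x_l)
    x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
    if x_l.shape != x_t.shape:
        raise ValueError(f"shape mismatch: {x_l.shape} vs {x_t.shape}")
    if module is None:
        rng = rng if rng is not None else np.random.default_rng(0)
        module = CamFuse(x_l.shape[1], r, rng)
    return module(x_l, x_t)


# ---------------------------------------------------------------------------
# HDDC bottleneck


class Hddc(nn.Module):
    """Hybrid dense dilated convolution bottleneck.

    A trunk of 3x3 convolutions with the given dilation rates is shared;
    branch 0 is a 1x1 path on the input and branch k taps the trunk after
    its k-th convolution.  Branches are merged either by per-branch 1x1
    projection and summation ('sum') or by concatenation followed by a
    single 1x1 projection ('concat').
    """

    def __init__(self, channels: int, rates: Sequence[int], rng,
                 merge: str = "sum"):
        super().__init__()
        if any(r < 1 for r in rates):
            raise ValueError(f"dilation rates must be >= 1, got {tuple(rates)}")
        self.rates = tuple(rates)
        self.merge = merge
        for k, rate in enumerate(self.rates):
            setattr(self, f"conv{k}", nn.Conv2d(channels, channels, 3, rng,
                                                dilation=rate))
            setattr(self, f"norm{k}", nn.BatchNorm2d(channels))
        n_branches = len(self.rates) + 1
        if merge == "sum":
            for k in range(n_branches):
                setattr(self, f"proj{k}", nn.Conv2d(channels, channels, 1, rng))
        else:
            self.proj = nn.Conv2d(channels * n_branches, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        taps = [x]
        t = x
        for k in range(len(self.rates)):
            t = self._modules[f"norm{k}"](self._modules[f"conv{k}"](t)).relu()
            taps.append(t)
        if self.merge == "sum":
            out = self._modules["proj0"](taps[0])
            for k in range(1, len(taps)):
                out = out + self._modules[f"proj{k}"](taps[k])
            return out
        return self.proj(nn.concat(taps, axis=1))


def hddc_forward(x, rates: Sequence[int] = (1, 3, 5), rng=None,
                 module: Hddc | None = None):
    """Functional wrapper around :class:`Hddc`."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    if module is None:
        rng = rng if rng is not None else np.random.default_rng(0)
        module = Hddc(x.shape[1], rates, rng)
    return module(x)


# ---------------------------------------------------------------------------
# receptive field audit


def receptive_field_of(layers: Sequence[tuple]) -> int:
    """Theoretical receptive field of a layer stack.

    Each layer is (kernel, stride, dilation).  Standard recurrence:
    rf += (effective_kernel - 1) * jump; jump *= stride.
    """
    rf, jump = 1, 1
    for kernel, stride, dilation in layers:
        eff = (kernel - 1) * dilation + 1
        rf += (eff - 1) * jump
        jump *= stride
    return rf


def receptive_field(config: ModelConfig) -> int:
    """Receptive field of the deepest bottleneck branch, in bottleneck pixels."""
    if not config.use_hddc:
        return 1
    return receptive_field_of([(3, 1, r) for r in config.hddc_rates])


# ---------------------------------------------------------------------------
# the full model


class ResidualBlock(nn.Module):
    def __init__(self, cin, cout, rng, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, stride=stride, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, rng, stride=stride,
                                       bias=False)
            self.down_bn = nn.BatchNorm2d(cout)
        else:
            self.down_conv = None

    def forward(self, x):
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + shortcut).relu()


class _DecoderStage(nn.Module):
    """Upsample, fuse the skip (CAM or plain addition), refine."""

    def __init__(self, cin, cout, rng, cam_r=None):
        super().__init__()
        self.up = nn.ConvTranspose2d(cin, cout, 2, rng)
        self.cam = CamFuse(cout, cam_r, rng) if cam_r is not None else None
        self.conv = nn.Conv2d(cout, cout, 3, rng, bias=False)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x, skip):
        x = self.up(x)
        x = self.cam(skip, x) if self.cam is not None else skip + x
        return self.bn(self.conv(x)).relu()


class CompositeResUNet(nn.Module):
    """Residual U-net with optional HDDC bottleneck and CAM skip fusion."""

    def __init__(self, config: ModelConfig, rng=None):
        super().__init__()
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)
        c0, c1, c2, c3, c4 = config.encoder

        self.stem_conv = nn.Conv2d(config.in_channels, c0, 7, rng, stride=2,
                                   padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(c0)

        stage_specs = [(c0, c1, 1), (c1, c2, 2), (c2, c3, 2), (c3, c4, 2)]
        for i, ((cin, cout, stride), n_blocks) in enumerate(
                zip(stage_specs, config.blocks), start=1):
            mods = [ResidualBlock(cin, cout, rng, stride=stride)]
            mods += [ResidualBlock(cout, cout, rng) for _ in range(n_blocks - 1)]
            setattr(self, f"stage{i}", nn.Sequential(*mods))

        if config.use_hddc:
            self.hddc = Hddc(c4, config.hddc_rates, rng, merge=config.hddc_merge)
        else:
            self.hddc = None

        cam_r = config.cam_reduction_r if config.use_cam else None
        self.dec4 = _DecoderStage(c4, c3, rng, cam_r)
        self.dec3 = _DecoderStage(c3, c2, rng, cam_r)
        self.dec2 = _DecoderStage(c2, c1, rng, cam_r)
        self.dec1 = _DecoderStage(c1, c0, rng, cam_r)
        self.final_up = nn.ConvTranspose2d(c0, c0, 2, rng)
        self.head = nn.Conv2d(c0, config.n_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        s0 = self.stem_bn(self.stem_conv(x)).relu()        # /2
        s1 = self.stage1(nn.max_pool2x2(s0))               # /4
        s2 = self.stage2(s1)                               # /8
        s3 = self.stage3(s2)                               # /16
        s4 = self.stage4(s3)                               # /32
        b = self.hddc(s4) if self.hddc is not None else s4
        d = self.dec4(b, s3)
        d = self.dec3(d, s2)
        d = self.dec2(d, s1)
        d = self.dec1(d, s0)
        return self.head(self.final_up(d).relu()).sigmoid()

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one 2D image (eval mode, no graph)."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 2:
            raise ValueError("predict expects a single 2D image")
        h, w = image.shape
        ph = (-h) % DOWNSAMPLE_FACTOR
        pw = (-w) % DOWNSAMPLE_FACTOR
        if ph or pw:
            if self.config.pad_mode == "error":
                raise ValueError(
                    f"input size {image.shape} not divisible by "
                    f"{DOWNSAMPLE_FACTOR}; set pad_mode='pad' to allow"
                )
            image = np.pad(image, ((0, ph), (0, pw)), mode="reflect")
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(Tensor(image[None, None])).data[0, 0]
        finally:
            self.train(was_training)
        return out[:h, :w]


def build_model(config: ModelConfig, seed: int = 0) -> CompositeResUNet:
    return CompositeResUNet(config, np.random.default_rng(seed))


def model_forward(image: np.ndarray, config: ModelConfig,
                  parameters: dict | None) -> np.ndarray:
    """Run one 2D image through a model described by (config, parameters).

    `parameters` is a state dict as returned by ``Module.state_dict``; a
    missing state dict is an error rather than silently using random
    weights.
    """
    if parameters is None:
        raise ValueError("parameters are required; got None")
    model = build_model(config)
    model.load_state_dict(parameters)
    return model.predict(np.asarray(image, dtype=np.float32))
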