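"""The four base segmentation networks.

All builders share one contract: a batch of B×H×W×3 images in [0, 1] maps
to a B×H×W×1 probability map in (0, 1) through a sigmoid head, with the
output spatial size equal to the input.  ``base_channels`` scales every
layer proportionally (64 reproduces the canonical layer tables; small
values give the same topology at a fraction of the width for CPU-scale
work).

* ``unet`` — classic encoder/decoder: per level two 3×3 conv + ReLU then
  2×2 max-pool, channels doubling; transposed-conv upsampling with skip
  concatenation from the matching encoder level.
* ``resnet50_seg`` — ResNet50 encoder (7×7/2 stem, max-pool, bottleneck
  residual stages of 3/4/6/3 blocks with batch norm), a dilated-convolution
  pyramid module at the bottleneck, and a five-step upsampling decoder with
  skip connections from the stem and each stage.
* ``unet_resnet_backbone`` — ResNet50 encoder taps at strides 2/4/8/16/32
  feeding a U-Net style double-conv decoder (4 skip connections).
* ``ctu_net`` — the U-Net with its bottleneck convolutions replaced by a
  transformer: the deepest feature map is flattened to one token per
  spatial position, learned positional embeddings are added, and pre-norm
  multi-head self-attention blocks mix global context before the map is
  reshaped for the decoder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from . import nn
from .nn import autograd as ag
from .nn.autograd import Tensor
from .errors import ConfigurationError, DimensionMismatchError

__all__ = [
    "TransformerConfig", "ArchitectureSpec", "SegmentationModel",
    "build_unet", "build_resnet50_seg", "build_unet_resnet_backbone",
    "build_ctu_net", "build_model", "predict", "n_parameters",
    "save_checkpoint", "load_checkpoint", "ARCHITECTURE_NAMES",
]

ARCHITECTURE_NAMES = ("unet", "resnet50_seg", "unet_resnet_backbone",
                      "ctu_net")


@dataclass(frozen=True)
class TransformerConfig:
    n_blocks: int = 2
    n_heads: int = 4
    mlp_ratio: float = 4.0


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    input_size: tuple[int, int] = (256, 256)
    base_channels: int = 64
    depth: int = 4
    pretrained_backbone: bool = False
    backbone_weights: str | None = None
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    ppm_dilations: tuple[int, ...] = (1, 2, 4)
    upsample: str = "transposed"   # or "bilinear"
    seed: int = 0

    def validate(self) -> None:
        if self.name not in ARCHITECTURE_NAMES:
            raise ConfigurationError(f"unknown architecture {self.name!r}")
        h, w = self.input_size
        if self.base_channels < 1:
            raise ConfigurationError("base_channels must be >= 1")
        if self.name in ("unet", "ctu_net"):
            if h % 2 ** self.depth or w % 2 ** self.depth:
                raise ConfigurationError(
                    f"input_size {self.input_size} not divisible by "
                    f"2^depth = {2 ** self.depth}")
        else:
            if h % 32 or w % 32:
                raise ConfigurationError(
                    f"input_size {self.input_size} not divisible by 32")
        if self.name == "ctu_net":
            dim = self.base_channels * 2 ** self.depth
            if dim % self.transformer.n_heads:
                raise ConfigurationError(
                    f"n_heads={self.transformer.n_heads} does not divide "
                    f"bottleneck dim {dim}")
        if self.upsample not in ("transposed", "bilinear"):
            raise ConfigurationError(f"unknown upsample mode {self.upsample!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["ppm_dilations"] = list(self.ppm_dilations)
        return d

    @staticmethod
    def from_dict(d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["input_size"] = tuple(d["input_size"])
        d["ppm_dilations"] = tuple(d.get("ppm_dilations", (1, 2, 4)))
        tf = d.get("transformer", {})
        if isinstance(tf, dict):
            d["transformer"] = TransformerConfig(**tf)
        return ArchitectureSpec(**d)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _upsample2x_bilinear(x: Tensor) -> Tensor:
    """Differentiable 2x bilinear upsampling (half-pixel convention)."""

    def axis_fwd(a: np.ndarray) -> np.ndarray:
        left = np.concatenate([a[..., :1], a[..., :-1]], axis=-1)
        right = np.concatenate([a[..., 1:], a[..., -1:]], axis=-1)
        even = 0.25 * left + 0.75 * a
        odd = 0.75 * a + 0.25 * right
        out = np.stack([even, odd], axis=-1)
        return out.reshape(*a.shape[:-1], a.shape[-1] * 2)

    def axis_adj(g: np.ndarray) -> np.ndarray:
        ge, go = g[..., 0::2], g[..., 1::2]
        dx = 0.75 * ge + 0.75 * go
        dx[..., :-1] += 0.25 * ge[..., 1:]
        dx[..., 0] += 0.25 * ge[..., 0]
        dx[..., 1:] += 0.25 * go[..., :-1]
        dx[..., -1] += 0.25 * go[..., -1]
        return dx

    data = axis_fwd(np.swapaxes(axis_fwd(x.data), -1, -2))
    data = np.swapaxes(data, -1, -2).astype(ag.DTYPE)

    def backward(g):
        d = np.swapaxes(axis_adj(np.swapaxes(g, -1, -2)), -1, -2)
        x._accumulate(axis_adj(d).astype(ag.DTYPE))

    return ag._make(data, (x,), backward)


class UpBlock(nn.Module):
    """x2 spatial upsampling with a channel change: transposed conv by
    default, or bilinear interpolation followed by a 3x3 conv."""

    def __init__(self, cin: int, cout: int, rng, mode: str = "transposed"):
        super().__init__()
        self.mode = mode
        if mode == "transposed":
            self.op = nn.ConvTranspose2d(cin, cout, 2, rng, stride=2)
        else:
            self.op = nn.Conv2d(cin, cout, 3, rng, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "transposed":
            return self.op(x)
        return self.op(_upsample2x_bilinear(x))


class DoubleConv(nn.Module):
    def __init__(self, cin: int, cout: int, rng, batch_norm: bool = False):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, padding=1)
        self.bn1 = nn.BatchNorm2d(cout) if batch_norm else None
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, padding=1)
        self.bn2 = nn.BatchNorm2d(cout) if batch_norm else None

    def forward(self, x: Tensor) -> Tensor:
        x = self.conv1(x)
        if self.bn1 is not None:
            x = self.bn1(x)
        x = ag.relu(x)
        x = self.conv2(x)
        if self.bn2 is not None:
            x = self.bn2(x)
        return ag.relu(x)


class _UNetDecoder(nn.Module):
    """Shared U-Net decoder: per level ConvT/bilinear up, skip concat,
    double conv.  ``skip_channels`` lists encoder tap widths, deepest first."""

    def __init__(self, cin: int, skip_channels: list[int],
                 out_channels: list[int], rng, mode: str,
                 final_up: bool = False):
        super().__init__()
        self.ups: list[nn.Module] = []
        self.blocks: list[nn.Module] = []
        ch = cin
        for skip_ch, out_ch in zip(skip_channels, out_channels):
            self.ups.append(UpBlock(ch, out_ch, rng, mode))
            self.blocks.append(DoubleConv(out_ch + skip_ch, out_ch, rng))
            ch = out_ch
        self.final_up = None
        self.final_block = None
        if final_up:
            self.final_up = UpBlock(ch, ch, rng, mode)
            self.final_block = DoubleConv(ch, ch, rng)
        self.out_channels = ch

    def forward(self, x: Tensor, skips: list[Tensor],
                use_skips: bool = True) -> Tensor:
        for up, block, skip in zip(self.ups, self.blocks, skips):
            x = up(x)
            if not use_skips:
                skip = ag.scale(skip, 0.0)
            x = ag.concat([skip, x], axis=1)
            x = block(x)
        if self.final_up is not None:
            x = self.final_block(self.final_up(x))
        return x


class UNetNet(nn.Module):
    def __init__(self, spec: ArchitectureSpec, rng):
        super().__init__()
        b, d = spec.base_channels, spec.depth
        widths = [b * 2 ** i for i in range(d)]
        self.encoder: list[nn.Module] = []
        cin = 3
        for wch in widths:
            self.encoder.append(DoubleConv(cin, wch, rng))
            cin = wch
        self.bottleneck = DoubleConv(widths[-1], b * 2 ** d, rng)
        self.decoder = _UNetDecoder(b * 2 ** d, widths[::-1], widths[::-1],
                                    rng, spec.upsample)
        self.head = nn.Conv2d(widths[0], 1, 1, rng)
        self.use_skips = True
        self.n_skips = d

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for block in self.encoder:
            x = block(x)
            skips.append(x)
            x = ag.max_pool2d(x, 2)
        x = self.bottleneck(x)
        x = self.decoder(x, skips[::-1], self.use_skips)
        return self.head(x)


class TransformerBottleneck(nn.Module):
    """Tokenise the deepest feature map (one token per spatial position),
    add learned positional embeddings, run pre-norm transformer blocks,
    and reshape back to a spatial map."""

    def __init__(self, cin: int, dim: int, grid: tuple[int, int],
                 cfg: TransformerConfig, rng):
        super().__init__()
        self.grid = grid
        self.n_tokens = grid[0] * grid[1]
        self.dim = dim
        self.proj = nn.Conv2d(cin, dim, 1, rng)
        self.pos_embed = nn.Parameter(
            rng.normal(0, 0.02, size=(1, self.n_tokens, dim)).astype(ag.DTYPE))
        self.blocks: list[nn.Module] = []
        mlp = int(cfg.mlp_ratio * dim)
        for _ in range(cfg.n_blocks):
            blk = nn.Module()
            blk.ln1 = nn.LayerNorm(dim)
            blk.attn = nn.MultiHeadSelfAttention(dim, cfg.n_heads, rng)
            blk.ln2 = nn.LayerNorm(dim)
            blk.fc1 = nn.Linear(dim, mlp, rng)
            blk.fc2 = nn.Linear(mlp, dim, rng)
            self.blocks.append(blk)
        self.ln_out = nn.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        b = x.shape[0]
        gh, gw = self.grid
        x = self.proj(x)                                   # B,D,gh,gw
        t = ag.reshape(x, (b, self.dim, self.n_tokens))
        t = ag.transpose(t, (0, 2, 1))                     # B,N,D
        t = ag.add(t, self.pos_embed)
        for blk in self.blocks:
            t = ag.add(t, blk.attn(blk.ln1(t)))
            h = blk.fc2(ag.relu(blk.fc1(blk.ln2(t))))
            t = ag.add(t, h)
        t = self.ln_out(t)
        t = ag.transpose(t, (0, 2, 1))
        return ag.reshape(t, (b, self.dim, gh, gw))


class CTUNet(UNetNet):
    def __init__(self, spec: ArchitectureSpec, rng):
        super().__init__(spec, rng)
        b, d = spec.base_channels, spec.depth
        grid = (spec.input_size[0] // 2 ** d, spec.input_size[1] // 2 ** d)
        self.bottleneck = TransformerBottleneck(
            b * 2 ** (d - 1), b * 2 ** d, grid, spec.transformer, rng)


class ResNetBottleneckBlock(nn.Module):
    """1x1 -> 3x3 -> 1x1 bottleneck residual block with batch norm and a
    projection shortcut when shape changes (expansion factor 4)."""

    def __init__(self, cin: int, mid: int, rng, stride: int = 1):
        super().__init__()
        cout = 4 * mid
        self.conv1 = nn.Conv2d(cin, mid, 1, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, 3, rng, stride=stride, padding=1,
                               bias=False)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, cout, 1, rng, bias=False)
        self.bn3 = nn.BatchNorm2d(cout)
        self.proj = None
        self.proj_bn = None
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, rng, stride=stride, bias=False)
            self.proj_bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        out = ag.relu(self.bn1(self.conv1(x)))
        out = ag.relu(self.bn2(self.conv2(out)))
        out = self.bn3(self.conv3(out))
        short = x if self.proj is None else self.proj_bn(self.proj(x))
        return ag.relu(ag.add(out, short))


class ResNet50Encoder(nn.Module):
    """Canonical ResNet50 feature extractor scaled by ``base_channels``.

    ``forward`` returns taps at strides 2 (stem), 4, 8, 16 and the final
    stride-32 map; widths are b, 4b, 8b, 16b, 32b.
    """

    BLOCK_COUNTS = (3, 4, 6, 3)

    def __init__(self, b: int, rng):
        super().__init__()
        self.stem = nn.Conv2d(3, b, 7, rng, stride=2, padding=3, bias=False)
        self.stem_bn = nn.BatchNorm2d(b)
        self.stages: list[list[nn.Module]] = []
        cin = b
        for i, n_blocks in enumerate(self.BLOCK_COUNTS):
            mid = b * 2 ** i
            stride = 1 if i == 0 else 2
            blocks = [ResNetBottleneckBlock(cin, mid, rng, stride=stride)]
            cin = 4 * mid
            blocks += [ResNetBottleneckBlock(cin, mid, rng)
                       for _ in range(n_blocks - 1)]
            self.stages.append(blocks)
        self.tap_channels = [b, 4 * b, 8 * b, 16 * b, 32 * b]

    def forward(self, x: Tensor) -> list[Tensor]:
        x = ag.relu(self.stem_bn(self.stem(x)))
        taps = [x]                       # stride 2
        x = ag.max_pool2d(x, 2)          # stride 4
        for stage in self.stages:
            for block in stage:
                x = block(x)
            taps.append(x)               # strides 4, 8, 16, 32
        return taps


class PyramidPooling(nn.Module):
    """Parallel 3x3 convolutions at several dilation rates, concatenated
    and fused by a 1x1 conv (multi-scale context at the bottleneck)."""

    def __init__(self, cin: int, branch_ch: int, cout: int,
                 dilations: tuple[int, ...], rng):
        super().__init__()
        self.branches = [nn.Conv2d(cin, branch_ch, 3, rng, padding=d,
                                   dilation=d) for d in dilations]
        self.fuse = nn.Conv2d(branch_ch * len(dilations), cout, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        outs = [ag.relu(b(x)) for b in self.branches]
        return ag.relu(self.fuse(ag.concat(outs, axis=1)))


class _SingleConvBN(nn.Module):
    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 3, rng, padding=1, bias=False)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))


class ResNet50SegNet(nn.Module):
    def __init__(self, spec: ArchitectureSpec, rng):
        super().__init__()
        b = spec.base_channels
        self.encoder = ResNet50Encoder(b, rng)
        tc = self.encoder.tap_channels
        self.ppm = PyramidPooling(tc[4], 4 * b, 16 * b, spec.ppm_dilations, rng)
        mode = spec.upsample
        self.ups = [UpBlock(16 * b, 8 * b, rng, mode),
                    UpBlock(8 * b, 4 * b, rng, mode),
                    UpBlock(4 * b, 2 * b, rng, mode),
                    UpBlock(2 * b, b, rng, mode),
                    UpBlock(b, b, rng, mode)]
        self.blocks = [_SingleConvBN(8 * b + tc[3], 8 * b, rng),
                       _SingleConvBN(4 * b + tc[2], 4 * b, rng),
                       _SingleConvBN(2 * b + tc[1], 2 * b, rng),
                       _SingleConvBN(b + tc[0], b, rng),
                       _SingleConvBN(b, b, rng)]
        self.head = nn.Conv2d(b, 1, 1, rng)
        self.use_skips = True
        self.n_skips = 4

    def forward(self, x: Tensor) -> Tensor:
        taps = self.encoder(x)
        x = self.ppm(taps[4])
        skips = [taps[3], taps[2], taps[1], taps[0], None]
        for up, block, skip in zip(self.ups, self.blocks, skips):
            x = up(x)
            if skip is not None:
                if not self.use_skips:
                    skip = ag.scale(skip, 0.0)
                x = ag.concat([skip, x], axis=1)
            x = block(x)
        return self.head(x)


class UNetResNetBackboneNet(nn.Module):
    def __init__(self, spec: ArchitectureSpec, rng):
        super().__init__()
        b = spec.base_channels
        self.encoder = ResNet50Encoder(b, rng)
        tc = self.encoder.tap_channels
        self.decoder = _UNetDecoder(tc[4], [tc[3], tc[2], tc[1], tc[0]],
                                    [8 * b, 4 * b, 2 * b, b], rng,
                                    spec.upsample, final_up=True)
        self.head = nn.Conv2d(self.decoder.out_channels, 1, 1, rng)
        self.use_skips = True
        self.n_skips = 4

    def forward(self, x: Tensor) -> Tensor:
        taps = self.encoder(x)
        x = self.decoder(taps[4], [taps[3], taps[2], taps[1], taps[0]],
                         self.use_skips)
        return self.head(x)


# ---------------------------------------------------------------------------
# model wrapper and builders
# ---------------------------------------------------------------------------

class SegmentationModel:
    """A parameterised map from B×H×W×3 image batches to B×H×W×1 vessel
    probability maps, wrapping one of the four network topologies."""

    def __init__(self, spec: ArchitectureSpec, net: nn.Module):
        self.spec = spec
        self.net = net

    # -- forward -------------------------------------------------------------
    def logits(self, batch_nchw: Tensor) -> Tensor:
        return self.net(batch_nchw)

    def predict(self, batch: np.ndarray, chunk: int = 8) -> np.ndarray:
        """Inference-mode probabilities for a B×H×W×3 batch (deterministic:
        batch norm uses running statistics, no graph is recorded)."""
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim == 3:
            batch = batch[None]
        if batch.shape[1:3] != self.spec.input_size or batch.shape[3] != 3:
            raise DimensionMismatchError(
                f"batch shape {batch.shape[1:]} does not match spec input "
                f"{self.spec.input_size} + 3 channels")
        was_training = self.net.training
        self.net.eval()
        outs = []
        try:
            with ag.no_grad():
                for i in range(0, batch.shape[0], chunk):
                    x = Tensor(batch[i:i + chunk].transpose(0, 3, 1, 2))
                    z = self.net(x).data.astype(np.float64)
                    outs.append(expit(z))
        finally:
            self.net.train(was_training)
        probs = np.concatenate(outs, axis=0).transpose(0, 2, 3, 1)
        return np.clip(probs, 1e-12, 1.0 - 1e-12)

    forward = predict

    # -- parameter plumbing ----------------------------------------------------
    def parameters(self):
        return self.net.parameters()

    def named_parameters(self):
        return self.net.named_parameters()

    def trainable_parameters(self):
        return [p for p in self.net.parameters() if p.requires_grad]

    def parameter_hash(self) -> str:
        return self.net.parameter_hash()

    def freeze(self, prefix: str = "") -> None:
        """Mark parameters (optionally only those under ``prefix``, e.g.
        ``"encoder"``) as non-trainable."""
        for name, p in self.net.named_parameters():
            if name.startswith(prefix):
                p.requires_grad = False

    def train(self, mode: bool = True) -> "SegmentationModel":
        self.net.train(mode)
        return self

    def eval(self) -> "SegmentationModel":
        self.net.eval()
        return self


def n_parameters(model) -> int:
    net = model.net if isinstance(model, SegmentationModel) else model
    return int(sum(p.data.size for p in net.parameters()))


def _check(spec: ArchitectureSpec, expected: str) -> None:
    if spec.name != expected:
        raise ConfigurationError(
            f"spec.name is {spec.name!r}, builder expects {expected!r}")
    spec.validate()


def _maybe_load_backbone(spec: ArchitectureSpec, net: nn.Module) -> None:
    if not spec.pretrained_backbone:
        return
    if not spec.backbone_weights:
        raise ConfigurationError(
            "pretrained_backbone=True requires backbone_weights to point at "
            "a saved encoder state")
    state = dict(np.load(spec.backbone_weights))
    enc_state = {k[len("encoder."):]: v for k, v in state.items()
                 if k.startswith("encoder.")} or state
    net.encoder.load_state_dict(enc_state)


def build_unet(spec: ArchitectureSpec) -> SegmentationModel:
    _check(spec, "unet")
    rng = np.random.default_rng(spec.seed)
    return SegmentationModel(spec, UNetNet(spec, rng))


def build_ctu_net(spec: ArchitectureSpec) -> SegmentationModel:
    _check(spec, "ctu_net")
    rng = np.random.default_rng(spec.seed)
    return SegmentationModel(spec, CTUNet(spec, rng))


def build_resnet50_seg(spec: ArchitectureSpec) -> SegmentationModel:
    _check(spec, "resnet50_seg")
    rng = np.random.default_rng(spec.seed)
    net = ResNet50SegNet(spec, rng)
    _maybe_load_backbone(spec, net)
    return SegmentationModel(spec, net)


def build_unet_resnet_backbone(spec: ArchitectureSpec) -> SegmentationModel:
    _check(spec, "unet_resnet_backbone")
    rng = np.random.default_rng(spec.seed)
    net = UNetResNetBackboneNet(spec, rng)
    _maybe_load_backbone(spec, net)
    return SegmentationModel(spec, net)


_BUILDERS = {
    "unet": build_unet,
    "resnet50_seg": build_resnet50_seg,
    "unet_resnet_backbone": build_unet_resnet_backbone,
    "ctu_net": build_ctu_net,
}


def build_model(spec: ArchitectureSpec) -> SegmentationModel:
    spec.validate()
    return _BUILDERS[spec.name](spec)


def predict(model: SegmentationModel, batch: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`SegmentationModel.predict`."""
    return model.predict(batch)


def save_checkpoint(model: SegmentationModel, path) -> None:
    """Single-file parameter state keyed by layer path, with the spec
    embedded for reload validation."""
    state = model.net.state_dict()
    state["__spec__"] = np.frombuffer(
        json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path, expected_spec: ArchitectureSpec | None = None
                    ) -> SegmentationModel:
    archive = np.load(path)
    spec = ArchitectureSpec.from_dict(
        json.loads(archive["__spec__"].tobytes().decode()))
    if expected_spec is not None and spec != expected_spec:
        raise ConfigurationError("checkpoint spec does not match expectation")
    model = build_model(spec)
    state = {k: archive[k] for k in archive.files if k != "__spec__"}
    model.net.load_state_dict(state)
    return model
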