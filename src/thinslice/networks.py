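"""Generator and discriminator for slice-axis CT super-resolution.

The generator is an ESRGAN-style residual-in-residual dense network adapted
to volumetric data: 23 ResBlocks of 3D convolutions (64 channels, kernel 3,
stride 1, padding 1), each ResBlock holding two densely connected small
blocks of five convolutions with leaky-ReLU activations, local and global
residual connections with small residual scaling, then a channel-expanding
convolution, a VoxelShuffle-SG channel-to-depth rearrangement that creates
``r`` new slices per input slice, and two output convolutions.  The
discriminator stacks eight conv/LReLU pairs and two dense layers ending in a
sigmoid; it scores thin-slice realism (real -> 1, generated -> 0).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor


# ---------------------------------------------------------------------------
# VoxelShuffle-SG
# ---------------------------------------------------------------------------

def voxel_shuffle_sg(x, r: int):
    """Rearrange channels into depth: (b, c*r, h, w, d) -> (b, c, h, w, d*r).

    Channel-major interleave: ``out[b, c, h, w, d*r + k] == x[b, c*r + k, h,
    w, d]`` for ``k in [0, r)``.  A pure index permutation — the value
    multiset is preserved.  Works on numpy arrays and autodiff tensors.
    """
    r = int(r)
    if r < 1:
        raise ValueError("r must be >= 1")
    b, c, h, w, d = x.shape
    if c % r:
        raise ValueError(f"channel count {c} not divisible by r={r}")
    y = x.reshape((b, c // r, r, h, w, d))
    y = y.transpose((0, 1, 3, 4, 5, 2))
    return y.reshape((b, c // r, h, w, d * r))


def voxel_unshuffle_sg(x, r: int):
    """Exact inverse of :func:`voxel_shuffle_sg`."""
    r = int(r)
    b, c, h, w, dr = x.shape
    if dr % r:
        raise ValueError(f"depth {dr} not divisible by r={r}")
    y = x.reshape((b, c, h, w, dr // r, r))
    y = y.transpose((0, 1, 5, 2, 3, 4))
    return y.reshape((b, c * r, h, w, dr // r))


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Architecture hyperparameters of the slice-generation network.

    Defaults follow the full-scale network (23 ResBlocks, 64 channels,
    4x slice-axis scale).  ``growth_channels`` is the width of the dense
    connections inside a small block; ``residual_beta`` scales every local
    and block-level residual branch; ``interp_skip`` adds a trilinear
    depth-upsampling skip from input to output so the network learns a
    residual on top of linear interpolation.
    """
    n_resblocks: int = 23
    base_channels: int = 64
    growth_channels: int = 32
    kernel: int = 3
    scale: int = 4
    residual_beta: float = 0.2
    lrelu_slope: float = 0.2
    interp_skip: bool = True
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_resblocks, self.base_channels, self.growth_channels,
               self.kernel, self.scale) < 1:
            raise ValueError("all GeneratorConfig sizes must be positive")
        if not (0.0 < self.residual_beta <= 1.0):
            raise ValueError("residual_beta must lie in (0, 1]")


class SmallBlock(nn.Module):
    """Five convolutions with dense connections; LReLU after the first four.

    The input of convolution i is the concatenation of the block input and
    the outputs of convolutions 1..i-1 (each ``growth_channels`` wide); the
    fifth convolution maps back to ``base_channels`` and a residual scaled by
    beta closes the block.
    """

    def __init__(self, cfg: GeneratorConfig, rng):
        c, g, k = cfg.base_channels, cfg.growth_channels, cfg.kernel
        pad = (k // 2,) * 3
        self.convs = [
            nn.Conv3d(c + i * g, g if i < 4 else c, kernel=(k, k, k),
                      padding=pad, rng=rng, init_scale=cfg.init_scale)
            for i in range(5)
        ]
        self.beta = cfg.residual_beta
        self.slope = cfg.lrelu_slope

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for i, conv in enumerate(self.convs):
            inp = feats[0] if len(feats) == 1 else nn.concat(feats, axis=1)
            y = conv(inp)
            if i < 4:
                y = nn.leaky_relu(y, self.slope)
            feats.append(y)
        return x + self.beta * feats[-1]


class ResBlock(nn.Module):
    """Two small blocks with a central residual around the pair."""

    def __init__(self, cfg: GeneratorConfig, rng):
        self.blocks = [SmallBlock(cfg, rng), SmallBlock(cfg, rng)]
        self.beta = cfg.residual_beta

    def forward(self, x: Tensor) -> Tensor:
        y = self.blocks[1](self.blocks[0](x))
        return x + self.beta * y


class Generator(nn.Module):
    """Thick-to-thin slice generator over (batch, 1, h, w, d) tensors."""

    def __init__(self, cfg: GeneratorConfig):
        rng = np.random.default_rng(cfg.seed)
        c, k, r = cfg.base_channels, cfg.kernel, cfg.scale
        pad = (k // 2,) * 3
        self.cfg = cfg
        self.conv_first = nn.Conv3d(1, c, kernel=(k, k, k), padding=pad,
                                    rng=rng, init_scale=cfg.init_scale)
        self.trunk = [ResBlock(cfg, rng) for _ in range(cfg.n_resblocks)]
        self.conv_up = nn.Conv3d(c, c * r, kernel=(k, k, k), padding=pad,
                                 rng=rng, init_scale=cfg.init_scale)
        self.conv_hr = nn.Conv3d(c, c, kernel=(k, k, k), padding=pad,
                                 rng=rng, init_scale=cfg.init_scale)
        self.conv_last = nn.Conv3d(c, 1, kernel=(k, k, k), padding=pad,
                                   rng=rng, init_scale=cfg.init_scale)

    def forward(self, x: Tensor) -> Tensor:
        if not np.all(np.isfinite(x.data)):
            raise ValueError("generator input contains non-finite values")
        cfg = self.cfg
        feat = self.conv_first(x)
        y = feat
        for block in self.trunk:
            y = block(y)
        # global residual: first-ResBlock input added to last-ResBlock output
        y = feat + y
        y = self.conv_up(y)
        y = voxel_shuffle_sg(y, cfg.scale)
        y = nn.leaky_relu(self.conv_hr(y), cfg.lrelu_slope)
        out = self.conv_last(y)
        if cfg.interp_skip:
            out = out + nn.upsample_depth_linear(x, cfg.scale)
        return out


# ---------------------------------------------------------------------------
# Discriminator
# ---------------------------------------------------------------------------

@dataclass
class DiscriminatorConfig:
    """Eight conv/LReLU pairs, then dense layers 1024 -> 1 -> sigmoid.

    Channels double every second pair and stride-2 pairs halve each spatial
    axis; the dense fan-in is derived from ``input_patch_shape`` (in
    super-resolved space).
    """
    n_conv_pairs: int = 8
    base_channels: int = 64
    dense_width: int = 1024
    input_patch_shape: tuple = (64, 64, 32)
    lrelu_slope: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_conv_pairs < 1 or self.dense_width < 1:
            raise ValueError("invalid DiscriminatorConfig")
        self.input_patch_shape = tuple(int(s) for s in self.input_patch_shape)


class Discriminator(nn.Module):
    def __init__(self, cfg: DiscriminatorConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        chans, convs = [], []
        c_in = 1
        shape = np.array(cfg.input_patch_shape, dtype=int)
        for i in range(cfg.n_conv_pairs):
            c_out = cfg.base_channels * (2 ** (i // 2))
            stride = 1 if i % 2 == 0 else 2
            convs.append(nn.Conv3d(c_in, c_out, kernel=(3, 3, 3),
                                   stride=(stride,) * 3, padding=(1, 1, 1),
                                   rng=rng, init_scale=1.0))
            if stride == 2:
                shape = (shape + 1) // 2
            chans.append(c_out)
            c_in = c_out
        if shape.min() < 1:
            raise ValueError("input_patch_shape too small for conv stack")
        self.convs = convs
        self.slope = cfg.lrelu_slope
        self._fan_in = int(c_in * int(np.prod(shape)))
        self.dense1 = nn.Linear(self._fan_in, cfg.dense_width, rng=rng)
        self.dense2 = nn.Linear(cfg.dense_width, 1, rng=rng)

    def forward_logit(self, x: Tensor) -> Tensor:
        if x.shape[2:] != self.cfg.input_patch_shape:
            raise ValueError(
                f"discriminator expects patch shape "
                f"{self.cfg.input_patch_shape}, got {x.shape[2:]}")
        y = x
        for conv in self.convs:
            y = nn.leaky_relu(conv(y), self.slope)
        y = y.reshape((y.shape[0], -1))
        y = nn.leaky_relu(self.dense1(y), self.slope)
        return self.dense2(y)

    def forward(self, x: Tensor) -> Tensor:
        """Realism score in (0, 1): real thin slices -> 1, generated -> 0."""
        return nn.sigmoid(self.forward_logit(x))


# ---------------------------------------------------------------------------
# Perceptual feature extractor
# ---------------------------------------------------------------------------

@dataclass
class FeatureExtractorSpec:
    """Slice-wise 2D feature map phi_{i,j}: features after the j-th
    convolution of stage i of a VGG16-style stack (before the i-th pool).

    ``width_scale`` shrinks the canonical 64/128/256 stage widths; the
    bundled extractor uses fixed-seed random weights so no pretrained
    download is required.
    """
    layer: tuple = (3, 3)
    width_scale: float = 0.125
    seed: int = 0


_VGG16_STAGES = ((64, 2), (128, 2), (256, 3), (512, 3), (512, 3))


class VGGFeatures(nn.Module):
    """VGG16-topology 2D feature extractor applied per slice.

    Input: (n_slices, 1, h, w, 1) single-channel slices in [0, 1]; they are
    replicated to three channels as a 2D classification stack expects.
    """

    def __init__(self, spec: FeatureExtractorSpec):
        i_stage, j_conv = spec.layer
        if not (1 <= i_stage <= len(_VGG16_STAGES)):
            raise ValueError("stage index out of range")
        if not (1 <= j_conv <= _VGG16_STAGES[i_stage - 1][1]):
            raise ValueError("conv index out of range for stage")
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.convs = []
        self._plan = []  # (conv_idx, pool_after)
        c_in = 3
        for s in range(i_stage):
            width, n_conv = _VGG16_STAGES[s]
            width = max(1, int(round(width * spec.width_scale)))
            n = n_conv if s < i_stage - 1 else j_conv
            for j in range(n):
                self.convs.append(nn.Conv3d(c_in, width, kernel=(3, 3, 1),
                                            padding=(1, 1, 0), rng=rng,
                                            init_scale=1.0))
                c_in = width
            self._plan.append(n)

    def forward(self, x: Tensor) -> Tensor:
        y = nn.concat([x, x, x], axis=1)
        ci = 0
        n_stages = len(self._plan)
        for s, n in enumerate(self._plan):
            for _ in range(n):
                y = nn.relu(self.convs[ci](y))
                ci += 1
            if s < n_stages - 1:
                y = nn.maxpool_hw(y)
        return y


# ---------------------------------------------------------------------------
# Builders (stable functional surface)
# ---------------------------------------------------------------------------

def build_generator(cfg: GeneratorConfig | None = None) -> Generator:
    return Generator(cfg or GeneratorConfig())


def build_discriminator(cfg: DiscriminatorConfig | None = None) -> Discriminator:
    return Discriminator(cfg or DiscriminatorConfig())


def generator_forward(net: Generator, lr_chunk: np.ndarray) -> np.ndarray:
    """Inference forward pass on a (1, 1, h, w, d) array; returns
    (1, 1, h, w, d*r).  Runs without graph construction."""
    with nn.no_grad():
        out = net(Tensor(np.asarray(lr_chunk, dtype=np.float32)))
    return out.data


def discriminator_forward(net: Discriminator, patch: np.ndarray) -> float:
    with nn.no_grad():
        score = net(Tensor(np.asarray(patch, dtype=np.float32)))
    return float(score.data.reshape(-1)[0])


def generator_config_dict(cfg: GeneratorConfig) -> dict:
    return asdict(cfg)
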