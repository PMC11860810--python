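"""Training losses: voxel-wise MSE, slice-wise perceptual loss, adversarial
generator loss, discriminator binary cross-entropy, and the weighted total.

The MSE term is the mean squared HU (or unit-scale) difference over the
``r*D x H x W`` super-resolved grid.  The perceptual term feeds volumes to a
2D feature extractor slice by slice — each slice's feature distance is the
mean squared feature difference normalised by the feature-map size — and
averages over slices.  The adversarial generator term sums ``-log D(G(lr))``
over the batch, pushing generated scores toward the "real" label 1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .networks import FeatureExtractorSpec, VGGFeatures


@dataclass
class LossWeights:
    """Combination weights for the total generator loss (ESRGAN-style
    defaults: perceptual-dominated, small MSE anchor, tiny adversarial)."""

    mse: float = 0.01
    perceptual: float = 1.0
    adversarial: float = 0.005

    def __post_init__(self):
        if min(self.mse, self.perceptual, self.adversarial) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.mse == self.perceptual == self.adversarial == 0:
            raise ValueError("at least one loss weight must be positive")


# ---------------------------------------------------------------------------
# numpy-facing loss values (reporting / tests)
# ---------------------------------------------------------------------------

def mse_loss(gt: np.ndarray, gen: np.ndarray) -> float:
    """Mean squared voxel difference; symmetric, zero iff gen == gt."""
    gt = np.asarray(gt, dtype=np.float64)
    gen = np.asarray(gen, dtype=np.float64)
    if gt.shape != gen.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {gen.shape}")
    return float(np.mean((gt - gen) ** 2))


def perceptual_loss(gt: np.ndarray, gen: np.ndarray,
                    extractor: VGGFeatures | None = None,
                    slice_axis: int = -1) -> float:
    """Mean over slices of the normalised squared feature distance.

    ``gt``/``gen`` are 3D (h, w, d) arrays on the unit intensity scale;
    slices are taken along ``slice_axis`` (default: depth, the slice-stacking
    axis of the network tensors).  When no extractor is given the bundled
    fixed-seed random-weight extractor is used.
    """
    gt = np.asarray(gt, dtype=np.float32)
    gen = np.asarray(gen, dtype=np.float32)
    if gt.shape != gen.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {gen.shape}")
    if gt.ndim != 3:
        raise ValueError("perceptual_loss expects 3D (h, w, d) volumes")
    if extractor is None:
        extractor = default_extractor()
    gt_t = Tensor(_slices_to_batch(gt, slice_axis))
    gen_t = Tensor(_slices_to_batch(gen, slice_axis))
    with nn.no_grad():
        fg = extractor(gt_t).data.astype(np.float64)
        fe = extractor(gen_t).data.astype(np.float64)
    per_slice = ((fg - fe) ** 2).mean(axis=(1, 2, 3, 4))
    return float(per_slice.mean())


def adversarial_generator_loss(scores) -> float:
    """Sum over the batch of -log D(G(I_LR)); scores must lie in (0, 1)."""
    s = np.asarray(scores, dtype=np.float64).reshape(-1)
    if s.size < 1:
        raise ValueError("need at least one score")
    if np.any(s <= 0.0) or np.any(s >= 1.0):
        raise ValueError("scores must lie strictly in (0, 1)")
    return float(-np.log(s).sum())


def discriminator_loss(real_scores, fake_scores) -> float:
    """Binary cross-entropy with real -> 1, generated -> 0 labels."""
    r = np.asarray(real_scores, dtype=np.float64).reshape(-1)
    f = np.asarray(fake_scores, dtype=np.float64).reshape(-1)
    for s in (r, f):
        if s.size < 1:
            raise ValueError("need at least one score")
        if np.any(s <= 0.0) or np.any(s >= 1.0):
            raise ValueError("scores must lie strictly in (0, 1)")
    return float(-np.log(r).mean() - np.log(1.0 - f).mean())


def total_generator_loss(components, weights: LossWeights | None = None) -> float:
    """Weighted sum of (mse, perceptual, adversarial) components."""
    w = weights or LossWeights()
    l_mse, l_perc, l_adv = (float(c) for c in components)
    return w.mse * l_mse + w.perceptual * l_perc + w.adversarial * l_adv


# ---------------------------------------------------------------------------
# autodiff-facing versions (training path)
# ---------------------------------------------------------------------------

def mse_loss_t(gt: Tensor, gen: Tensor) -> Tensor:
    d = gt + (-1.0) * gen
    return nn.mean(nn.square(d))


def perceptual_loss_t(gt: Tensor, gen: Tensor,
                      extractor: VGGFeatures) -> Tensor:
    """Slice-wise feature distance for 5-axis (b, 1, h, w, d) tensors,
    slicing along depth, differentiable through ``gen``."""
    fg = extractor(_tensor_slices_to_batch(gt))
    fe = extractor(_tensor_slices_to_batch(gen))
    d = fg + (-1.0) * fe
    return nn.mean(nn.square(d))


def generator_adversarial_loss_t(fake_logits: Tensor) -> Tensor:
    """Sum of -log sigmoid(logit): the stable form of Eq-style
    ``sum -log D(G)``."""
    return nn.sum_(nn.softplus((-1.0) * fake_logits))


def discriminator_loss_t(real_logits: Tensor, fake_logits: Tensor) -> Tensor:
    return nn.mean(nn.softplus((-1.0) * real_logits)) + \
        nn.mean(nn.softplus(fake_logits))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_DEFAULT_EXTRACTOR: VGGFeatures | None = None


def default_extractor() -> VGGFeatures:
    """The bundled fixed-seed random-weight extractor (cached)."""
    global _DEFAULT_EXTRACTOR
    if _DEFAULT_EXTRACTOR is None:
        _DEFAULT_EXTRACTOR = VGGFeatures(FeatureExtractorSpec())
    return _DEFAULT_EXTRACTOR


def _slices_to_batch(vol: np.ndarray, slice_axis: int) -> np.ndarray:
    """(h, w, d) -> (n_slices, 1, a, b, 1) stack of 2D slices."""
    moved = np.moveaxis(vol, slice_axis, 0)
    return moved[:, None, :, :, None]


def _tensor_slices_to_batch(x: Tensor) -> Tensor:
    """(b, 1, h, w, d) -> (b*d, 1, h, w, 1), differentiable."""
    b, c, h, w, d = x.shape
    y = x.transpose((0, 4, 1, 2, 3))   # (b, d, 1, h, w)
    return y.reshape((b * d, c, h, w, 1))
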