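"""Adversarial training of the slice-generation network, checkpointing, and
whole-volume inference.

Training pairs are produced on the fly: a ground-truth thin-slice patch is
sampled from a training volume and degraded by slice averaging into its
thick-slice counterpart.  Each iteration updates the discriminator on
(real, generated) patches with real -> 1 / generated -> 0 labels, then the
generator on the weighted MSE + perceptual + adversarial loss.  The first
10% of iterations are an MSE-only generator warm-up.  Given a seed the run
is deterministic on one device.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import nn
from .losses import (LossWeights, discriminator_loss_t,
                     generator_adversarial_loss_t, mse_loss_t,
                     perceptual_loss_t)
from .networks import (DiscriminatorConfig, FeatureExtractorSpec, Generator,
                       GeneratorConfig, VGGFeatures, build_discriminator,
                       build_generator)
from .nn import Tensor
from .volume import CTVolume, chunk_z, hu_to_unit, stitch_z, unit_to_hu


@dataclass
class TrainConfig:
    """Hyperparameters of a (desk-scale by default) training run.

    ``lr_patch`` is the low-resolution patch shape (h, w, d); d may not
    exceed 16, the deepest chunk the network consumes.  All randomness
    derives from ``seed``.

    The default loss weighting is MSE-dominant with a long MSE-only
    warm-up: the bundled perceptual extractor carries random weights, whose
    feature scale is not comparable to a pretrained classification
    network's, so at desk scale the voxel term anchors optimization and the
    perceptual/adversarial terms fine-tune.  Gradients are global-norm
    clipped on both networks.

    Two choices target slice-axis edge restoration, the property nodule
    volumetry depends on: the fidelity term adds a depth-gradient MSE
    (``slice_gradient_weight``), and patch sampling draws
    ``edge_patch_candidates`` candidates and keeps the one with the highest
    depth-gradient energy in the ground truth, so flat lung interior does
    not dominate the training signal.
    """

    seed: int = 0
    learning_rate_g: float = 3e-3
    learning_rate_d: float = 3e-4
    iterations: int = 200
    lr_patch: tuple = (16, 16, 8)
    batch_size: int = 4
    loss_weights: LossWeights = field(
        default_factory=lambda: LossWeights(mse=1.0, perceptual=0.1,
                                            adversarial=1e-5))
    r: int = 4
    checkpoint_every: int = 50
    validation_fraction: float = 0.0
    warmup_fraction: float = 0.5
    grad_clip_norm: float = 1.0
    slice_gradient_weight: float = 4.0
    edge_patch_candidates: int = 4
    generator: GeneratorConfig | None = None
    discriminator: DiscriminatorConfig | None = None
    extractor: FeatureExtractorSpec | None = None

    def __post_init__(self):
        self.lr_patch = tuple(int(v) for v in self.lr_patch)
        if self.lr_patch[2] > 16:
            raise ValueError("lr_patch depth may not exceed 16")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.generator is None:
            # desk-scale generator: small trunk, same topology
            self.generator = GeneratorConfig(
                n_resblocks=2, base_channels=16, growth_channels=8,
                scale=self.r, seed=self.seed)
        if self.generator.scale != self.r:
            raise ValueError("generator scale must equal degradation factor")
        hr_shape = (self.lr_patch[0], self.lr_patch[1],
                    self.lr_patch[2] * self.r)
        if self.discriminator is None:
            self.discriminator = DiscriminatorConfig(
                base_channels=8, dense_width=128,
                input_patch_shape=hr_shape, seed=self.seed + 1)
        if self.extractor is None:
            self.extractor = FeatureExtractorSpec(seed=self.seed + 2)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(ckpt: dict, path) -> None:
    arrays = {f"param/{k}": v for k, v in ckpt["generator_state"].items()}
    meta = {"config": asdict(ckpt["config"]), "seed": ckpt.get("seed", 0),
            "r": ckpt["r"], "kind": ckpt.get("kind", "generator")}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> dict:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    cfg = GeneratorConfig(**meta["config"])
    return {"kind": meta.get("kind", "generator"), "generator_state": state,
            "config": cfg, "seed": meta.get("seed", 0), "r": meta["r"]}


def checkpoint_from_generator(gen: Generator, seed: int = 0) -> dict:
    return {"kind": "generator", "generator_state": gen.state_dict(),
            "config": gen.cfg, "seed": seed, "r": gen.cfg.scale}


def nearest_repeat_checkpoint(r: int) -> dict:
    """Stub generator: each thick slice repeated r times (no network)."""
    return {"kind": "nearest", "r": int(r)}


def interpolation_checkpoint(r: int, order: int = 3) -> dict:
    """Baseline generator: spline depth-upsampling (1 = trilinear,
    3 = tricubic) instead of a network."""
    return {"kind": "interp", "r": int(r), "order": int(order)}


def generator_from_checkpoint(ckpt: dict) -> Generator:
    gen = build_generator(ckpt["config"])
    gen.load_state_dict(ckpt["generator_state"])
    return gen


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _sample_patch_pair(rng, units, cfg: TrainConfig):
    """One (lr, gt) unit-scale patch pair from a random training volume.

    Draws ``edge_patch_candidates`` candidate positions and keeps the one
    whose ground-truth patch has the largest slice-axis gradient energy.
    """
    h, w, d = cfg.lr_patch
    r = cfg.r
    best = None
    best_energy = -1.0
    for _ in range(max(1, cfg.edge_patch_candidates)):
        vol = units[rng.integers(len(units))]
        zt, yt, xt = vol.shape
        if yt < h or xt < w or zt < d * r:
            raise ValueError(
                f"lr_patch {cfg.lr_patch} (x{r} in z) exceeds volume "
                f"{vol.shape}")
        k = rng.integers(zt // r - d + 1)
        y0 = rng.integers(yt - h + 1)
        x0 = rng.integers(xt - w + 1)
        gt = vol[k * r:(k + d) * r, y0:y0 + h, x0:x0 + w]
        energy = float(np.mean(np.diff(gt, axis=0) ** 2))
        if energy > best_energy:
            best_energy = energy
            best = gt
    lr = best.reshape(d, r, h, w).mean(axis=1)
    # (z, y, x) -> (h, w, depth=z)
    return lr.transpose(1, 2, 0), best.transpose(1, 2, 0)


def _batch(rng, units, cfg: TrainConfig):
    lrs, gts = zip(*(_sample_patch_pair(rng, units, cfg)
                     for _ in range(cfg.batch_size)))
    return (np.stack(lrs)[:, None].astype(np.float32),
            np.stack(gts)[:, None].astype(np.float32))


def train(cfg: TrainConfig, thin_volumes, out_dir=None, resume_from=None):
    """Train on thin-slice volumes; returns (checkpoint, history frame).

    ``history`` has one row per iteration with every loss component; when
    ``validation_fraction`` > 0 the trailing volumes are held out and their
    patch MSE is logged at checkpoint cadence together with a plateau flag.
    ``resume_from`` continues from an earlier checkpoint's generator
    weights (a staged run: optimizer state restarts, the warm-up schedule
    applies to the new stage).
    """
    if not thin_volumes:
        raise ValueError("need at least one training volume")
    units = [hu_to_unit(v.voxels, v.intensity_range) for v in thin_volumes]
    n_val = int(round(cfg.validation_fraction * len(units)))
    val_units = units[len(units) - n_val:] if n_val else []
    units = units[:len(units) - n_val] if n_val else units
    if not units:
        raise ValueError("validation split left no training volumes")

    rng = np.random.default_rng(cfg.seed)
    if resume_from is not None:
        if int(resume_from["r"]) != cfg.r:
            raise ValueError("resume checkpoint r mismatch")
        gen = build_generator(resume_from["config"])
        gen.load_state_dict(resume_from["generator_state"])
    else:
        gen = build_generator(cfg.generator)
    disc = build_discriminator(cfg.discriminator)
    extractor = VGGFeatures(cfg.extractor)
    opt_g = nn.Adam(gen.parameters(), lr=cfg.learning_rate_g)
    opt_d = nn.Adam(disc.parameters(), lr=cfg.learning_rate_d)
    warmup = int(np.ceil(cfg.warmup_fraction * cfg.iterations))
    w = cfg.loss_weights

    rows = []
    val_hist = []
    for it in range(cfg.iterations):
        lr_np, gt_np = _batch(rng, units, cfg)
        lr_t, gt_t = Tensor(lr_np), Tensor(gt_np)
        in_warmup = it < warmup

        l_d = 0.0
        if not in_warmup:
            fake = gen(lr_t)
            fake_det = fake.detach()
            disc.zero_grad()
            d_loss = discriminator_loss_t(disc.forward_logit(gt_t),
                                          disc.forward_logit(fake_det))
            d_loss.backward()
            nn.clip_grad_norm(disc.parameters(), cfg.grad_clip_norm)
            opt_d.step()
            l_d = d_loss.item()

        gen.zero_grad()
        disc.zero_grad()
        out = gen(lr_t)
        l_mse_t = mse_loss_t(gt_t, out)
        fidelity = l_mse_t
        if cfg.slice_gradient_weight > 0:
            l_grad_t = mse_loss_t(nn.depth_diff(gt_t), nn.depth_diff(out))
            fidelity = fidelity + cfg.slice_gradient_weight * l_grad_t
        if in_warmup:
            total = fidelity
            l_perc = l_adv = 0.0
        else:
            l_perc_t = perceptual_loss_t(gt_t, out, extractor)
            l_adv_t = generator_adversarial_loss_t(disc.forward_logit(out))
            total = w.mse * fidelity + w.perceptual * l_perc_t \
                + w.adversarial * l_adv_t
            l_perc, l_adv = l_perc_t.item(), l_adv_t.item()
        total.backward()
        nn.clip_grad_norm(gen.parameters(), cfg.grad_clip_norm)
        opt_g.step()

        row = {"iteration": it, "l_mse": l_mse_t.item(), "l_perc": l_perc,
               "l_adv_g": l_adv, "l_d": l_d, "total": total.item()}
        if not all(np.isfinite(v) for v in row.values()):
            raise FloatingPointError(f"non-finite loss at iteration {it}: {row}")
        rows.append(row)

        if val_units and ((it + 1) % cfg.checkpoint_every == 0
                          or it + 1 == cfg.iterations):
            val_hist.append(_validation_mse(gen, val_units, cfg))

    history = pd.DataFrame(rows)
    plateau = bool(len(val_hist) >= 2
                   and val_hist[-1] > 0.995 * val_hist[-2])
    ckpt = checkpoint_from_generator(gen, seed=cfg.seed)
    ckpt["validation_mse"] = val_hist
    ckpt["validation_plateau"] = plateau
    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        save_checkpoint(ckpt, os.path.join(out_dir, "generator.npz"))
        history.to_csv(os.path.join(out_dir, "history.csv"), index=False)
    return ckpt, history


def _validation_mse(gen: Generator, val_units, cfg: TrainConfig) -> float:
    rng = np.random.default_rng(12345)
    errs = []
    for _ in range(4):
        lr_np, gt_np = _batch(rng, val_units, cfg)
        with nn.no_grad():
            out = gen(Tensor(lr_np)).data
        errs.append(float(np.mean((out - gt_np) ** 2)))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# whole-volume inference
# ---------------------------------------------------------------------------

def generate(checkpoint: dict, thick_vol: CTVolume, r: int | None = None,
             segment_length_z: int = 16, overlap_z: int = 2,
             data_consistency: bool = False) -> CTVolume:
    """Generate a thin-slice volume from a thick-slice one.

    The volume is chunked into 16-slice z segments, each segment is pushed
    through the generator, and the outputs are cross-fade stitched; slice
    spacing shrinks from dz to dz/r.

    With ``data_consistency`` the stitched output is projected onto the
    degradation constraint: every group of r generated slices is shifted by
    a constant so its mean equals the corresponding thick input slice.  The
    projection lowers voxel error (the true thin volume satisfies the
    constraint exactly) but the constant-per-group shift re-smears
    restored edges within a group, which measurably degrades downstream
    threshold volumetry — hence off by default.
    """
    ckpt_r = int(checkpoint["r"])
    if r is not None and int(r) != ckpt_r:
        raise ValueError(f"requested r={r} but checkpoint was trained "
                         f"with r={ckpt_r}")
    r = ckpt_r
    if checkpoint.get("kind") == "interp":
        from .degrade import upsample_z
        return upsample_z(thick_vol, r, order=checkpoint.get("order", 3))
    if checkpoint.get("kind") == "nearest":
        vox = np.repeat(thick_vol.voxels, r, axis=0)
        dz = thick_vol.spacing[0] / r
        from dataclasses import replace
        return replace(thick_vol, voxels=vox,
                       spacing=(dz,) + thick_vol.spacing[1:],
                       origin=(thick_vol.origin[0] - dz * (r - 1) / 2.0,)
                       + thick_vol.origin[1:])

    gen = generator_from_checkpoint(checkpoint)
    segments, plan = chunk_z(thick_vol, segment_length_z, overlap_z)
    out_segments = []
    for seg in segments:
        unit = hu_to_unit(seg.voxels, seg.intensity_range)
        x = unit.transpose(1, 2, 0)[None, None]  # (1,1,h,w,d)
        with nn.no_grad():
            y = gen(Tensor(x.astype(np.float32))).data
        sr = np.clip(y[0, 0].transpose(2, 0, 1), 0.0, 1.0)
        hu = unit_to_hu(sr, seg.intensity_range)
        dz = seg.spacing[0] / r
        out_segments.append(CTVolume(
            hu, spacing=(dz,) + seg.spacing[1:],
            origin=(seg.origin[0] - dz * (r - 1) / 2.0,) + seg.origin[1:],
            intensity_range=seg.intensity_range, plane=seg.plane))
    out = stitch_z(out_segments, plan, r)
    if data_consistency:
        vox = out.voxels
        z = thick_vol.z_len
        groups = vox[:z * r].reshape(z, r, *vox.shape[1:])
        resid = thick_vol.voxels - groups.mean(axis=1)
        groups += resid[:, None]
        lo, hi = out.intensity_range
        out.voxels = np.clip(groups.reshape(z * r, *vox.shape[1:]), lo, hi)
    return out
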