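"""Synthetic chest-like CT phantoms with lung nodules of known volume.

A phantom is a soft-tissue block (≈40 HU) holding two ellipsoidal lung
fields (≈-850 HU) threaded by a few vessel-like tubes (≈40 HU), plus
spherical nodules: solid (≈-50 HU throughout), ground-glass (≈-650 HU), or
part-solid (ground-glass shell around a solid core).  Sphere radii give
analytic total and solid volumes (4/3*pi*r^3), which serve as ground truth
for volumetry; Gaussian HU noise is the only corruption.  Generation is
deterministic given the spec seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .volume import CTVolume, DEFAULT_HU_RANGE

NODULE_TYPES = ("solid", "part_solid", "GGN")


class PhantomSpecError(ValueError):
    """Nodules overlap, leave the lung fields, or the spec is inconsistent."""


@dataclass
class SyntheticNodule:
    """Ground-truth description of one spherical nodule.

    ``radius_mm`` is the outer radius; ``core_radius_mm`` the solid-core
    radius (0 for a pure ground-glass nodule, equal to ``radius_mm`` for a
    solid one).  Centre is in mm, (z, y, x), in volume coordinates.
    """

    center_mm: tuple
    type: str
    radius_mm: float
    core_radius_mm: float
    hu_core: float = -50.0
    hu_ggo: float = -650.0

    def __post_init__(self):
        if self.type not in NODULE_TYPES:
            raise ValueError(f"unknown nodule type {self.type!r}")
        if not (0.0 <= self.core_radius_mm <= self.radius_mm):
            raise ValueError("need 0 <= core radius <= outer radius")

    @property
    def total_volume_mm3(self) -> float:
        return sphere_volume(self.radius_mm)

    @property
    def solid_volume_mm3(self) -> float:
        return sphere_volume(self.core_radius_mm)


@dataclass
class PhantomSpec:
    """Layout of one phantom volume.

    Shape is (z, y, x) voxels with thin-slice spacing in mm.  HU levels are
    chosen so a -300 HU threshold separates solid cores from ground glass
    and -750 HU separates any nodule tissue from aerated lung.
    """

    shape: tuple = (64, 96, 96)
    spacing: tuple = (1.0, 0.7, 0.7)
    nodules: list = field(default_factory=list)
    noise_sd: float = 20.0
    seed: int = 0
    hu_tissue: float = 40.0
    hu_lung: float = -850.0
    hu_vessel: float = 40.0
    vessel_count: int = 3
    vessel_radius_mm: tuple = (0.8, 1.5)
    lung_margin_mm: float = 3.0


def sphere_volume(radius_mm: float) -> float:
    """4/3 * pi * r^3 in mm^3."""
    return 4.0 / 3.0 * math.pi * float(radius_mm) ** 3


def radius_from_volume(volume_mm3: float) -> float:
    """Inverse sphere volume: r = (3V / 4 pi)^(1/3)."""
    return (3.0 * float(volume_mm3) / (4.0 * math.pi)) ** (1.0 / 3.0)


def _lung_fields(spec: PhantomSpec):
    """Two ellipsoids (centre_mm, semi_axes_mm) filling most of the block."""
    ext = np.array(spec.shape, dtype=np.float64) * np.array(spec.spacing)
    cz, cy, cx = ext / 2.0
    semi = np.array([0.46 * ext[0], 0.40 * ext[1], 0.22 * ext[2]])
    off = 0.25 * ext[2]
    return [((cz, cy, cx - off), semi), ((cz, cy, cx + off), semi)]


def _coord_grids(spec: PhantomSpec):
    """Voxel-centre coordinates in mm along each axis."""
    return [np.arange(n, dtype=np.float64) * s
            for n, s in zip(spec.shape, spec.spacing)]


def _ellipsoid_mask(grids, center, semi) -> np.ndarray:
    z, y, x = grids
    t = (((z - center[0]) / semi[0]) ** 2)[:, None, None] \
        + (((y - center[1]) / semi[1]) ** 2)[None, :, None] \
        + (((x - center[2]) / semi[2]) ** 2)[None, None, :]
    return t <= 1.0


def _sphere_mask(grids, center, radius) -> np.ndarray:
    z, y, x = grids
    d2 = ((z - center[0]) ** 2)[:, None, None] \
        + ((y - center[1]) ** 2)[None, :, None] \
        + ((x - center[2]) ** 2)[None, None, :]
    return d2 <= radius ** 2


def _sphere_coverage(grids, center, radius, spacing,
                     supersample: int = 3) -> np.ndarray:
    """Fraction of each voxel covered by the sphere (partial volume).

    Voxels are supersampled ``supersample`` times per axis, so boundary
    voxels take intermediate coverage in [0, 1] — the volume-averaging
    physics of CT voxels, without which a rasterized phantom has
    unrealistically binary edges.
    """
    z, y, x = grids
    cov = np.zeros((len(z), len(y), len(x)), dtype=np.float32)
    n = int(supersample)
    offsets = (np.arange(n) - (n - 1) / 2.0) / n
    for oz in offsets * spacing[0]:
        dz2 = ((z + oz - center[0]) ** 2)[:, None, None]
        for oy in offsets * spacing[1]:
            dy2 = ((y + oy - center[1]) ** 2)[None, :, None]
            for ox in offsets * spacing[2]:
                dx2 = ((x + ox - center[2]) ** 2)[None, None, :]
                cov += (dz2 + dy2 + dx2) <= radius ** 2
    cov /= n ** 3
    return cov


def _inside_lung(center, radius, lungs, margin) -> bool:
    """Sphere of ``radius`` fits inside some lung ellipsoid shrunk by
    ``radius + margin`` (conservative containment test)."""
    for lc, semi in lungs:
        shrunk = semi - (radius + margin)
        if np.any(shrunk <= 0):
            continue
        t = sum(((c - l) / s) ** 2 for c, l, s in zip(center, lc, shrunk))
        if t <= 1.0:
            return True
    return False


def generate_phantom(spec: PhantomSpec):
    """Rasterize a phantom.

    Returns ``(CTVolume, masks, nodules)`` where ``masks`` is a list of
    ``(total_mask, solid_mask)`` boolean arrays aligned with
    ``spec.nodules``.  Raises :class:`PhantomSpecError` for overlapping or
    out-of-lung nodules.
    """
    rng = np.random.default_rng(spec.seed)
    grids = _coord_grids(spec)
    lungs = _lung_fields(spec)

    for i, nod in enumerate(spec.nodules):
        if not _inside_lung(nod.center_mm, nod.radius_mm, lungs,
                            spec.lung_margin_mm):
            raise PhantomSpecError(
                f"nodule {i} does not fit inside a lung field")
        for j in range(i + 1, len(spec.nodules)):
            other = spec.nodules[j]
            d = math.dist(nod.center_mm, other.center_mm)
            if d < nod.radius_mm + other.radius_mm + 2.0:
                raise PhantomSpecError(f"nodules {i} and {j} overlap")

    hu = np.full(spec.shape, spec.hu_tissue, dtype=np.float32)
    lung_mask = np.zeros(spec.shape, dtype=bool)
    for lc, semi in lungs:
        lung_mask |= _ellipsoid_mask(grids, lc, semi)
    hu[lung_mask] = spec.hu_lung

    # vessel-like tubes inside each lung, roughly along z, kept clear of
    # every nodule so threshold volumetry is not confounded by attachment
    keep_out = np.zeros(spec.shape, dtype=bool)
    for nod in spec.nodules:
        keep_out |= _sphere_mask(grids, nod.center_mm,
                                 nod.radius_mm + spec.lung_margin_mm)
    z_mm = grids[0]
    ny, nx = spec.shape[1], spec.shape[2]
    yy = grids[1][:, None]
    xx = grids[2][None, :]
    for lc, semi in lungs:
        for _ in range(spec.vessel_count):
            r_v = rng.uniform(*spec.vessel_radius_mm)
            y0 = lc[1] + rng.uniform(-0.5, 0.5) * semi[1]
            x0 = lc[2] + rng.uniform(-0.5, 0.5) * semi[2]
            # small transverse drift along z
            slope_y = rng.uniform(-0.1, 0.1)
            slope_x = rng.uniform(-0.1, 0.1)
            for iz, zc in enumerate(z_mm):
                cy = y0 + slope_y * (zc - lc[0])
                cx = x0 + slope_x * (zc - lc[0])
                disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_v ** 2
                disk &= lung_mask[iz]
                disk &= ~keep_out[iz]
                hu[iz][disk] = spec.hu_vessel

    masks = []
    nodules = []
    for nod in spec.nodules:
        # coverage-weighted (partial-volume) rasterization: a voxel's HU is
        # the volume-average of the tissues inside it, as in real CT
        total = _sphere_mask(grids, nod.center_mm, nod.radius_mm)
        cov_outer = _sphere_coverage(grids, nod.center_mm, nod.radius_mm,
                                     spec.spacing)
        if nod.type == "solid":
            solid = total
            hu += cov_outer * (nod.hu_core - hu)
        elif nod.type == "GGN":
            solid = np.zeros_like(total)
            hu += cov_outer * (nod.hu_ggo - hu)
        else:
            solid = _sphere_mask(grids, nod.center_mm, nod.core_radius_mm)
            cov_core = _sphere_coverage(grids, nod.center_mm,
                                        nod.core_radius_mm, spec.spacing)
            hu += cov_outer * (nod.hu_ggo - hu)
            hu += cov_core * (nod.hu_core - hu)
        masks.append((total, solid))
        nodules.append(nod)

    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
    lo, hi = DEFAULT_HU_RANGE
    np.clip(hu, lo, hi, out=hu)
    vol = CTVolume(hu, spacing=spec.spacing)
    return vol, masks, nodules


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSeries:
    """One phantom series: thin volume, per-nodule masks, ground truth."""

    volume: CTVolume
    masks: list
    nodules: list
    spec: PhantomSpec


def _sample_nodules(rng, spec: PhantomSpec, n: int, volume_range,
                    type_cycle) -> list:
    """Rejection-sample ``n`` non-overlapping in-lung nodules."""
    lungs = _lung_fields(spec)
    placed: list[SyntheticNodule] = []
    lo_v, hi_v = volume_range
    for i in range(n):
        ntype = type_cycle[i % len(type_cycle)]
        for _ in range(400):
            vol_mm3 = rng.uniform(lo_v, hi_v)
            radius = radius_from_volume(vol_mm3)
            lung = lungs[rng.integers(len(lungs))]
            lc, semi = lung
            shrunk = semi - (radius + spec.lung_margin_mm)
            if np.any(shrunk <= 0):
                continue
            u = rng.uniform(-1.0, 1.0, size=3)
            if np.sum(u ** 2) > 1.0:
                continue
            center = tuple(lc[k] + u[k] * shrunk[k] for k in range(3))
            if any(math.dist(center, p.center_mm)
                   < radius + p.radius_mm + 2.0 for p in placed):
                continue
            if ntype == "solid":
                core = radius
            elif ntype == "GGN":
                core = 0.0
            else:
                core = radius * rng.uniform(0.3, 0.7) ** (1.0 / 3.0)
            placed.append(SyntheticNodule(center, ntype, radius, core))
            break
        else:
            raise PhantomSpecError(
                f"could not place nodule {i} after 400 attempts")
    return placed


def make_test_cohort(n_series: int, nodules_per_series=None,
                     volume_range=(80.0, 350.0), seed: int = 0,
                     shape=(64, 96, 96), spacing=(1.0, 0.7, 0.7),
                     noise_sd: float = 20.0, total_nodules: int | None = None):
    """Build a cohort of thin-slice phantoms with stratified nodule types.

    ``nodules_per_series`` may be an int or None; with ``total_nodules``
    given, per-series counts are spread so the cohort totals that many
    nodules (mirroring a 40-series / 55-nodule style cohort).  Deterministic
    given ``seed``.
    """
    if n_series < 1:
        raise ValueError("need at least one series")
    rng = np.random.default_rng(seed)
    if total_nodules is not None:
        base = total_nodules // n_series
        extra = total_nodules - base * n_series
        counts = [base + (1 if i < extra else 0) for i in range(n_series)]
    else:
        k = 2 if nodules_per_series is None else int(nodules_per_series)
        counts = [k] * n_series
    type_cycle = list(NODULE_TYPES)
    series = []
    nodule_idx = 0
    for i, count in enumerate(counts):
        spec = PhantomSpec(shape=shape, spacing=spacing, noise_sd=noise_sd,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        cycle = [type_cycle[(nodule_idx + j) % 3] for j in range(count)]
        spec.nodules = _sample_nodules(rng, spec, count, volume_range, cycle)
        nodule_idx += count
        vol, masks, nodules = generate_phantom(spec)
        series.append(CohortSeries(vol, masks, nodules, spec))
    return series
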