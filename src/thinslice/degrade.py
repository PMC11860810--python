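"""Thick-slice simulation and interpolation baselines.

Thick-slice CT is simulated from thin-slice CT by averaging every ``r``
consecutive slices into one (r = 4 by default: 1.0 mm stacks become 4.0 mm
stacks, e.g. 300 slices -> 75).  The averaging fixes the geometric
alignment used throughout the package: thick slice ``k`` is centred on thin
coordinate ``k*r + (r-1)/2``, and every depth upsampler (the generator's
skip connection and the spline baselines here) inverts exactly that map.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import make_interp_spline

from .volume import CTVolume


@dataclass
class DegradationSpec:
    """Slice-averaging degradation: integer factor, arithmetic mean."""

    factor: int = 4
    mode: str = "mean"

    def __post_init__(self):
        self.factor = int(self.factor)
        if self.factor < 1:
            raise ValueError("degradation factor must be >= 1")
        if self.mode != "mean":
            raise ValueError(f"unsupported degradation mode {self.mode!r}")


def simulate_thick(vol: CTVolume, spec: DegradationSpec | int = 4) -> CTVolume:
    """Average every ``r`` consecutive slices into one thick slice.

    Output slice k is the arithmetic mean of input slices [k*r, (k+1)*r);
    trailing ``z_len mod r`` slices are dropped so every output slice is an
    equal-weight mean.  Slice thickness becomes ``r * dz`` and the origin
    shifts to the centre of the first group.
    """
    r = spec.factor if isinstance(spec, DegradationSpec) else int(spec)
    if r < 1:
        raise ValueError("degradation factor must be >= 1")
    z = vol.z_len
    if z < r:
        raise ValueError(f"volume has {z} slices, fewer than factor {r}")
    if r == 1:
        return vol.copy()
    zt = z // r
    vox = vol.voxels[:zt * r].reshape(zt, r, *vol.voxels.shape[1:])
    thick = vox.mean(axis=1, dtype=np.float64).astype(np.float32)
    dz = vol.spacing[0]
    return replace(vol, voxels=thick,
                   spacing=(dz * r,) + vol.spacing[1:],
                   origin=(vol.origin[0] + dz * (r - 1) / 2.0,)
                   + vol.origin[1:])


def upsample_z_array(arr: np.ndarray, r: int, order: int = 3) -> np.ndarray:
    """Spline-interpolate a (z, ...) array r-fold along z.

    ``order`` 1 = trilinear, 3 = tricubic.  Query coordinates follow the
    slice-mean alignment (thin index z maps to thick coordinate
    ``(z - (r-1)/2) / r``), clamped at the edges.
    """
    r = int(r)
    if r == 1:
        return np.asarray(arr, dtype=np.float32).copy()
    z = arr.shape[0]
    if z == 1:
        return np.repeat(np.asarray(arr, dtype=np.float32), r, axis=0)
    k = min(int(order), z - 1)
    grid = np.arange(z, dtype=np.float64)
    q = (np.arange(z * r, dtype=np.float64) - (r - 1) / 2.0) / r
    q = np.clip(q, 0.0, z - 1.0)
    spl = make_interp_spline(grid, np.asarray(arr, dtype=np.float64),
                             k=k, axis=0)
    return spl(q).astype(np.float32)


def upsample_z(vol: CTVolume, r: int, order: int = 3) -> CTVolume:
    """Interpolation baseline: r-fold thin-slice volume from a thick one."""
    r = int(r)
    up = upsample_z_array(vol.voxels, r, order=order)
    lo, hi = vol.intensity_range
    up = np.clip(up, lo, hi)
    dz = vol.spacing[0] / r
    return replace(vol, voxels=up, spacing=(dz,) + vol.spacing[1:],
                   origin=(vol.origin[0] - dz * (r - 1) / 2.0,)
                   + vol.origin[1:])
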