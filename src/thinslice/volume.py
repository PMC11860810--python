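"""CT volume container, DICOM/NIfTI I/O, reformatting, chunking/stitching.

Volumes are held as (z, y, x) Hounsfield-unit arrays with z the
slice-stacking axis; ``spacing = (dz, dy, dx)`` in mm, so ``dz`` is the
slice thickness.  Intensities are clipped on load to the 12-bit CT range
[-1024, 3071] HU and the network operates on a linear [0, 1] rescale of
that range.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np

DEFAULT_HU_RANGE = (-1024.0, 3071.0)

_PLANES = ("axial", "coronal", "sagittal")
# permutation of (z, y, x) axes that maps an axial volume into each plane
_PLANE_PERM = {"axial": (0, 1, 2), "coronal": (1, 0, 2), "sagittal": (2, 0, 1)}


class VolumeFormatError(ValueError):
    """Unreadable or inconsistent volume data."""


class ChunkConfigError(ValueError):
    """Invalid segmentation parameters."""


@dataclass
class CTVolume:
    """A 3D HU voxel grid with per-axis spacing and origin in mm."""

    voxels: np.ndarray
    spacing: tuple
    origin: tuple = (0.0, 0.0, 0.0)
    intensity_range: tuple = DEFAULT_HU_RANGE
    plane: str = "axial"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D (z, y, x) array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels contain non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise ValueError("spacing must be three strictly positive values")
        if self.plane not in _PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def z_len(self) -> int:
        return self.voxels.shape[0]

    def copy(self) -> "CTVolume":
        return replace(self, voxels=self.voxels.copy())


@dataclass
class ChunkPlan:
    """Bookkeeping for z-axis segmentation into fixed-length segments."""

    segment_count: int
    segment_length_z: int
    overlap_z: int
    segment_offsets: list
    z_len: int
    pad_z: int


# ---------------------------------------------------------------------------
# intensity scaling
# ---------------------------------------------------------------------------

def hu_to_unit(hu, intensity_range=DEFAULT_HU_RANGE):
    """Linearly map [lo, hi] HU to [0, 1] (clipping outside)."""
    lo, hi = intensity_range
    return np.clip((np.asarray(hu, dtype=np.float32) - lo) / (hi - lo), 0.0, 1.0)


def unit_to_hu(u, intensity_range=DEFAULT_HU_RANGE):
    lo, hi = intensity_range
    return np.asarray(u, dtype=np.float32) * (hi - lo) + lo


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path, format: str | None = None) -> CTVolume:
    """Read a DICOM series directory or a NIfTI file into a CTVolume.

    Voxels are rescaled to HU (DICOM slope/intercept applied) and clipped
    to the default intensity range.
    """
    path = os.fspath(path)
    if format is None:
        format = "dicom_series" if os.path.isdir(path) else "nifti"
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom_series":
        return _read_dicom_series(path)
    raise VolumeFormatError(f"unknown format {format!r}")


def _read_nifti(path) -> CTVolume:
    import nibabel as nib

    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several error types
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    affine = img.affine
    if not np.allclose(affine[:3, :3] - np.diag(np.diag(affine[:3, :3])), 0.0,
                       atol=1e-4):
        raise VolumeFormatError(
            f"{path}: only axis-aligned NIfTI volumes are supported")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume")
    # headers hold float32; round away the representation noise
    dx, dy, dz = (round(abs(float(v)), 6) for v in np.diag(affine[:3, :3]))
    ox, oy, oz = (round(float(v), 6) for v in affine[:3, 3])
    lo, hi = DEFAULT_HU_RANGE
    voxels = np.clip(data.transpose(2, 1, 0), lo, hi)
    return CTVolume(voxels, spacing=(dz, dy, dx), origin=(oz, oy, ox))


def _read_dicom_series(path) -> CTVolume:
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path)
        if not f.startswith("."))
    if not files:
        raise VolumeFormatError(f"no files in DICOM directory {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:
            raise VolumeFormatError(f"unreadable DICOM file {f}: {exc}") from exc
        slices.append((f, ds))
    def zpos(item):
        ds = item[1]
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))
    slices.sort(key=zpos)
    zs = np.array([zpos(s) for s in slices], dtype=np.float64)
    if len(zs) > 1:
        dzs = np.diff(zs)
        if dzs.min() <= 0:
            raise VolumeFormatError(
                f"duplicate or unordered slice position at {slices[int(np.argmin(dzs)) + 1][0]}")
        if not np.allclose(dzs, dzs[0], atol=1e-3):
            bad = slices[int(np.argmax(np.abs(dzs - dzs[0]))) + 1][0]
            raise VolumeFormatError(
                f"non-uniform inter-slice spacing at {bad}")
        dz = float(dzs[0])
    else:
        dz = float(getattr(slices[0][1], "SliceThickness", 1.0))
    first = slices[0][1]
    dy, dx = (float(v) for v in first.PixelSpacing)
    lo, hi = DEFAULT_HU_RANGE
    planes = []
    for f, ds in slices:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = ds.pixel_array.astype(np.float32) * slope + intercept
        if arr.shape != slices[0][1].pixel_array.shape:
            raise VolumeFormatError(f"slice shape mismatch at {f}")
        planes.append(np.clip(arr, lo, hi))
    origin = (float(zs[0]),
              float(first.ImagePositionPatient[1]) if hasattr(first, "ImagePositionPatient") else 0.0,
              float(first.ImagePositionPatient[0]) if hasattr(first, "ImagePositionPatient") else 0.0)
    return CTVolume(np.stack(planes, axis=0), spacing=(dz, dy, dx),
                    origin=origin)


def write_volume(vol: CTVolume, path, format: str = "nifti") -> None:
    """Write a CTVolume as NIfTI (float32; spacing/origin in the affine)."""
    if format != "nifti":
        raise VolumeFormatError(f"unsupported output format {format!r}")
    import nibabel as nib

    dz, dy, dx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.array([[dx, 0, 0, ox],
                       [0, dy, 0, oy],
                       [0, 0, dz, oz],
                       [0, 0, 0, 1]], dtype=np.float64)
    img = nib.Nifti1Image(vol.voxels.transpose(2, 1, 0), affine)
    img.header.set_zooms((dx, dy, dz))
    try:
        nib.save(img, os.fspath(path))
    except Exception as exc:
        raise IOError(f"cannot write volume to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# reformatting
# ---------------------------------------------------------------------------

def reformat(vol: CTVolume, plane: str) -> CTVolume:
    """Permute axes into the requested anatomical viewing plane.

    A pure axis permutation with matching spacing/origin permutation;
    reformat(reformat(v, p), "axial") == v.
    """
    if plane not in _PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    # back to axial first
    cur = _PLANE_PERM[vol.plane]
    inv = tuple(int(i) for i in np.argsort(cur))
    ax_vox = vol.voxels.transpose(inv)
    ax_spc = tuple(vol.spacing[i] for i in inv)
    ax_org = tuple(vol.origin[i] for i in inv)
    perm = _PLANE_PERM[plane]
    return CTVolume(ax_vox.transpose(perm),
                    spacing=tuple(ax_spc[i] for i in perm),
                    origin=tuple(ax_org[i] for i in perm),
                    intensity_range=vol.intensity_range, plane=plane)


# ---------------------------------------------------------------------------
# chunking / stitching along z
# ---------------------------------------------------------------------------

def chunk_z(vol: CTVolume, segment_length_z: int = 16,
            overlap_z: int = 2):
    """Split a volume into fixed-length z segments with overlap.

    The final segment is edge-replication padded when z_len is not covered
    exactly; the pad length is recorded in the plan so stitching can crop.
    """
    L = int(segment_length_z)
    ov = int(overlap_z)
    if L < 1 or ov < 0:
        raise ChunkConfigError("segment length must be >= 1, overlap >= 0")
    if ov >= L / 2 and ov > 0:
        raise ChunkConfigError(
            f"overlap_z={ov} must be smaller than segment_length_z/2={L / 2}")
    z = vol.z_len
    stride = L - ov
    offsets = [0]
    while offsets[-1] + L < z:
        offsets.append(offsets[-1] + stride)
    pad = offsets[-1] + L - z
    vox = vol.voxels
    if pad:
        vox = np.concatenate([vox, np.repeat(vox[-1:], pad, axis=0)], axis=0)
    dz = vol.spacing[0]
    segments = []
    for off in offsets:
        seg_origin = (vol.origin[0] + off * dz,) + vol.origin[1:]
        segments.append(CTVolume(vox[off:off + L], spacing=vol.spacing,
                                 origin=seg_origin,
                                 intensity_range=vol.intensity_range,
                                 plane=vol.plane))
    plan = ChunkPlan(segment_count=len(offsets), segment_length_z=L,
                     overlap_z=ov, segment_offsets=offsets, z_len=z,
                     pad_z=pad)
    return segments, plan


def stitch_z(segments, plan: ChunkPlan, r: int = 1) -> CTVolume:
    """Recombine z segments (each upsampled in z by factor r).

    Overlap regions are blended with a linear cross-fade; the padding added
    by :func:`chunk_z` is cropped off, so the output has exactly
    ``r * plan.z_len`` slices.
    """
    if len(segments) != plan.segment_count:
        raise ValueError(
            f"expected {plan.segment_count} segments, got {len(segments)}")
    r = int(r)
    Lr = plan.segment_length_z * r
    ovr = plan.overlap_z * r
    total = (plan.segment_offsets[-1] + plan.segment_length_z) * r
    first = segments[0]
    _, y, x = first.voxels.shape
    num = np.zeros((total, y, x), dtype=np.float64)
    den = np.zeros((total, 1, 1), dtype=np.float64)
    n_seg = len(segments)
    for i, (seg, off) in enumerate(zip(segments, plan.segment_offsets)):
        if seg.voxels.shape[0] != Lr:
            raise ValueError(
                f"segment {i} has z_len {seg.voxels.shape[0]}, expected {Lr}")
        w = np.ones(Lr, dtype=np.float64)
        if ovr and i > 0:
            w[:ovr] = np.arange(1, ovr + 1) / (ovr + 1)
        if ovr and i < n_seg - 1:
            w[-ovr:] = np.arange(ovr, 0, -1) / (ovr + 1)
        o = off * r
        num[o:o + Lr] += w[:, None, None] * seg.voxels
        den[o:o + Lr, 0, 0] += w
    out = (num / den).astype(np.float32)[:plan.z_len * r]
    dz = first.spacing[0]
    return CTVolume(out, spacing=first.spacing,
                    origin=first.origin, intensity_range=first.intensity_range,
                    plane=first.plane)
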