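"""Nodule volumetry, type classification, Lung-RADS categorization, and
agreement statistics.

Volumetry is voxel counting on segmentation masks times the voxel volume.
Nodule type (solid / part-solid / ground-glass) comes from the histogram of
HU values inside the nodule: the fraction of voxels at or above a solid
threshold (default -300 HU) decides the type.  Categories 2/3/4A/4B follow
a configurable Lung-RADS v2022 volume-threshold table shipped as versioned
YAML; categorization of solid and part-solid nodules uses solid and total
volume, ground-glass nodules use total volume only.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .volume import CTVolume

CATEGORIES = ("2", "3", "4A", "4B")
NODULE_TYPES = ("solid", "part_solid", "GGN")


@dataclass
class NoduleMeasurement:
    """Total and solid volume in mm^3 plus nodule type."""

    total_volume_mm3: float
    solid_volume_mm3: float
    type: str

    def __post_init__(self):
        if self.type not in NODULE_TYPES:
            raise ValueError(f"unknown nodule type {self.type!r}")
        if self.total_volume_mm3 <= 0:
            raise ValueError("total volume must be positive")
        if not (0.0 <= self.solid_volume_mm3 <= self.total_volume_mm3 + 1e-9):
            raise ValueError("need 0 <= solid volume <= total volume")


# ---------------------------------------------------------------------------
# volumetry and type classification
# ---------------------------------------------------------------------------

def measure_volumes(total_mask: np.ndarray, solid_mask: np.ndarray,
                    spacing, nodule_type: str = "solid") -> NoduleMeasurement:
    """Volume = voxel count x dz*dy*dx, for total and solid masks."""
    total_mask = np.asarray(total_mask, dtype=bool)
    solid_mask = np.asarray(solid_mask, dtype=bool)
    if total_mask.shape != solid_mask.shape:
        raise ValueError("mask shapes differ")
    if np.any(solid_mask & ~total_mask):
        raise ValueError("solid mask must be contained in total mask")
    n_total = int(total_mask.sum())
    if n_total == 0:
        raise ValueError("empty total mask")
    dz, dy, dx = (float(s) for s in spacing)
    if min(dz, dy, dx) <= 0:
        raise ValueError("spacing must be strictly positive")
    voxel = dz * dy * dx
    return NoduleMeasurement(total_volume_mm3=n_total * voxel,
                             solid_volume_mm3=int(solid_mask.sum()) * voxel,
                             type=nodule_type)


def classify_type(hu_values, solid_hu_threshold: float = -300.0,
                  fractions=(0.1, 0.9)) -> str:
    """Histogram-based type call from the HU distribution inside a nodule.

    With s = fraction of voxels >= ``solid_hu_threshold``: GGN if
    s < f_low, part-solid if f_low <= s < f_high, solid if s >= f_high.
    """
    hu = np.asarray(hu_values, dtype=np.float64).reshape(-1)
    if hu.size < 1:
        raise ValueError("need at least one voxel")
    f_low, f_high = fractions
    s = float(np.mean(hu >= solid_hu_threshold))
    if s < f_low:
        return "GGN"
    if s < f_high:
        return "part_solid"
    return "solid"


# ---------------------------------------------------------------------------
# Lung-RADS table
# ---------------------------------------------------------------------------

class LungRADSTable:
    """Volume-threshold lookup mapping (type, solid, total) -> category.

    Intervals are closed-open: a volume equal to a cutpoint falls in the
    higher category, volumes below the lowest cutpoint take the floor
    category, and volumes at or above the highest take the ceiling.
    """

    def __init__(self, config: dict):
        self.version = str(config.get("version", "unversioned"))
        self._cfg = config
        for key in ("solid", "part_solid", "ggn"):
            if key not in config:
                raise ValueError(f"table missing section {key!r}")
        for section in (config["solid"], config["ggn"]):
            cuts = section["total_cutpoints_mm3"]
            if list(cuts) != sorted(cuts) or len(set(cuts)) != len(cuts):
                raise ValueError("cutpoints must be strictly increasing")
            if len(section["total_categories"]) != len(cuts) + 1:
                raise ValueError("need one more category than cutpoints")
        ps = config["part_solid"]
        cuts = ps["solid_cutpoints_mm3"]
        if list(cuts) != sorted(cuts) or len(set(cuts)) != len(cuts):
            raise ValueError("cutpoints must be strictly increasing")
        if len(ps["solid_categories"]) != len(cuts) + 1:
            raise ValueError("need one more category than cutpoints")

    @classmethod
    def default(cls) -> "LungRADSTable":
        ref = importlib.resources.files("thinslice.data") / "lungrads_v2022.yaml"
        return cls(yaml.safe_load(ref.read_text()))

    @classmethod
    def from_yaml(cls, path) -> "LungRADSTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @staticmethod
    def _lookup(value: float, cutpoints, categories) -> str:
        idx = int(np.searchsorted(np.asarray(cutpoints, dtype=np.float64),
                                  value, side="right"))
        return categories[idx]

    def categorize(self, m: NoduleMeasurement) -> str:
        if m.type == "solid":
            sec = self._cfg["solid"]
            return self._lookup(m.total_volume_mm3,
                                sec["total_cutpoints_mm3"],
                                sec["total_categories"])
        if m.type == "part_solid":
            sec = self._cfg["part_solid"]
            if m.total_volume_mm3 < float(sec["total_floor_mm3"]):
                return str(sec["floor_category"])
            return self._lookup(m.solid_volume_mm3,
                                sec["solid_cutpoints_mm3"],
                                sec["solid_categories"])
        sec = self._cfg["ggn"]
        return self._lookup(m.total_volume_mm3,
                            sec["total_cutpoints_mm3"],
                            sec["total_categories"])


def categorize(m: NoduleMeasurement,
               table: LungRADSTable | None = None) -> str:
    """Assign the Lung-RADS category for one measurement."""
    return (table or LungRADSTable.default()).categorize(m)


def filter_by_volume(measurements, lo: float = 80.0,
                     hi: float = 350.0):
    """Keep measurements with lo <= total volume <= hi (closed interval)."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    return [m for m in measurements if lo <= m.total_volume_mm3 <= hi]


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

@dataclass
class CategoryAgreement:
    """Confusion matrix of predicted vs reference categories plus accuracy."""

    matrix: pd.DataFrame   # rows: reference, columns: predicted
    accuracy: float
    n: int


@dataclass
class PairedCategoryAgreement:
    """Two conditions (A, B) against one reference: the four-way
    correct/incorrect partition and per-condition accuracy."""

    only_a_correct: int
    only_b_correct: int
    both_incorrect: int
    both_correct: int
    accuracy_a: float
    accuracy_b: float
    n: int


def _check_labels(labels):
    arr = [str(v) for v in labels]
    bad = set(arr) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown category labels: {sorted(bad)}")
    return arr


def agreement(pred_categories, ref_categories) -> CategoryAgreement:
    """Tally a 4x4 confusion matrix (reference rows) and its accuracy."""
    pred = _check_labels(pred_categories)
    ref = _check_labels(ref_categories)
    if len(pred) != len(ref):
        raise ValueError("prediction/reference length mismatch")
    mat = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for p, t in zip(pred, ref):
        mat.loc[t, p] += 1
    n = len(pred)
    acc = float(np.trace(mat.values)) / n if n else float("nan")
    return CategoryAgreement(matrix=mat, accuracy=acc, n=n)


def paired_agreement(pred_a, pred_b, ref) -> PairedCategoryAgreement:
    """Partition nodules by which condition categorized them correctly."""
    a = _check_labels(pred_a)
    b = _check_labels(pred_b)
    t = _check_labels(ref)
    if not (len(a) == len(b) == len(t)):
        raise ValueError("length mismatch between conditions and reference")
    only_a = sum(1 for x, y, z in zip(a, b, t) if x == z and y != z)
    only_b = sum(1 for x, y, z in zip(a, b, t) if x != z and y == z)
    both = sum(1 for x, y, z in zip(a, b, t) if x == z and y == z)
    neither = len(t) - only_a - only_b - both
    n = len(t)
    return PairedCategoryAgreement(
        only_a_correct=only_a, only_b_correct=only_b,
        both_incorrect=neither, both_correct=both,
        accuracy_a=(only_a + both) / n, accuracy_b=(only_b + both) / n, n=n)


# ---------------------------------------------------------------------------
# image quality
# ---------------------------------------------------------------------------

def image_quality(gt: CTVolume | np.ndarray, gen: CTVolume | np.ndarray,
                  data_range: float | None = None):
    """(PSNR in dB, mean SSIM over axial slices) between two volumes.

    PSNR is ``20 log10(data_range / rmse)``; identical volumes report
    ``inf``.  SSIM uses the standard windowed formulation per axial slice.
    """
    from skimage.metrics import structural_similarity

    a = gt.voxels if isinstance(gt, CTVolume) else np.asarray(gt)
    b = gen.voxels if isinstance(gen, CTVolume) else np.asarray(gen)
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        if isinstance(gt, CTVolume):
            lo, hi = gt.intensity_range
            data_range = hi - lo
        else:
            data_range = float(a.max() - a.min()) or 1.0
    mse = float(np.mean((a - b) ** 2))
    psnr = float("inf") if mse == 0 else 20.0 * np.log10(
        data_range / np.sqrt(mse))
    ssims = [structural_similarity(a[k], b[k], data_range=data_range)
             for k in range(a.shape[0])]
    return psnr, float(np.mean(ssims))


# ---------------------------------------------------------------------------
# convenience segmentation (the detection network is out of scope)
# ---------------------------------------------------------------------------

def segment_nodule(vol: CTVolume, center_mm, max_radius_mm: float,
                   nodule_hu_threshold: float = -750.0,
                   solid_hu_threshold: float = -300.0):
    """Fixed-threshold segmentation inside a spherical search region.

    Total mask: connected component of voxels >= ``nodule_hu_threshold``
    containing (or nearest to) the seed centre, restricted to a sphere of
    ``max_radius_mm`` around it.  Solid mask: voxels of the total mask at
    or above ``solid_hu_threshold``.
    """
    from scipy import ndimage

    dz, dy, dx = vol.spacing
    z = np.arange(vol.shape[0]) * dz + vol.origin[0]
    y = np.arange(vol.shape[1]) * dy + vol.origin[1]
    x = np.arange(vol.shape[2]) * dx + vol.origin[2]
    d2 = ((z - center_mm[0]) ** 2)[:, None, None] \
        + ((y - center_mm[1]) ** 2)[None, :, None] \
        + ((x - center_mm[2]) ** 2)[None, None, :]
    roi = d2 <= float(max_radius_mm) ** 2
    cand = roi & (vol.voxels >= nodule_hu_threshold)
    if not cand.any():
        return np.zeros(vol.shape, bool), np.zeros(vol.shape, bool)
    labels, _ = ndimage.label(cand)
    seed_idx = np.unravel_index(int(np.argmin(d2)), vol.shape)
    lab = labels[seed_idx]
    if lab == 0:
        # seed voxel below threshold: take the component nearest the centre
        cand_labels = labels[cand]
        dists = d2[cand]
        lab = int(cand_labels[np.argmin(dists)])
    total = labels == lab
    solid = total & (vol.voxels >= solid_hu_threshold)
    return total, solid
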