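"""Volume/mask containers, NIfTI I/O, preprocessing, and volumetric overlap measures.

The analysis operates on non-contrast CT volumes in Hounsfield units (HU)
with paired per-kidney label masks (0 = background, 1 = renal parenchyma,
2 = hydronephrosis).  Preprocessing follows a fixed order: resample to the
target grid, clip intensities to the kidney window, z-score normalize.
Resampling first makes every downstream feature grid-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CTVolume",
    "SegmentationMask",
    "KidneyVolumetry",
    "GridMismatchError",
    "resample_to_grid",
    "window_and_normalize",
    "region_volume_ml",
    "dice_coefficient",
    "kidney_volumetry",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "read_manifest",
]

PARENCHYMA = 1
HYDRONEPHROSIS = 2
VALID_LABELS = frozenset({0, PARENCHYMA, HYDRONEPHROSIS})

# Kidney window used for intensity clipping (width/level in HU).
KIDNEY_WINDOW_WIDTH = 260.0
KIDNEY_WINDOW_LEVEL = 60.0


class GridMismatchError(ValueError):
    """Raised when two volumes/masks do not share shape and spacing."""


@dataclass
class CTVolume:
    """A 3D scalar field with voxel spacing and a spatial origin.

    Parameters
    ----------
    voxels
        3D array; HU for raw CT, dimensionless after normalization.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        Spatial offset of voxel (0, 0, 0) in mm.
    orientation
        Free-form orientation tag; ``"RAS"`` by default, matching the
        diagonal affine this package writes to NIfTI.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class SegmentationMask:
    """Integer label volume on the same grid as its paired :class:`CTVolume`.

    Labels: 0 background, 1 parenchyma, 2 hydronephrosis.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    side: str = "left"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("labels must be integer-valued")
            self.labels = np.round(self.labels).astype(np.uint8)
        present = set(np.unique(self.labels).tolist())
        if not present <= VALID_LABELS:
            raise ValueError(f"labels must be in {sorted(VALID_LABELS)}, got {sorted(present)}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def region(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class KidneyVolumetry:
    """Per-kidney volumes and each kidney's share of the patient total.

    ``percent_rpv``/``percent_rhv`` are fractions of the two-kidney total;
    when the total hydronephrosis volume is zero the share is undefined and
    stored as ``nan`` (downstream SRF code substitutes the uninformative 0.5).
    """

    rpv_ml: float
    rhv_ml: float
    percent_rpv: float
    percent_rhv: float


def _check_same_grid(a, b) -> None:
    if a.shape != b.shape or not np.allclose(a.spacing, b.spacing):
        raise GridMismatchError(
            f"grid mismatch: shape {a.shape} / spacing {a.spacing} vs "
            f"shape {b.shape} / spacing {b.spacing}"
        )


def resample_to_grid(
    volume: CTVolume,
    masks: list[SegmentationMask] | None = None,
    target_shape: tuple[int, int, int] = (256, 256, 80),
) -> tuple[CTVolume, list[SegmentationMask]]:
    """Resample a volume (trilinear) and its masks (nearest label) to a new grid.

    Spacing is rescaled so the physical extent of the field of view is
    preserved; the label set of a mask can never grow.
    """
    masks = list(masks) if masks is not None else []
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t <= 0 for t in target_shape):
        raise ValueError("target_shape must be three positive integers")
    for m in masks:
        _check_same_grid(volume, m)

    src_shape = np.array(volume.shape, dtype=float)
    tgt_shape = np.array(target_shape, dtype=float)
    zoom = tgt_shape / src_shape
    new_spacing = tuple(np.array(volume.spacing) * src_shape / tgt_shape)

    if target_shape == volume.shape:
        out_vox = volume.voxels.copy()
    else:
        out_vox = ndimage.zoom(
            volume.voxels.astype(np.float64), zoom, order=1, mode="nearest", grid_mode=True
        )
        assert out_vox.shape == target_shape
    out_volume = CTVolume(out_vox, new_spacing, volume.origin, volume.orientation)

    out_masks = []
    for m in masks:
        if target_shape == m.shape:
            lab = m.labels.copy()
        else:
            lab = ndimage.zoom(m.labels, zoom, order=0, mode="nearest", grid_mode=True)
        out_masks.append(SegmentationMask(lab, new_spacing, m.side, m.origin))
    return out_volume, out_masks


def window_and_normalize(
    volume: CTVolume,
    width: float = KIDNEY_WINDOW_WIDTH,
    level: float = KIDNEY_WINDOW_LEVEL,
) -> CTVolume:
    """Clip to the intensity window [level - width/2, level + width/2], then z-score.

    A constant post-clip volume has no scale; it maps to all zeros with a
    warning rather than dividing by zero.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    lo, hi = level - width / 2.0, level + width / 2.0
    clipped = np.clip(volume.voxels.astype(np.float64), lo, hi)
    sd = clipped.std()
    if sd == 0:
        warnings.warn("constant volume after clipping; returning all-zero intensities")
        out = np.zeros_like(clipped)
    else:
        out = (clipped - clipped.mean()) / sd
    return replace(volume, voxels=out)


def region_volume_ml(mask: SegmentationMask, label: int) -> float:
    """Volume of a labeled region in mL (voxel count x voxel volume)."""
    if label not in (PARENCHYMA, HYDRONEPHROSIS):
        raise ValueError("label must be 1 (parenchyma) or 2 (hydronephrosis)")
    n = int(np.count_nonzero(mask.labels == label))
    return n * mask.voxel_volume_mm3 / 1000.0


def dice_coefficient(mask_a: SegmentationMask, mask_b: SegmentationMask, label: int) -> float:
    """Dice similarity coefficient 2|A∩B|/(|A|+|B|) for one label.

    Two empty regions agree perfectly on absence and score 1.0.
    """
    _check_same_grid(mask_a, mask_b)
    a = mask_a.labels == label
    b = mask_b.labels == label
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def kidney_volumetry(
    left: SegmentationMask, right: SegmentationMask
) -> dict[str, KidneyVolumetry]:
    """Per-side RPV/RHV plus each side's fraction of the patient total."""
    rpv = {"left": region_volume_ml(left, PARENCHYMA), "right": region_volume_ml(right, PARENCHYMA)}
    rhv = {
        "left": region_volume_ml(left, HYDRONEPHROSIS),
        "right": region_volume_ml(right, HYDRONEPHROSIS),
    }
    tot_rpv = rpv["left"] + rpv["right"]
    tot_rhv = rhv["left"] + rhv["right"]
    out = {}
    for side in ("left", "right"):
        out[side] = KidneyVolumetry(
            rpv_ml=rpv[side],
            rhv_ml=rhv[side],
            percent_rpv=rpv[side] / tot_rpv if tot_rpv > 0 else float("nan"),
            percent_rhv=rhv[side] / tot_rhv if tot_rhv > 0 else float("nan"),
        )
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O and manifests


def save_volume(volume: CTVolume, path) -> None:
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), volume.affine()), str(path))


def save_mask(mask: SegmentationMask, path) -> None:
    aff = np.diag(list(mask.spacing) + [1.0])
    aff[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), aff), str(path))


def _spacing_origin(img) -> tuple[tuple, tuple]:
    aff = img.affine
    spacing = tuple(float(s) for s in np.sqrt((aff[:3, :3] ** 2).sum(axis=0)))
    origin = tuple(float(o) for o in aff[:3, 3])
    return spacing, origin


def load_volume(path) -> CTVolume:
    img = nib.load(str(path))
    spacing, origin = _spacing_origin(img)
    return CTVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_mask(path, side: str) -> SegmentationMask:
    img = nib.load(str(path))
    spacing, origin = _spacing_origin(img)
    labels = np.asarray(img.dataobj)
    return SegmentationMask(np.rint(labels).astype(np.uint8), spacing, side, origin)


MANIFEST_COLUMNS = ["patient_id", "side", "volume_path", "mask_path"]


def read_manifest(path) -> pd.DataFrame:
    """Read a per-kidney manifest CSV (patient_id, side, volume_path, mask_path, ...)."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    bad = set(df["side"].unique()) - {"left", "right"}
    if bad:
        raise ValueError(f"manifest side values must be left/right, got {bad}")
    return df
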