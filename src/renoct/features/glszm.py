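"""Gray-level size-zone matrix (GLSZM) texture features.

A zone is a 26-connected component of voxels sharing one discretized gray
level; the matrix P(i, j) counts zones of level i and size j.  Sixteen
standard features are derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .firstorder import EmptyRegionError

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class GrayLevelSizeZoneMatrix:
    """Sparse GLSZM: per distinct (level, size) cell a zone count.

    Invariant: counts.sum() == n_zones; n_voxels is the region size used
    for ZonePercentage.
    """

    levels: np.ndarray  # gray level i per cell
    sizes: np.ndarray  # zone size j per cell
    counts: np.ndarray  # P(i, j)
    n_voxels: int

    @property
    def n_zones(self) -> int:
        return int(self.counts.sum())


def glszm_matrix(level_volume: np.ndarray, mask: np.ndarray) -> GrayLevelSizeZoneMatrix:
    """Enumerate 26-connected equal-level zones inside ``mask``.

    ``level_volume`` holds 1-based gray levels inside the mask (values
    outside the mask are ignored).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("GLSZM needs a non-empty region")
    lv = np.where(mask, np.asarray(level_volume, dtype=np.int64), 0)
    cells: dict[tuple[int, int], int] = {}
    for level in np.unique(lv[mask]):
        lab, n_comp = ndimage.label(lv == level, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        for size, cnt in zip(*np.unique(sizes, return_counts=True)):
            cells[(int(level), int(size))] = cells.get((int(level), int(size)), 0) + int(cnt)
    keys = sorted(cells)
    return GrayLevelSizeZoneMatrix(
        levels=np.array([k[0] for k in keys], dtype=np.int64),
        sizes=np.array([k[1] for k in keys], dtype=np.int64),
        counts=np.array([cells[k] for k in keys], dtype=np.int64),
        n_voxels=int(mask.sum()),
    )


def glszm_features(glszm: GrayLevelSizeZoneMatrix) -> dict[str, float]:
    i = glszm.levels.astype(np.float64)
    j = glszm.sizes.astype(np.float64)
    P = glszm.counts.astype(np.float64)
    nz = P.sum()
    p = P / nz
    mu_i = np.sum(p * i)
    mu_j = np.sum(p * j)

    # marginals over distinct levels / sizes
    lev_marg = {}
    for lv, c in zip(glszm.levels, P):
        lev_marg[lv] = lev_marg.get(lv, 0.0) + c
    size_marg = {}
    for sz, c in zip(glszm.sizes, P):
        size_marg[sz] = size_marg.get(sz, 0.0) + c
    gln = sum(v**2 for v in lev_marg.values()) / nz
    szn = sum(v**2 for v in size_marg.values()) / nz

    return {
        "SmallAreaEmphasis": float(np.sum(P / j**2) / nz),
        "LargeAreaEmphasis": float(np.sum(P * j**2) / nz),
        "GrayLevelNonUniformity": float(gln),
        "GrayLevelNonUniformityNormalized": float(gln / nz),
        "SizeZoneNonUniformity": float(szn),
        "SizeZoneNonUniformityNormalized": float(szn / nz),
        "ZonePercentage": float(nz / glszm.n_voxels),
        "GrayLevelVariance": float(np.sum(p * (i - mu_i) ** 2)),
        "ZoneVariance": float(np.sum(p * (j - mu_j) ** 2)),
        "ZoneEntropy": float(-np.sum(p * np.log2(p))),
        "LowGrayLevelZoneEmphasis": float(np.sum(P / i**2) / nz),
        "HighGrayLevelZoneEmphasis": float(np.sum(P * i**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(P / (i**2 * j**2)) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(P * i**2 / j**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(P * j**2 / i**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(P * i**2 * j**2) / nz),
    }
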