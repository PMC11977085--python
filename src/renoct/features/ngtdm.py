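"""Neighborhood gray-tone difference matrix (NGTDM) texture features.

For every in-region voxel the mean gray level of its 26-neighborhood
(restricted to the region, center excluded) is computed; per gray level i
the matrix stores the voxel count n_i, probability p_i and the summed
absolute deviation s_i = sum |i - neighborhood mean|.  Voxels with no
in-region neighbor are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .firstorder import EmptyRegionError

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

_KERNEL = np.ones((3, 3, 3), dtype=np.float64)
_KERNEL[1, 1, 1] = 0.0

# Cap applied when sum(p_i * s_i) == 0 (perfectly uniform region).
COARSENESS_CAP = 1e6


@dataclass(frozen=True)
class NeighborhoodGrayToneMatrix:
    levels: np.ndarray  # distinct gray levels i with n_i > 0
    n: np.ndarray  # voxel counts n_i
    p: np.ndarray  # probabilities n_i / N_vp
    s: np.ndarray  # summed absolute deviations s_i

    @property
    def n_voxels(self) -> int:
        return int(self.n.sum())


def ngtdm_matrix(level_volume: np.ndarray, mask: np.ndarray) -> NeighborhoodGrayToneMatrix:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRegionError("NGTDM needs a non-empty region")
    lv = np.where(mask, np.asarray(level_volume, dtype=np.float64), 0.0)
    neigh_sum = ndimage.correlate(lv, _KERNEL, mode="constant", cval=0.0)
    neigh_cnt = ndimage.correlate(mask.astype(np.float64), _KERNEL, mode="constant", cval=0.0)
    valid = mask & (neigh_cnt > 0)
    if not valid.any():
        raise EmptyRegionError("no region voxel has an in-region neighbor")
    with np.errstate(invalid="ignore"):
        neigh_mean = neigh_sum / neigh_cnt
    dev = np.abs(lv - neigh_mean)[valid]
    vox_levels = np.asarray(level_volume)[valid].astype(np.int64)

    levels = np.unique(vox_levels)
    n = np.array([(vox_levels == i).sum() for i in levels], dtype=np.int64)
    s = np.array([dev[vox_levels == i].sum() for i in levels], dtype=np.float64)
    return NeighborhoodGrayToneMatrix(levels=levels, n=n, p=n / n.sum(), s=s)


def ngtdm_features(m: NeighborhoodGrayToneMatrix) -> dict[str, float]:
    i = m.levels.astype(np.float64)
    p, s = m.p, m.s
    nvp = m.n_voxels
    ngp = len(i)
    ps = float(np.sum(p * s))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi, pj = np.meshgrid(p, p, indexing="ij")
    si, sj = np.meshgrid(s, s, indexing="ij")
    off = ~np.eye(ngp, dtype=bool)

    if ngp > 1:
        contrast = float(
            np.sum(pi * pj * (ii - jj) ** 2) / (ngp * (ngp - 1)) * np.sum(s) / nvp
        )
        busy_den = float(np.sum(np.abs(ii * pi - jj * pj)[off]))
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = float(
            np.sum((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj))[off]) / nvp
        )
        ssum = float(np.sum(s))
        strength = float(np.sum(((pi + pj) * (ii - jj) ** 2)[off])) / ssum if ssum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP
    return {
        "Coarseness": min(coarseness, COARSENESS_CAP),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
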