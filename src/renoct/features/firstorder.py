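"""Intensity discretization and first-order (histogram) features."""

from __future__ import annotations

import numpy as np

FIRST_ORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


class EmptyRegionError(ValueError):
    """Raised when a feature is requested on a region with no voxels."""


def discretize(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Fixed-bin-width gray-level discretization.

    level = floor((x - min) / bin_width) + 1; the region minimum maps to
    level 1, so levels are 1-based positive integers.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise EmptyRegionError("cannot discretize an empty region")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return (np.floor((x - x.min()) / bin_width) + 1).astype(np.int64)


def first_order_features(
    values: np.ndarray, voxel_volume: float, bin_width: float = 0.25
) -> dict[str, float]:
    """The 18 first-order features of a region's intensity sample.

    Entropy and Uniformity use the fixed-bin-width histogram; skewness and
    kurtosis use population moments (kurtosis is not excess-corrected) and
    are 0 for a constant region.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise EmptyRegionError("first-order features need a non-empty region")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    p10, p25, med, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    levels = discretize(x, bin_width)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n

    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        rmad = np.mean(np.abs(robust - robust.mean()))
    else:  # pragma: no cover - p10<=x<=p90 always captures some voxels
        rmad = 0.0

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume) * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(med),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "RobustMeanAbsoluteDeviation": float(rmad),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": float(np.mean(dev**3) / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(np.mean(dev**4) / m2**2) if m2 > 0 else 0.0,
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
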