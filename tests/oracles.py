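"""Independent brute-force oracles for feature and statistic definitions.

These re-derive every quantity from its literal definition with explicit
Python loops / enumeration, deliberately sharing no code with the package
implementation.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


# ---------------------------------------------------------------------------
# first-order


def first_order_oracle(values, voxel_volume, bin_width) -> dict[str, float]:
    x = sorted(float(v) for v in np.asarray(values).ravel())
    n = len(x)
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    p10, p25, med, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    lo = min(x)
    counts: dict[int, int] = {}
    for v in x:
        lvl = int(math.floor((v - lo) / bin_width)) + 1
        counts[lvl] = counts.get(lvl, 0) + 1
    probs = [c / n for c in counts.values()]
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    energy = sum(v * v for v in x)
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": lo,
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": max(x),
        "Mean": mean,
        "Median": med,
        "InterquartileRange": p75 - p25,
        "Range": max(x) - lo,
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": sum((v - mean) ** 3 for v in x) / n / sd**3 if sd > 0 else 0.0,
        "Kurtosis": sum((v - mean) ** 4 for v in x) / n / var**2 if var > 0 else 0.0,
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
    }


# ---------------------------------------------------------------------------
# zone enumeration (GLSZM)


def _neighbors26(idx, shape):
    deltas = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    x, y, z = idx
    for dx, dy, dz in deltas:
        nx, ny, nz = x + dx, y + dy, z + dz
        if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
            yield nx, ny, nz


def enumerate_zones(level_volume, mask) -> list[tuple[int, int]]:
    """All (gray level, size) zones by breadth-first flood fill."""
    mask = np.asarray(mask, bool)
    lv = np.asarray(level_volume)
    seen = np.zeros(mask.shape, bool)
    zones = []
    for idx in map(tuple, np.argwhere(mask)):
        if seen[idx]:
            continue
        level = lv[idx]
        queue = deque([idx])
        seen[idx] = True
        size = 0
        while queue:
            cur = queue.popleft()
            size += 1
            for nb in _neighbors26(cur, mask.shape):
                if mask[nb] and not seen[nb] and lv[nb] == level:
                    seen[nb] = True
                    queue.append(nb)
        zones.append((int(level), size))
    return zones


def glszm_oracle(level_volume, mask) -> dict[str, float]:
    zones = enumerate_zones(level_volume, mask)
    nz = len(zones)
    npix = int(np.asarray(mask, bool).sum())
    levels = sorted({i for i, _ in zones})
    sizes = sorted({j for _, j in zones})
    P = {(i, j): sum(1 for zi, zj in zones if (zi, zj) == (i, j)) for i in levels for j in sizes}
    row = {i: sum(P[(i, j)] for j in sizes) for i in levels}
    col = {j: sum(P[(i, j)] for i in levels) for j in sizes}
    mu_i = sum(i * P[(i, j)] for i in levels for j in sizes) / nz
    mu_j = sum(j * P[(i, j)] for i in levels for j in sizes) / nz

    def S(f):
        return sum(f(i, j) * P[(i, j)] for i in levels for j in sizes)

    probs = [P[(i, j)] / nz for i in levels for j in sizes if P[(i, j)] > 0]
    return {
        "SmallAreaEmphasis": S(lambda i, j: 1 / j**2) / nz,
        "LargeAreaEmphasis": S(lambda i, j: j**2) / nz,
        "GrayLevelNonUniformity": sum(v**2 for v in row.values()) / nz,
        "GrayLevelNonUniformityNormalized": sum(v**2 for v in row.values()) / nz**2,
        "SizeZoneNonUniformity": sum(v**2 for v in col.values()) / nz,
        "SizeZoneNonUniformityNormalized": sum(v**2 for v in col.values()) / nz**2,
        "ZonePercentage": nz / npix,
        "GrayLevelVariance": S(lambda i, j: (i - mu_i) ** 2) / nz,
        "ZoneVariance": S(lambda i, j: (j - mu_j) ** 2) / nz,
        "ZoneEntropy": -sum(p * math.log2(p) for p in probs),
        "LowGrayLevelZoneEmphasis": S(lambda i, j: 1 / i**2) / nz,
        "HighGrayLevelZoneEmphasis": S(lambda i, j: i**2) / nz,
        "SmallAreaLowGrayLevelEmphasis": S(lambda i, j: 1 / (i**2 * j**2)) / nz,
        "SmallAreaHighGrayLevelEmphasis": S(lambda i, j: i**2 / j**2) / nz,
        "LargeAreaLowGrayLevelEmphasis": S(lambda i, j: j**2 / i**2) / nz,
        "LargeAreaHighGrayLevelEmphasis": S(lambda i, j: i**2 * j**2) / nz,
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_oracle(level_volume, mask) -> dict[str, float]:
    mask = np.asarray(mask, bool)
    lv = np.asarray(level_volume)
    records = []  # (level, |level - neighborhood mean|)
    for idx in map(tuple, np.argwhere(mask)):
        nb_vals = [lv[nb] for nb in _neighbors26(idx, mask.shape) if mask[nb]]
        if not nb_vals:
            continue
        records.append((int(lv[idx]), abs(float(lv[idx]) - sum(nb_vals) / len(nb_vals))))
    nvp = len(records)
    levels = sorted({l for l, _ in records})
    n = {i: sum(1 for l, _ in records if l == i) for i in levels}
    s = {i: sum(d for l, d in records if l == i) for i in levels}
    p = {i: n[i] / nvp for i in levels}
    ngp = len(levels)
    ps = sum(p[i] * s[i] for i in levels)

    if ngp > 1:
        contrast = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in levels for j in levels)
            / (ngp * (ngp - 1))
            * sum(s.values())
            / nvp
        )
        busy_den = sum(
            abs(i * p[i] - j * p[j]) for i in levels for j in levels if i != j
        )
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in levels
                for j in levels
                if i != j
            )
            / nvp
        )
        ssum = sum(s.values())
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in levels for j in levels if i != j) / ssum
            if ssum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": min(1.0 / ps if ps > 0 else 1e6, 1e6),
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


# ---------------------------------------------------------------------------
# statistics


def auc_pair_counting(scores, labels) -> float:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def icc_mean_squares_oracle(manual, auto) -> float:
    """ICC(2,1) from explicitly assembled ANOVA sums of squares."""
    x = np.column_stack([manual, auto]).astype(float)
    n, k = x.shape
    subj = x.mean(axis=1)
    rater = x.mean(axis=0)
    grand = x.mean()
    msr = k * sum((m - grand) ** 2 for m in subj) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in rater) / (k - 1)
    sse = sum(
        (x[i, j] - subj[i] - rater[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
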