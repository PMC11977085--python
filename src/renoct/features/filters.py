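"""Image filters feeding the "filtering" feature classes.

Each filter maps the preprocessed volume to one or more derived volumes on
the same grid:

* ``square``    — sign-preserving square, rescaled to the input magnitude
                  range: sign(x) * x**2 / max|x|.
* ``logarithm`` — sign-preserving compressed scale:
                  sign(x) * log(|x| + 1), rescaled to the input range.
* ``gradient``  — gradient magnitude with spacing-aware central differences.
* ``wavelet``   — the 8 sub-bands of a single-level 3D discrete wavelet
                  decomposition (coif1, symmetric padding), each
                  reconstructed back to the original grid so masks apply
                  unchanged.
"""

from __future__ import annotations

import numpy as np
import pywt

FILTER_NAMES = ("original", "square", "logarithm", "gradient", "wavelet")

_WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _square(x: np.ndarray) -> np.ndarray:
    c = np.abs(x).max()
    if c == 0:
        return np.zeros_like(x)
    return np.sign(x) * x**2 / c


def _logarithm(x: np.ndarray) -> np.ndarray:
    c = np.abs(x).max()
    if c == 0:
        return np.zeros_like(x)
    out = np.sign(x) * np.log1p(np.abs(x))
    return out * (c / np.log1p(c))


def _gradient(x: np.ndarray, spacing) -> np.ndarray:
    gx, gy, gz = np.gradient(x.astype(np.float64), *spacing)
    return np.sqrt(gx**2 + gy**2 + gz**2)


def _wavelet(x: np.ndarray, wavelet: str) -> dict[str, np.ndarray]:
    coeffs = pywt.dwtn(x, wavelet, mode="symmetric")
    out = {}
    for key, arr in coeffs.items():
        # a->L (lowpass), d->H (highpass); reconstruct each sub-band alone
        zeroed = {k: (v if k == key else np.zeros_like(v)) for k, v in coeffs.items()}
        rec = pywt.idwtn(zeroed, wavelet, mode="symmetric")
        rec = rec[tuple(slice(0, s) for s in x.shape)]
        name = "".join("L" if c == "a" else "H" for c in key)
        out[f"wavelet-{name}"] = rec
    return {k: out[k] for k in (f"wavelet-{b}" for b in _WAVELET_SUBBANDS)}


def apply_image_filter(
    voxels: np.ndarray,
    filter_name: str,
    spacing=(1.0, 1.0, 1.0),
    wavelet: str = "coif1",
) -> dict[str, np.ndarray]:
    """Return the derived volume(s) for one filter as ``{variant: array}``."""
    x = np.asarray(voxels, dtype=np.float64)
    if filter_name == "original":
        return {"original": x}
    if filter_name == "square":
        return {"square": _square(x)}
    if filter_name == "logarithm":
        return {"logarithm": _logarithm(x)}
    if filter_name == "gradient":
        return {"gradient": _gradient(x, spacing)}
    if filter_name == "wavelet":
        return _wavelet(x, wavelet)
    raise ValueError(f"unknown filter {filter_name!r}; expected one of {FILTER_NAMES}")


def filter_bank(
    voxels: np.ndarray,
    filters=FILTER_NAMES,
    spacing=(1.0, 1.0, 1.0),
    wavelet: str = "coif1",
) -> dict[str, np.ndarray]:
    """All derived volumes for the enabled filters, keyed by variant name."""
    out: dict[str, np.ndarray] = {}
    for f in filters:
        out.update(apply_image_filter(voxels, f, spacing=spacing, wavelet=wavelet))
    return out
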