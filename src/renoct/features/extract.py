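"""Feature-table assembly for kidneys.

Column naming convention: ``filter__region__family_Feature``, e.g.
``wavelet-LLH__parenchyma__glszm_SizeZoneNonUniformity``.  Shape features
describe geometry and are computed once, on the original grid.  A kidney
without hydronephrosis gets zero-filled hydronephrosis intensity features
plus a ``hydronephrosis_present`` indicator column (not itself a radiomic
feature column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ..imaging import CTVolume, SegmentationMask, PARENCHYMA, HYDRONEPHROSIS
from .filters import FILTER_NAMES, filter_bank
from .firstorder import FIRST_ORDER_NAMES, discretize, first_order_features
from .glszm import GLSZM_NAMES, glszm_features, glszm_matrix
from .ngtdm import NGTDM_NAMES, ngtdm_features, ngtdm_matrix
from .shape import SHAPE_NAMES, shape_features

FAMILY_NAMES = ("shape", "firstorder", "glszm", "ngtdm")
REGION_LABELS = {"parenchyma": PARENCHYMA, "hydronephrosis": HYDRONEPHROSIS}
PRESENCE_COLUMN = "hydronephrosis_present"


@dataclass(frozen=True)
class FeatureDescriptor:
    """Provenance of one feature column."""

    name: str
    filter: str
    region: str
    family: str
    feature: str


def parse_feature_name(column: str) -> FeatureDescriptor:
    """Split ``filter__region__family_Feature`` into its parts."""
    try:
        filt, region, rest = column.split("__")
        family, feat = rest.split("_", 1)
    except ValueError as exc:
        raise ValueError(f"not a radiomic feature column: {column!r}") from exc
    return FeatureDescriptor(column, filt, region, family, feat)


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The radiomic feature columns of a table (three-part names)."""
    return [c for c in df.columns if c.count("__") == 2]


@dataclass
class ExtractionConfig:
    """What to extract.

    ``bin_width`` is in the units of the preprocessed intensities; the
    default 0.25 suits z-scored volumes (roughly 25-30 occupied gray
    levels over a typical region).
    """

    bin_width: float = 0.25
    families: tuple[str, ...] = FAMILY_NAMES
    filters: tuple[str, ...] = FILTER_NAMES
    regions: tuple[str, ...] = ("parenchyma", "hydronephrosis")
    wavelet: str = "coif1"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not self.families:
            raise ValueError("at least one feature family must be enabled")
        unknown = set(self.families) - set(FAMILY_NAMES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")
        unknown = set(self.filters) - set(FILTER_NAMES)
        if unknown:
            raise ValueError(f"unknown filters: {sorted(unknown)}")
        unknown = set(self.regions) - set(REGION_LABELS)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")


_FAMILY_FEATURES = {
    "shape": SHAPE_NAMES,
    "firstorder": FIRST_ORDER_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
}


def _bbox(mask: np.ndarray) -> tuple[slice, ...]:
    sl = ndimage.find_objects(mask.astype(np.int8))[0]
    return sl


def _texture_inputs(variant: np.ndarray, region: np.ndarray, bin_width: float):
    sl = _bbox(region)
    crop_mask = region[sl]
    crop_vals = variant[sl]
    levels = np.zeros(crop_mask.shape, dtype=np.int64)
    levels[crop_mask] = discretize(crop_vals[crop_mask], bin_width)
    return levels, crop_mask


def extract_kidney_features(
    filtered: dict[str, np.ndarray],
    mask: SegmentationMask,
    config: ExtractionConfig,
) -> dict[str, float]:
    """Features for one kidney given a precomputed filter bank.

    ``filtered`` maps variant name (``original``, ``square``, ...,
    ``wavelet-HHH``) to a derived volume on the mask's grid.
    """
    voxel_volume = mask.voxel_volume_mm3
    out: dict[str, float] = {}
    parenchyma = mask.labels == PARENCHYMA
    if "parenchyma" in config.regions and not parenchyma.any():
        raise ValueError(f"kidney ({mask.side}) has no parenchyma region")

    for region_name in config.regions:
        region = mask.labels == REGION_LABELS[region_name]
        present = bool(region.any())
        if region_name == "hydronephrosis":
            out[PRESENCE_COLUMN] = float(present)

        if "shape" in config.families:
            vals = shape_features(region, mask.spacing) if present else dict.fromkeys(SHAPE_NAMES, 0.0)
            for feat, v in vals.items():
                out[f"original__{region_name}__shape_{feat}"] = v

        for variant, arr in filtered.items():
            if present:
                region_vals = arr[region]
                fo = first_order_features(region_vals, voxel_volume, config.bin_width)
                if {"glszm", "ngtdm"} & set(config.families):
                    levels, crop_mask = _texture_inputs(arr, region, config.bin_width)
            if "firstorder" in config.families:
                vals = fo if present else dict.fromkeys(FIRST_ORDER_NAMES, 0.0)
                for feat, v in vals.items():
                    out[f"{variant}__{region_name}__firstorder_{feat}"] = v
            if "glszm" in config.families:
                vals = (
                    glszm_features(glszm_matrix(levels, crop_mask))
                    if present
                    else dict.fromkeys(GLSZM_NAMES, 0.0)
                )
                for feat, v in vals.items():
                    out[f"{variant}__{region_name}__glszm_{feat}"] = v
            if "ngtdm" in config.families:
                vals = (
                    ngtdm_features(ngtdm_matrix(levels, crop_mask))
                    if present
                    else dict.fromkeys(NGTDM_NAMES, 0.0)
                )
                for feat, v in vals.items():
                    out[f"{variant}__{region_name}__ngtdm_{feat}"] = v
    return out


def extract_feature_table(
    volume: CTVolume,
    masks: list[SegmentationMask],
    config: ExtractionConfig | None = None,
    patient_id: str = "patient",
    source: str = "manual",
    filtered: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Extract all enabled features for each kidney mask of one volume.

    Returns a DataFrame indexed by (patient_id, side, source).  Pass a
    precomputed ``filtered`` bank (from :func:`filter_bank`) to share the
    filtering cost between manual and auto masks.
    """
    config = config or ExtractionConfig()
    needs_intensity = {"firstorder", "glszm", "ngtdm"} & set(config.families)
    if filtered is None:
        filtered = (
            filter_bank(volume.voxels, config.filters, volume.spacing, config.wavelet)
            if needs_intensity
            else {}
        )
    rows, index = [], []
    for mask in masks:
        if mask.shape != volume.shape:
            raise ValueError("mask grid does not match volume grid")
        rows.append(extract_kidney_features(filtered, mask, config))
        index.append((patient_id, mask.side, source))
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["patient_id", "side", "source"]))
    feats = df[feature_columns(df)]
    if not np.isfinite(feats.to_numpy()).all():
        bad = feats.columns[~np.isfinite(feats.to_numpy()).all(axis=0)].tolist()
        raise FloatingPointError(f"non-finite feature values in columns {bad[:5]}")
    return df
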