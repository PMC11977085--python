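"""Seeded synthetic phantom cohorts for the GFR/SRF estimation pipeline.

Each phantom patient is a CT-like volume holding two ellipsoidal kidneys
(left/right), each a parenchymal shell with Gaussian-random-field texture
and, in roughly half of kidneys, a water-density hydronephrosis core whose
volume follows a heavy-tailed (zero-inflated lognormal) distribution.
Atrophic kidneys are drawn with reduced semi-axes.  The reference
("SPECT-like") single-kidney GFR is generated from quantities the imaging
pipeline can measure — parenchymal volume, parenchymal density, texture
amplitude, hydronephrosis volume and age — so that end-to-end parameter
recovery is a meaningful test.  Split renal function (SRF) follows from the
two kidney GFRs and sums to 100% per patient.

Default parameters were calibrated once so a default cohort matches the
clinical moments the pipeline targets (mean RPV ~ 153 mL, zero-inflated
RHV ~ 35 mL, single-kidney GFR ~ 40 +/- 14 mL/min/1.73 m2, age ~ 53 y).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import (
    CTVolume,
    SegmentationMask,
    PARENCHYMA,
    HYDRONEPHROSIS,
    region_volume_ml,
    save_mask,
    save_volume,
)

__all__ = [
    "PhantomParams",
    "PhantomKidney",
    "PhantomPatient",
    "generate_cohort",
    "iter_cohort",
    "perturb_mask",
    "truth_table",
    "write_cohort",
]

SIDES = ("left", "right")


@dataclass
class PhantomParams:
    """Tunable study conditions for cohort generation.

    Geometry is in mm, intensities in HU, volumes in mL, GFR in
    mL/min/1.73 m2.  ``gfr_coefs`` are (intercept, per-mL RPV, per-HU
    parenchymal density, per-HU texture amplitude, per-mL RHV [subtracted],
    per-year age [subtracted]).
    """

    n_patients: int = 100
    seed: int = 0
    # grid
    shape: tuple[int, int, int] = (128, 96, 40)
    spacing: tuple[float, float, float] = (1.5, 1.5, 5.0)
    # kidney geometry (ellipsoid semi-axes, mm)
    semi_axes: tuple[float, float, float] = (27.0, 29.0, 54.5)
    semi_axes_rel_sd: float = 0.10
    center_jitter_mm: float = 5.0
    # pathology
    atrophy_prob: float = 0.25
    atrophy_scale: tuple[float, float] = (0.72, 0.90)
    hydro_prob: float = 0.5
    hydro_rhv_log_mu: float = np.log(70.0)
    hydro_rhv_log_sigma: float = 1.2
    hydro_max_core_frac: float = 1.0
    hydro_expansion: float = 0.8  # fraction of RHV added to outer envelope
    # intensities
    parenchyma_hu: tuple[float, float] = (35.0, 5.0)  # patient-kidney mean, sd
    hydro_hu: tuple[float, float] = (5.0, 3.0)
    background_hu: tuple[float, float] = (-45.0, 10.0)
    texture_amplitude: tuple[float, float] = (12.0, 3.0)  # GRF sd in HU
    texture_corr_mm: float = 6.0
    noise_sd: float = 5.0
    # clinical covariates
    age_mean_sd: tuple[float, float] = (52.8, 13.7)
    age_range: tuple[float, float] = (18.0, 90.0)
    male_prob: float = 0.578
    bmi_mean_sd: tuple[float, float] = (23.9, 3.3)
    # reference GFR generative model
    gfr_coefs: tuple[float, float, float, float, float, float] = (
        0.0,
        0.20,
        0.60,
        0.30,
        0.05,
        0.25,
    )
    gfr_noise_sd: float = 7.5
    # auto-segmentation emulation
    mask_perturb_severity: float = 0.6

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(a <= 0 for a in self.semi_axes) or any(s <= 0 for s in self.spacing):
            raise ValueError("geometry and spacing must be strictly positive")
        for p in (self.atrophy_prob, self.hydro_prob, self.male_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for sd in (self.noise_sd, self.gfr_noise_sd, self.semi_axes_rel_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")


@dataclass
class PhantomKidney:
    side: str
    manual_mask: SegmentationMask
    auto_mask: SegmentationMask
    true_gfr: float
    true_srf: float
    rpv_ml: float
    rhv_ml: float
    atrophic: bool
    parenchyma_hu_mean: float
    texture_amplitude: float


@dataclass
class PhantomPatient:
    patient_id: str
    age: float
    sex: str  # "M" / "F"
    bmi: float
    volume: CTVolume
    kidneys: dict[str, PhantomKidney]

    @property
    def true_gfr(self) -> dict[str, float]:
        return {s: k.true_gfr for s, k in self.kidneys.items()}

    @property
    def true_srf(self) -> dict[str, float]:
        return {s: k.true_srf for s, k in self.kidneys.items()}


def _grf(rng: np.random.Generator, shape, spacing, corr_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(shape)
    sigma = [corr_mm / s for s in spacing]
    f = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    q = np.zeros(coords[0].shape)
    for c, ctr, ax in zip(coords, center, semi_axes):
        q += ((c - ctr) / ax) ** 2
    return q <= 1.0


def _render_patient(idx: int, params: PhantomParams, rng: np.random.Generator) -> PhantomPatient:
    shape, spacing = params.shape, params.spacing
    extent = [n * s for n, s in zip(shape, spacing)]
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    voxel_ml = float(np.prod(spacing)) / 1000.0

    age = float(np.clip(rng.normal(*params.age_mean_sd), *params.age_range))
    sex = "M" if rng.random() < params.male_prob else "F"
    bmi = float(rng.normal(*params.bmi_mean_sd))

    bg_mu, bg_sd = params.background_hu
    volume_hu = bg_mu + bg_sd * _grf(rng, shape, spacing, 2.0 * params.texture_corr_mm)

    kidneys: dict[str, dict] = {}
    for side_i, side in enumerate(SIDES):
        axes = np.array(params.semi_axes) * rng.lognormal(
            0.0, params.semi_axes_rel_sd, size=3
        )
        atrophic = rng.random() < params.atrophy_prob
        if atrophic:
            axes = axes * rng.uniform(*params.atrophy_scale)
        v_kidney_ml = 4.0 / 3.0 * np.pi * np.prod(axes) / 1000.0

        hydro = rng.random() < params.hydro_prob
        rhv_target = 0.0
        if hydro:
            rhv_target = float(
                min(
                    rng.lognormal(params.hydro_rhv_log_mu, params.hydro_rhv_log_sigma),
                    params.hydro_max_core_frac * v_kidney_ml,
                )
            )
            # collecting-system dilation expands the outer envelope
            grow = (1.0 + params.hydro_expansion * rhv_target / v_kidney_ml) ** (1.0 / 3.0)
            axes_outer = axes * grow
            v_outer_ml = v_kidney_ml * grow**3
            core_frac = (rhv_target / v_outer_ml) ** (1.0 / 3.0)
        else:
            axes_outer = axes
            core_frac = 0.0

        center = [
            extent[0] * (0.27 if side_i == 0 else 0.73),
            extent[1] / 2.0,
            extent[2] / 2.0,
        ]
        center = [c + rng.uniform(-1, 1) * params.center_jitter_mm for c in center]

        outer = _ellipsoid(coords, center, axes_outer)
        labels = np.zeros(shape, dtype=np.uint8)
        labels[outer] = PARENCHYMA
        if core_frac > 0:
            core = _ellipsoid(coords, center, axes_outer * core_frac)
            labels[core & outer] = HYDRONEPHROSIS

        par_mu = rng.normal(*params.parenchyma_hu)
        tex_amp = max(rng.normal(*params.texture_amplitude), 0.5)
        texture = tex_amp * _grf(rng, shape, spacing, params.texture_corr_mm)
        par = labels == PARENCHYMA
        hyd = labels == HYDRONEPHROSIS
        volume_hu[par] = par_mu + texture[par]
        if hyd.any():
            volume_hu[hyd] = rng.normal(*params.hydro_hu) + 0.3 * texture[hyd]

        kidneys[side] = dict(
            labels=labels,
            atrophic=atrophic,
            par_mu=par_mu,
            tex_amp=tex_amp,
            rpv=float(np.count_nonzero(par)) * voxel_ml,
            rhv=float(np.count_nonzero(hyd)) * voxel_ml,
        )

    volume_hu = volume_hu + params.noise_sd * rng.standard_normal(shape)
    ct = CTVolume(volume_hu.astype(np.float32), spacing)

    b0, b_rpv, b_hu, b_tex, b_rhv, b_age = params.gfr_coefs
    gfr = {}
    for side in SIDES:
        k = kidneys[side]
        gfr[side] = max(
            b0
            + b_rpv * k["rpv"]
            + b_hu * k["par_mu"]
            + b_tex * k["tex_amp"]
            - b_rhv * k["rhv"]
            - b_age * age
            + rng.normal(0.0, params.gfr_noise_sd),
            0.0,
        )
    total = gfr["left"] + gfr["right"]
    srf = (
        {s: 100.0 * gfr[s] / total for s in SIDES}
        if total > 0
        else {s: 50.0 for s in SIDES}
    )

    out_kidneys = {}
    for side in SIDES:
        k = kidneys[side]
        manual = SegmentationMask(k["labels"], spacing, side)
        auto = perturb_mask(
            manual,
            params.mask_perturb_severity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out_kidneys[side] = PhantomKidney(
            side=side,
            manual_mask=manual,
            auto_mask=auto,
            true_gfr=gfr[side],
            true_srf=srf[side],
            rpv_ml=k["rpv"],
            rhv_ml=k["rhv"],
            atrophic=k["atrophic"],
            parenchyma_hu_mean=k["par_mu"],
            texture_amplitude=k["tex_amp"],
        )
    return PhantomPatient(
        patient_id=f"P{idx:04d}", age=age, sex=sex, bmi=bmi, volume=ct, kidneys=out_kidneys
    )


def iter_cohort(params: PhantomParams):
    """Yield phantom patients one at a time (memory-friendly), seeded."""
    children = np.random.SeedSequence(params.seed).spawn(params.n_patients)
    for i, child in enumerate(children):
        yield _render_patient(i, params, np.random.default_rng(child))


def generate_cohort(params: PhantomParams) -> list[PhantomPatient]:
    """Materialize the full cohort; deterministic for a given seed."""
    return list(iter_cohort(params))


def perturb_mask(mask: SegmentationMask, severity: float, seed: int = 0) -> SegmentationMask:
    """Emulate automatic-segmentation error on one kidney mask.

    The signed distance to each region boundary is shifted by a smooth
    random field whose amplitude scales with ``severity`` (boundary-
    localized dilation/erosion), then small disconnected components are
    dropped.  Severity 0 returns an identical mask; the perturbed label
    set never exceeds the original one.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if severity == 0.0:
        return SegmentationMask(mask.labels.copy(), mask.spacing, mask.side, mask.origin)
    rng = np.random.default_rng(seed)
    spacing = np.array(mask.spacing)

    # work on a padded bounding box: the deformation is boundary-local
    if (mask.labels > 0).any():
        sl = ndimage.find_objects((mask.labels > 0).astype(np.int8))[0]
        margin = np.ceil(15.0 / spacing).astype(int)
        sl = tuple(
            slice(max(s.start - m, 0), min(s.stop + m, dim))
            for s, m, dim in zip(sl, margin, mask.labels.shape)
        )
    else:
        sl = tuple(slice(None) for _ in range(3))

    def deform(binary: np.ndarray) -> np.ndarray:
        if not binary.any():
            return binary.copy()
        inside = ndimage.distance_transform_edt(binary, sampling=spacing)
        outside = ndimage.distance_transform_edt(~binary, sampling=spacing)
        signed = inside - outside
        noise = _grf(rng, binary.shape, spacing, corr_mm=8.0)
        out = signed + severity * 6.0 * noise > 0.0
        # drop stray small components away from the main body
        lab, n = ndimage.label(out)
        if n > 1:
            sizes = np.bincount(lab.ravel())[1:]
            keep = np.argmax(sizes) + 1
            for comp in range(1, n + 1):
                if comp != keep and rng.random() < 0.5 + severity / 2.0:
                    out[lab == comp] = False
        return out

    kidney = deform(mask.labels[sl] > 0)
    hydro_orig = mask.labels[sl] == HYDRONEPHROSIS
    crop = np.zeros_like(mask.labels[sl])
    crop[kidney] = PARENCHYMA
    if hydro_orig.any():
        hydro = deform(hydro_orig) & kidney
        crop[hydro] = HYDRONEPHROSIS
    labels = np.zeros_like(mask.labels)
    labels[sl] = crop
    if not (labels == PARENCHYMA).any():  # extreme erosion: keep the original
        labels = mask.labels.copy()
    return SegmentationMask(labels, mask.spacing, mask.side, mask.origin)


def truth_table(patients: list[PhantomPatient]) -> pd.DataFrame:
    """Cohort truth table: one row per kidney with covariates and references."""
    rows = []
    for p in patients:
        for side, k in p.kidneys.items():
            rows.append(
                dict(
                    patient_id=p.patient_id,
                    side=side,
                    age=p.age,
                    sex=p.sex,
                    bmi=p.bmi,
                    true_gfr=k.true_gfr,
                    true_srf=k.true_srf,
                    rpv_ml=k.rpv_ml,
                    rhv_ml=k.rhv_ml,
                    atrophic=k.atrophic,
                )
            )
    return pd.DataFrame(rows)


def write_cohort(patients: list[PhantomPatient], outdir) -> pd.DataFrame:
    """Write NIfTI volumes/masks plus manifest and truth CSVs; returns the manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        vol_path = outdir / f"{p.patient_id}_ct.nii.gz"
        save_volume(p.volume, vol_path)
        for side, k in p.kidneys.items():
            suffix = "L" if side == "left" else "R"
            man_path = outdir / f"{p.patient_id}_mask_{suffix}.nii.gz"
            auto_path = outdir / f"{p.patient_id}_automask_{suffix}.nii.gz"
            save_mask(k.manual_mask, man_path)
            save_mask(k.auto_mask, auto_path)
            rows.append(
                dict(
                    patient_id=p.patient_id,
                    side=side,
                    volume_path=str(vol_path),
                    mask_path=str(man_path),
                    auto_mask_path=str(auto_path),
                )
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    truth_table(patients).to_csv(outdir / "truth.csv", index=False)
    return manifest
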