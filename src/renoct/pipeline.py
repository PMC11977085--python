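"""End-to-end orchestration: extract -> select -> fit -> estimate -> evaluate.

The training pipeline mirrors the estimation chain: radiomic features from
segmented parenchyma/hydronephrosis regions feed a cross-validated elastic
net (rGFR); rGFR plus clinical covariates feed a backward-eliminated MLR
(rcGFR); the rcGFR share, the parenchymal-volume share (pSRF) and the
hydronephrosis-volume share (hSRF) are combined by a second MLR into
rcphSRF.  Evaluation produces agreement panels against the reference
values and diagnostic reports for the five health-status cutoffs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, metrics, models, phantom
from .features import ExtractionConfig, extract_feature_table, feature_columns, filter_bank
from .selection import ICCRepeatabilityFilter, SpearmanRedundancyFilter

logger = logging.getLogger("renoct")

__all__ = [
    "PipelineConfig",
    "CohortData",
    "TrainingResult",
    "build_phantom_dataset",
    "load_manifest_dataset",
    "run_training",
    "run_inference",
    "run_simulation_study",
    "agreement_panel",
    "classification_panel",
]

ESTIMATE_COLUMNS = ["rGFR", "rcGFR", "rcSRF", "pSRF", "hSRF", "rcphSRF"]
GFR_TASKS = ("impaired", "non_functioning")
SRF_TASKS = ("nephrectomy", "lower_function", "non_dominant")


@dataclass
class PipelineConfig:
    """Thresholds and sizes for one pipeline run."""

    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    icc_threshold: float = 0.9
    scc_threshold: float = 0.9
    cv_folds: int = 10
    alpha_stay: float = 0.05
    resample_shape: tuple[int, int, int] | None = None
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        for t in (self.icc_threshold, self.scc_threshold):
            if not 0.0 < t <= 1.0:
                raise ValueError("thresholds must lie in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class CohortData:
    """Aligned per-kidney tables, indexed by (patient_id, side)."""

    manual: pd.DataFrame  # radiomic features, manual segmentation
    auto: pd.DataFrame  # radiomic features, auto-style segmentation
    clinical: pd.DataFrame  # age, sex_male, bmi
    volumetry: pd.DataFrame  # rpv_ml, rhv_ml, percent_rpv, percent_rhv
    reference: pd.DataFrame | None  # true_gfr, true_srf (training only)
    dice: pd.DataFrame | None = None  # parenchyma/hydronephrosis DSC per kidney

    def subset(self, patient_ids) -> "CohortData":
        ids = set(patient_ids)

        def take(df):
            if df is None:
                return None
            return df[df.index.get_level_values("patient_id").isin(ids)]

        return CohortData(
            manual=take(self.manual),
            auto=take(self.auto),
            clinical=take(self.clinical),
            volumetry=take(self.volumetry),
            reference=take(self.reference),
            dice=take(self.dice),
        )

    @property
    def patient_ids(self) -> list[str]:
        return sorted(set(self.manual.index.get_level_values("patient_id")))


def _preprocess(volume, masks, config: PipelineConfig):
    if config.resample_shape is not None:
        volume, masks = imaging.resample_to_grid(volume, masks, config.resample_shape)
    return imaging.window_and_normalize(volume), masks


def build_phantom_dataset(
    params: phantom.PhantomParams, config: PipelineConfig
) -> CohortData:
    """Generate a phantom cohort and extract all per-kidney tables.

    Patients are processed one at a time so rendered volumes never
    accumulate in memory; the filter bank is shared between the manual and
    auto extractions of each patient.
    """
    man_rows, auto_rows, clin, volr, refr, dicer = [], [], [], [], [], []
    for patient in phantom.iter_cohort(params):
        masks_manual = [patient.kidneys[s].manual_mask for s in phantom.SIDES]
        masks_auto = [patient.kidneys[s].auto_mask for s in phantom.SIDES]
        vol, pre_masks = _preprocess(patient.volume, masks_manual + masks_auto, config)
        masks_manual, masks_auto = pre_masks[:2], pre_masks[2:]
        bank = filter_bank(
            vol.voxels, config.extraction.filters, vol.spacing, config.extraction.wavelet
        )
        man_rows.append(
            extract_feature_table(
                vol, masks_manual, config.extraction, patient.patient_id, "manual", bank
            )
        )
        auto_rows.append(
            extract_feature_table(
                vol, masks_auto, config.extraction, patient.patient_id, "auto", bank
            )
        )
        volumetry = imaging.kidney_volumetry(masks_manual[0], masks_manual[1])
        for side, mman, mauto in zip(phantom.SIDES, masks_manual, masks_auto):
            k = patient.kidneys[side]
            key = dict(patient_id=patient.patient_id, side=side)
            clin.append(
                dict(**key, age=patient.age, sex_male=float(patient.sex == "M"), bmi=patient.bmi)
            )
            v = volumetry[side]
            volr.append(
                dict(
                    **key,
                    rpv_ml=v.rpv_ml,
                    rhv_ml=v.rhv_ml,
                    percent_rpv=v.percent_rpv,
                    percent_rhv=v.percent_rhv,
                )
            )
            refr.append(dict(**key, true_gfr=k.true_gfr, true_srf=k.true_srf))
            dicer.append(
                dict(
                    **key,
                    dsc_parenchyma=imaging.dice_coefficient(mman, mauto, imaging.PARENCHYMA),
                    dsc_hydronephrosis=imaging.dice_coefficient(
                        mman, mauto, imaging.HYDRONEPHROSIS
                    ),
                )
            )
        logger.info("extracted %s: %d feature columns", patient.patient_id, man_rows[-1].shape[1])

    def frame(rows):
        return pd.DataFrame(rows).set_index(["patient_id", "side"]).sort_index()

    manual = pd.concat(man_rows).droplevel("source").sort_index()
    auto = pd.concat(auto_rows).droplevel("source").sort_index()
    return CohortData(
        manual=manual,
        auto=auto,
        clinical=frame(clin),
        volumetry=frame(volr),
        reference=frame(refr),
        dice=frame(dicer),
    )


def load_manifest_dataset(
    manifest_path,
    config: PipelineConfig,
    clinical_path=None,
    truth_path=None,
) -> CohortData:
    """Build a dataset from a NIfTI manifest CSV (plus optional clinical/truth CSVs)."""
    manifest = imaging.read_manifest(manifest_path)
    has_auto = "auto_mask_path" in manifest.columns
    man_rows, auto_rows, volr, dicer = [], [], [], []
    for pid, grp in manifest.groupby("patient_id", sort=True):
        vol = imaging.load_volume(grp.iloc[0]["volume_path"])
        masks_manual = [
            imaging.load_mask(r["mask_path"], r["side"]) for _, r in grp.iterrows()
        ]
        masks_auto = (
            [imaging.load_mask(r["auto_mask_path"], r["side"]) for _, r in grp.iterrows()]
            if has_auto
            else [m for m in masks_manual]
        )
        vol, pre = _preprocess(vol, masks_manual + masks_auto, config)
        masks_manual, masks_auto = pre[: len(grp)], pre[len(grp) :]
        bank = filter_bank(
            vol.voxels, config.extraction.filters, vol.spacing, config.extraction.wavelet
        )
        man_rows.append(
            extract_feature_table(vol, masks_manual, config.extraction, pid, "manual", bank)
        )
        auto_rows.append(
            extract_feature_table(vol, masks_auto, config.extraction, pid, "auto", bank)
        )
        if len(masks_manual) == 2:
            sides = {m.side: m for m in masks_manual}
            volumetry = imaging.kidney_volumetry(sides["left"], sides["right"])
        else:
            volumetry = None
        for mman, mauto in zip(masks_manual, masks_auto):
            key = dict(patient_id=pid, side=mman.side)
            if volumetry is not None:
                v = volumetry[mman.side]
                volr.append(
                    dict(
                        **key,
                        rpv_ml=v.rpv_ml,
                        rhv_ml=v.rhv_ml,
                        percent_rpv=v.percent_rpv,
                        percent_rhv=v.percent_rhv,
                    )
                )
            dicer.append(
                dict(
                    **key,
                    dsc_parenchyma=imaging.dice_coefficient(mman, mauto, imaging.PARENCHYMA),
                    dsc_hydronephrosis=imaging.dice_coefficient(
                        mman, mauto, imaging.HYDRONEPHROSIS
                    ),
                )
            )

    def frame(rows):
        return pd.DataFrame(rows).set_index(["patient_id", "side"]).sort_index() if rows else None

    clinical = None
    if clinical_path is not None:
        clinical = pd.read_csv(clinical_path).set_index(["patient_id", "side"]).sort_index()
    reference = None
    if truth_path is not None:
        truth = pd.read_csv(truth_path).set_index(["patient_id", "side"]).sort_index()
        reference = truth[["true_gfr", "true_srf"]]
        if clinical is None and "age" in truth.columns:
            clinical = pd.DataFrame(
                dict(
                    age=truth["age"],
                    sex_male=(truth["sex"] == "M").astype(float),
                    bmi=truth["bmi"],
                )
            )
    return CohortData(
        manual=pd.concat(man_rows).droplevel("source").sort_index(),
        auto=pd.concat(auto_rows).droplevel("source").sort_index(),
        clinical=clinical,
        volumetry=frame(volr),
        reference=reference,
        dice=frame(dicer),
    )


# ---------------------------------------------------------------------------
# training / inference


@dataclass
class TrainingResult:
    config: PipelineConfig
    icc_filter: ICCRepeatabilityFilter
    scc_filter: SpearmanRedundancyFilter
    rgfr_model: models.ElasticNetGFR
    rcgfr_model: models.BackwardLinearRegression
    psrf_model: models.PercentVolumeSRF
    hsrf_model: models.PercentVolumeSRF | None
    rcphsrf_model: models.BackwardLinearRegression
    estimates: pd.DataFrame
    agreement: dict[str, metrics.AgreementReport]
    classification: list[metrics.ClassificationReport]
    notes: list[str] = field(default_factory=list)

    @property
    def retained_features(self) -> list[str]:
        return self.scc_filter.retained_


def _drop_constant(candidates: pd.DataFrame, notes: list[str]) -> pd.DataFrame:
    """Remove zero-variance predictor candidates (would make OLS singular)."""
    keep = candidates.columns[candidates.std() > 0]
    for c in candidates.columns.difference(keep):
        notes.append(f"candidate {c} constant in cohort: dropped before MLR")
    return candidates[keep]


def _percent_rhv_filled(volumetry: pd.DataFrame) -> pd.Series:
    """Hydronephrosis volume share; 0.5 for patients with no hydronephrosis."""
    return volumetry["percent_rhv"].fillna(0.5)


def _rcsrf_from_pairs(rcgfr: pd.Series) -> pd.Series:
    out = pd.Series(index=rcgfr.index, dtype=float)
    for pid, grp in rcgfr.groupby(level="patient_id"):
        if len(grp) != 2:
            raise ValueError(f"patient {pid} does not have exactly two kidneys")
        sides = grp.index.get_level_values("side").tolist()
        left = grp[grp.index.get_level_values("side") == "left"].iloc[0]
        right = grp[grp.index.get_level_values("side") == "right"].iloc[0]
        srf_l, srf_r = models.compute_rcsrf(left, right)
        out[(pid, "left")] = srf_l
        out[(pid, "right")] = srf_r
    return out


def run_training(dataset: CohortData, config: PipelineConfig) -> TrainingResult:
    """Fit the full estimation chain on a cohort with reference values."""
    if dataset.reference is None:
        raise ValueError("training requires a reference table with true_gfr and true_srf")
    for col in ("true_gfr", "true_srf"):
        if col not in dataset.reference.columns:
            raise ValueError(f"reference table is missing column {col!r}")
    feats = feature_columns(dataset.manual)
    manual = dataset.manual[feats]
    auto = dataset.auto[feats]
    ref = dataset.reference.loc[manual.index]
    notes: list[str] = []

    logger.info("stage=icc rows=%d cols=%d", *manual.shape)
    icc = ICCRepeatabilityFilter(config.icc_threshold).fit(manual, auto)
    logger.info("stage=scc retained_in=%d", len(icc.retained_))
    scc = SpearmanRedundancyFilter(config.scc_threshold).fit(icc.transform(manual))
    selected = scc.transform(manual)
    logger.info("stage=elasticnet features=%d", selected.shape[1])

    groups = selected.index.get_level_values("patient_id")
    rgfr_model = models.ElasticNetGFR(cv=config.cv_folds, seed=config.seed).fit(
        selected, ref["true_gfr"], groups=groups
    )
    rgfr = pd.Series(rgfr_model.predict(selected), index=selected.index, name="rGFR")

    clin = dataset.clinical.loc[selected.index]
    rcgfr_candidates = pd.DataFrame(
        dict(rGFR=rgfr, age=clin["age"], sex_male=clin["sex_male"], bmi=clin["bmi"])
    )
    rcgfr_candidates = _drop_constant(rcgfr_candidates, notes)
    rcgfr_model = models.BackwardLinearRegression(config.alpha_stay).fit(
        rcgfr_candidates, ref["true_gfr"]
    )
    rcgfr = pd.Series(rcgfr_model.predict(rcgfr_candidates), index=selected.index, name="rcGFR")

    rcsrf = _rcsrf_from_pairs(rcgfr)
    volumetry = dataset.volumetry.loc[selected.index]
    psrf_model = models.PercentVolumeSRF().fit(volumetry["percent_rpv"], ref["true_srf"])
    psrf = pd.Series(
        psrf_model.predict(volumetry["percent_rpv"]), index=selected.index, name="pSRF"
    )
    prhv = _percent_rhv_filled(volumetry)
    if prhv.std() == 0:
        hsrf_model = None
        hsrf = pd.Series(50.0, index=selected.index, name="hSRF")
        notes.append("no hydronephrosis variance in cohort: hSRF uninformative (50%)")
    else:
        hsrf_model = models.PercentVolumeSRF().fit(prhv, ref["true_srf"])
        hsrf = pd.Series(hsrf_model.predict(prhv), index=selected.index, name="hSRF")

    srf_candidates = _drop_constant(
        pd.DataFrame(dict(rcSRF=rcsrf, pSRF=psrf, hSRF=hsrf)), notes
    )
    rcphsrf_model = models.BackwardLinearRegression(config.alpha_stay).fit(
        srf_candidates, ref["true_srf"]
    )
    rcphsrf = pd.Series(
        np.clip(rcphsrf_model.predict(srf_candidates), 0.0, 100.0),
        index=selected.index,
        name="rcphSRF",
    )

    estimates = pd.DataFrame(
        dict(rGFR=rgfr, rcGFR=rcgfr, rcSRF=rcsrf, pSRF=psrf, hSRF=hsrf, rcphSRF=rcphsrf)
    )
    agreement = agreement_panel(estimates, ref)
    classification = classification_panel(estimates, ref)
    return TrainingResult(
        config=config,
        icc_filter=icc,
        scc_filter=scc,
        rgfr_model=rgfr_model,
        rcgfr_model=rcgfr_model,
        psrf_model=psrf_model,
        hsrf_model=hsrf_model,
        rcphsrf_model=rcphsrf_model,
        estimates=estimates,
        agreement=agreement,
        classification=classification,
        notes=notes,
    )


def run_inference(result: TrainingResult, dataset: CohortData) -> pd.DataFrame:
    """Apply fitted models to a new cohort; never refits."""
    feats = result.retained_features
    missing = [f for f in feats if f not in dataset.manual.columns]
    if missing:
        raise ValueError(f"new extraction lacks required features: {missing[:5]}")
    selected = dataset.manual[feats]
    rgfr = pd.Series(result.rgfr_model.predict(dataset.manual), index=selected.index)
    clin = dataset.clinical.loc[selected.index]
    rcgfr_candidates = pd.DataFrame(
        dict(rGFR=rgfr, age=clin["age"], sex_male=clin["sex_male"], bmi=clin["bmi"])
    )
    rcgfr = pd.Series(result.rcgfr_model.predict(rcgfr_candidates), index=selected.index)
    rcsrf = _rcsrf_from_pairs(rcgfr)
    volumetry = dataset.volumetry.loc[selected.index]
    psrf = pd.Series(
        result.psrf_model.predict(volumetry["percent_rpv"]), index=selected.index
    )
    prhv = _percent_rhv_filled(volumetry)
    if result.hsrf_model is None:
        hsrf = pd.Series(50.0, index=selected.index)
    else:
        hsrf = pd.Series(result.hsrf_model.predict(prhv), index=selected.index)
    srf_candidates = pd.DataFrame(dict(rcSRF=rcsrf, pSRF=psrf, hSRF=hsrf))
    rcphsrf = pd.Series(
        np.clip(result.rcphsrf_model.predict(srf_candidates), 0.0, 100.0),
        index=selected.index,
    )
    return pd.DataFrame(
        dict(rGFR=rgfr, rcGFR=rcgfr, rcSRF=rcsrf, pSRF=psrf, hSRF=hsrf, rcphSRF=rcphsrf)
    )


def agreement_panel(estimates: pd.DataFrame, ref: pd.DataFrame):
    panel = {}
    for name in ESTIMATE_COLUMNS:
        target = ref["true_gfr"] if name in ("rGFR", "rcGFR") else ref["true_srf"]
        panel[name] = metrics.agreement_report(estimates[name], target)
    return panel


def classification_panel(estimates: pd.DataFrame, ref: pd.DataFrame):
    reports = []
    for task in GFR_TASKS + SRF_TASKS:
        rule = metrics.HEALTH_STATUS_RULES[task]
        est = estimates["rcGFR"] if task in GFR_TASKS else estimates["rcphSRF"]
        target = ref["true_gfr"] if task in GFR_TASKS else ref["true_srf"]
        truth = np.array([rule.is_positive(v) for v in target])
        pred = np.array([rule.is_positive(v) for v in est])
        if truth.all() or not truth.any():
            report = metrics.diagnostic_metrics_cp(pred, truth, task=task)
            report.notes.append("single-class task: AUC undefined")
        else:
            auc, ci = metrics.roc_auc_delong(-est.to_numpy(), truth)
            report = metrics.diagnostic_metrics_cp(pred, truth, task=task, auc=auc, auc_ci=ci)
        reports.append(report)
    return reports


# ---------------------------------------------------------------------------
# artifacts


def write_artifacts(result: TrainingResult, outdir, dataset: CohortData | None = None) -> None:
    """Write models, selections, estimates and reports to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.estimates.round(10).to_csv(out / "estimates.csv")
    model_dict = {
        "rgfr": result.rgfr_model,
        "rcgfr": result.rcgfr_model,
        "psrf": result.psrf_model,
        "rcphsrf": result.rcphsrf_model,
    }
    if result.hsrf_model is not None:
        model_dict["hsrf"] = result.hsrf_model
    models.save_models_json(model_dict, out / "models.json")
    result.icc_filter.report_.to_json(out / "selection_icc.json")
    result.scc_filter.report_.to_json(out / "selection_spearman.json")
    (out / "retained_features.txt").write_text("\n".join(result.retained_features) + "\n")
    with open(out / "agreement.json", "w") as fh:
        json.dump(
            {k: v.to_dict() for k, v in result.agreement.items()}, fh, indent=2, sort_keys=True
        )
    with open(out / "classification.json", "w") as fh:
        json.dump([r.to_dict() for r in result.classification], fh, indent=2, sort_keys=True)
    if dataset is not None and dataset.dice is not None:
        dataset.dice.round(10).to_csv(out / "dice.csv")
    if dataset is not None and dataset.reference is not None:
        scatter = result.estimates.join(dataset.reference)
        scatter.round(10).to_csv(out / "scatter.csv")
        ba = {
            name: metrics.bland_altman(
                result.estimates[name],
                dataset.reference["true_gfr" if name in ("rGFR", "rcGFR") else "true_srf"],
            ).to_dict()
            for name in ESTIMATE_COLUMNS
        }
        with open(out / "bland_altman.json", "w") as fh:
            json.dump(ba, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# simulation study


def split_patients(patient_ids: list[str], train_frac: float, seed: int) -> tuple[list[str], list[str]]:
    rng = np.random.default_rng(seed)
    ids = sorted(patient_ids)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_frac * len(ids)))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def evaluate_estimates(estimates: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """r/MAE/MSE/CCC of every estimator against the reference, one row each."""
    rows = []
    ref = reference.loc[estimates.index]
    for name in ESTIMATE_COLUMNS:
        target = ref["true_gfr"] if name in ("rGFR", "rcGFR") else ref["true_srf"]
        rep = metrics.agreement_report(estimates[name], target)
        rows.append(
            dict(estimator=name, r=rep.pearson_r, mae=rep.mae, mse=rep.mse, ccc=rep.ccc)
        )
    return pd.DataFrame(rows).set_index("estimator")


def run_simulation_study(
    params: phantom.PhantomParams,
    replicates: int = 1,
    seed: int = 0,
    train_frac: float = 0.6,
    config: PipelineConfig | None = None,
):
    """Repeated generate/split/train/test cycles; returns (per-replicate, summary).

    Each replicate renders a fresh cohort (sub-seeded), splits it by
    patient, fits the full chain on the training patients and evaluates
    r/MAE/MSE/CCC of each estimator against the simulated truth on the
    held-out patients.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or PipelineConfig(seed=seed)
    rows = []
    for rep in range(replicates):
        rep_seed = (seed + 104729 * rep) % (2**31 - 1)
        rep_params = dataclasses.replace(params, seed=rep_seed)
        dataset = build_phantom_dataset(rep_params, config)
        train_ids, test_ids = split_patients(dataset.patient_ids, train_frac, rep_seed)
        train, test = dataset.subset(train_ids), dataset.subset(test_ids)
        result = run_training(train, dataclasses.replace(config, seed=rep_seed))
        est_test = run_inference(result, test)
        perf = evaluate_estimates(est_test, test.reference)
        for name, row in perf.iterrows():
            rows.append(dict(replicate=rep, estimator=name, **row.to_dict()))
    per_rep = pd.DataFrame(rows)
    summary = per_rep.groupby("estimator")[["r", "mae", "mse", "ccc"]].agg(["mean", "std"])
    return per_rep, summary
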