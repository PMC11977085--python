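"""GFR and split-renal-function estimators.

* :class:`ElasticNetGFR` — penalized linear model mapping retained radiomic
  features to single-kidney GFR (rGFR); hyperparameters by patient-grouped
  ten-fold cross-validation.
* :class:`BackwardLinearRegression` — multivariable linear regression with
  backward elimination at a stay threshold (used for rcGFR from
  {rGFR, age, sex, BMI} and for rcphSRF from {rcSRF, pSRF, hSRF}).
* :func:`compute_rcsrf` — SRF as each kidney's share of the patient's total
  estimated GFR.
* :class:`PercentVolumeSRF` — simple linear regression of SRF on a kidney's
  share of total parenchymal (pSRF) or hydronephrosis (hSRF) volume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import GroupKFold, KFold

__all__ = [
    "ElasticNetGFR",
    "BackwardLinearRegression",
    "PercentVolumeSRF",
    "RankDeficiencyError",
    "compute_rcsrf",
    "fit_elastic_net_cv",
    "fit_mlr_backward",
    "fit_percent_volume_srf",
]

# Estimated GFR values are floored here before forming SRF ratios, so a
# (possible) negative linear-model output cannot produce SRF outside [0, 100].
GFR_FLOOR = 0.01


class RankDeficiencyError(ValueError):
    """Raised when a linear design matrix is singular/collinear."""


class ElasticNetGFR(BaseEstimator, RegressorMixin):
    """Elastic-net regression of single-kidney GFR on radiomic features.

    Features are standardized internally; fitted coefficients are reported
    on the original feature scale (``coef_``, ``intercept_``).  The mixing
    ratio grid is {0.1, ..., 1.0} and penalty strengths span six decades,
    selected by ``cv``-fold cross-validation grouped by patient so paired
    kidneys never straddle a fold.
    """

    def __init__(
        self,
        cv: int = 10,
        l1_ratios: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
        n_alphas: int = 60,
        alpha_decades: float = 6.0,
        alphas: tuple[float, ...] | None = None,
        seed: int = 0,
        max_iter: int = 50_000,
    ):
        self.cv = cv
        self.l1_ratios = l1_ratios
        self.n_alphas = n_alphas
        self.alpha_decades = alpha_decades
        self.alphas = alphas  # explicit penalty grid overrides the automatic one
        self.seed = seed
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y, groups=None) -> "ElasticNetGFR":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        n = len(X)
        if n < self.cv:
            raise ValueError(f"need at least cv={self.cv} rows, got {n}")
        if X.isna().to_numpy().any() or not np.isfinite(y).all():
            raise ValueError("missing or non-finite values in features/target")
        self.feature_names_ = list(X.columns)
        xv = X.to_numpy(float)
        self.scale_mean_ = xv.mean(axis=0)
        sd = xv.std(axis=0)
        self.scale_sd_ = np.where(sd > 0, sd, 1.0)
        xs = (xv - self.scale_mean_) / self.scale_sd_

        if y.std() == 0:
            warnings.warn("zero-variance target: fitting intercept-only model")
            self.intercept_ = float(y.mean())
            self.coef_ = np.zeros(xs.shape[1])
            self.alpha_ = None
            self.l1_ratio_ = None
            self.selected_features_ = []
            return self

        if self.alphas is not None:
            alphas = np.asarray(self.alphas, dtype=float)
        else:
            # alpha grid: six decades below the smallest lasso-null alpha
            alpha_max = np.max(np.abs(xs.T @ (y - y.mean()))) / (n * min(self.l1_ratios))
            alphas = np.logspace(
                np.log10(alpha_max), np.log10(alpha_max) - self.alpha_decades, self.n_alphas
            )
        if groups is not None:
            splits = list(GroupKFold(n_splits=self.cv).split(xs, y, groups))
        else:
            splits = list(
                KFold(n_splits=self.cv, shuffle=True, random_state=self.seed).split(xs)
            )
        model = ElasticNetCV(
            l1_ratio=list(self.l1_ratios),
            alphas=alphas,
            cv=splits,
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence chatter at tiny alphas
            model.fit(xs, y)
        self.alpha_ = float(model.alpha_)
        self.l1_ratio_ = float(model.l1_ratio_)
        # back-transform to original feature scale
        self.coef_ = model.coef_ / self.scale_sd_
        self.intercept_ = float(model.intercept_ - np.sum(model.coef_ * self.scale_mean_ / self.scale_sd_))
        self.selected_features_ = [
            f for f, c in zip(self.feature_names_, self.coef_) if c != 0.0
        ]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names_ if f not in pd.DataFrame(X).columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing[:5]}")
        xv = pd.DataFrame(X)[self.feature_names_].to_numpy(float)
        return self.intercept_ + xv @ self.coef_

    def to_dict(self) -> dict:
        return dict(
            model="elastic_net",
            intercept=self.intercept_,
            coefficients=dict(zip(self.feature_names_, map(float, self.coef_))),
            alpha=self.alpha_,
            l1_ratio=self.l1_ratio_,
            standardization=dict(
                mean=dict(zip(self.feature_names_, map(float, self.scale_mean_))),
                sd=dict(zip(self.feature_names_, map(float, self.scale_sd_))),
            ),
            selected_features=self.selected_features_,
        )


class BackwardLinearRegression(BaseEstimator, RegressorMixin):
    """OLS with backward elimination of predictors at ``alpha_stay``.

    All candidates are fitted, then the predictor with the largest p-value
    >= ``alpha_stay`` is removed and the model refitted, until every
    retained predictor is significant.  The intercept is always kept; an
    all-noise candidate set collapses to an intercept-only model.
    """

    def __init__(self, alpha_stay: float = 0.05):
        self.alpha_stay = alpha_stay

    def fit(self, X: pd.DataFrame, y) -> "BackwardLinearRegression":
        X = pd.DataFrame(X).astype(float)
        y = np.asarray(y, dtype=float)
        if len(X) < X.shape[1] + 2:
            raise ValueError("need at least n_candidates + 2 rows")
        self.candidates_ = list(X.columns)
        current = list(X.columns)
        while True:
            design = sm.add_constant(X[current], has_constant="add")
            if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
                offenders = _collinear_columns(design)
                raise RankDeficiencyError(
                    f"singular design matrix; collinear columns: {offenders}"
                )
            fit = sm.OLS(y, design).fit()
            if not current:
                break
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] >= self.alpha_stay:
                current = [c for c in current if c != worst]
            else:
                break
        self.retained_ = current
        self.result_ = fit
        self.intercept_ = float(fit.params["const"])
        self.coef_ = {c: float(fit.params[c]) for c in current}
        self.pvalues_ = {c: float(fit.pvalues[c]) for c in current}
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        out = np.full(len(X), self.intercept_)
        for c, b in self.coef_.items():
            if c not in X.columns:
                raise ValueError(f"missing predictor column: {c}")
            out = out + b * X[c].to_numpy(float)
        return out

    def to_dict(self) -> dict:
        return dict(
            model="backward_mlr",
            alpha_stay=self.alpha_stay,
            intercept=self.intercept_,
            coefficients=self.coef_,
            pvalues=self.pvalues_,
            candidates=self.candidates_,
            retained=self.retained_,
        )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Name columns involved in the rank deficiency (smallest singular vectors)."""
    mat = design.to_numpy(float)
    _, s, vt = np.linalg.svd(mat, full_matrices=False)
    tol = s.max() * max(mat.shape) * np.finfo(float).eps
    null_rows = vt[s < tol]
    names = design.columns.to_numpy()
    offenders: list[str] = []
    for row in null_rows:
        offenders.extend(names[np.abs(row) > 1e-8].tolist())
    return sorted(set(offenders))


def compute_rcsrf(gfr_left: float, gfr_right: float) -> tuple[float, float]:
    """Split renal function (%) from the two estimated single-kidney GFRs.

    Each value is floored at ``GFR_FLOOR`` before the ratio so that
    degenerate (non-positive) estimates cannot break the ratio; the pair
    always sums to exactly 100.
    """
    left = max(float(gfr_left), GFR_FLOOR)
    right = max(float(gfr_right), GFR_FLOOR)
    total = left + right
    return 100.0 * left / total, 100.0 * right / total


class PercentVolumeSRF(BaseEstimator, RegressorMixin):
    """SRF ~ a + b * (volume share), predictions clipped to [0, 100].

    ``volume share`` is a kidney's fraction of the patient's total
    parenchymal volume (pSRF) or hydronephrosis volume (hSRF).  When a
    patient has no hydronephrosis at all, both kidneys carry the
    uninformative share 0.5 (handled upstream).
    """

    def __init__(self):
        pass

    def fit(self, percent_volume, srf) -> "PercentVolumeSRF":
        x = np.asarray(percent_volume, dtype=float)
        y = np.asarray(srf, dtype=float)
        if x.size < 3:
            raise ValueError("need at least 3 kidneys")
        if x.std() == 0:
            raise ValueError("zero-variance volume share predictor")
        b, a = np.polyfit(x, y, 1)
        self.slope_ = float(b)
        self.intercept_ = float(a)
        return self

    def predict(self, percent_volume) -> np.ndarray:
        x = np.asarray(percent_volume, dtype=float)
        return np.clip(self.intercept_ + self.slope_ * x, 0.0, 100.0)

    def to_dict(self) -> dict:
        return dict(model="percent_volume_srf", intercept=self.intercept_, slope=self.slope_)


# ---------------------------------------------------------------------------
# thin functional wrappers


def fit_elastic_net_cv(features: pd.DataFrame, target, folds: int = 10, seed: int = 0, groups=None):
    return ElasticNetGFR(cv=folds, seed=seed).fit(features, target, groups=groups)


def fit_mlr_backward(candidates: pd.DataFrame, target, alpha_stay: float = 0.05):
    return BackwardLinearRegression(alpha_stay=alpha_stay).fit(candidates, target)


def fit_percent_volume_srf(percent_volume, reference_srf):
    return PercentVolumeSRF().fit(percent_volume, reference_srf)


def save_models_json(models: dict[str, object], path) -> None:
    """Serialize a dict of fitted models (anything with ``to_dict``) to JSON."""
    payload = {name: m.to_dict() for name, m in models.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
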