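"""Agreement, error-comparison and diagnostic-classification statistics.

Implements the method-agreement suite (Pearson r, MAE/MSE, Lin's
concordance correlation with Fisher-z CI, reduced-major-axis regression,
paired t, Bland-Altman limits of agreement, Wilcoxon error comparison),
the five published health-status cutoff rules, AUC with DeLong variance
and paired DeLong AUC comparison, exact (Clopper-Pearson) binomial CIs for
diagnostic rates, and the baseline cohort comparison (Mann-Whitney U /
chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "BlandAltmanReport",
    "ClassificationReport",
    "HealthStatusRule",
    "HEALTH_STATUS_RULES",
    "agreement_report",
    "bland_altman",
    "classify_health_status",
    "clopper_pearson",
    "cohort_baseline_comparison",
    "concordance_correlation",
    "delong_paired_test",
    "diagnostic_metrics_cp",
    "paired_error_comparison",
    "reduced_major_axis",
    "roc_auc_delong",
    "summarize_tasks",
]


# ---------------------------------------------------------------------------
# agreement


@dataclass
class AgreementReport:
    n: int
    pearson_r: float
    pearson_p: float
    mae: float
    mse: float
    ccc: float
    ccc_ci: tuple[float, float]
    rma_slope: float
    rma_intercept: float
    paired_t_p: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def concordance_correlation(x, y) -> float:
    """Lin's CCC with population (n-denominator) moments."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = np.mean((x - mx) * (y - my))
    return float(2.0 * cov / (vx + vy + (mx - my) ** 2))


def _ccc_ci(ccc: float, r: float, x, y, alpha: float = 0.05) -> tuple[float, float]:
    """Lin's asymptotic CI on the Fisher-z scale."""
    n = len(x)
    if n <= 3 or abs(ccc) >= 1 or r == 0:
        return (float("nan"), float("nan"))
    u = (np.mean(x) - np.mean(y)) / np.sqrt(np.std(x) * np.std(y))
    c2 = ccc**2
    se2 = (
        (1 - r**2) * c2 / ((1 - c2) * r**2)
        + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - c2) ** 2)
        - c2**2 * u**4 / (2 * r**2 * (1 - c2) ** 2)
    ) / (n - 2)
    se2 = max(se2, 0.0)
    z = np.arctanh(ccc)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    return tuple(float(np.tanh(z + s * zcrit * np.sqrt(se2))) for s in (-1, 1))


def reduced_major_axis(x, y) -> tuple[float, float]:
    """Symmetric line fit: slope = sign(r) * sd(y)/sd(x), through the means."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r = np.corrcoef(x, y)[0, 1]
    slope = float(np.sign(r) if r != 0 else 1.0) * y.std() / x.std()
    return float(slope), float(y.mean() - slope * x.mean())


def agreement_report(estimates, references) -> AgreementReport:
    """Full agreement panel of estimates against reference measurements.

    ``x`` in the RMA/CCC formulas is the reference axis, matching scatter
    plots of estimate (y) against reference (x).
    """
    y = np.asarray(estimates, float)
    x = np.asarray(references, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    mae = float(np.mean(np.abs(y - x)))
    mse = float(np.mean((y - x) ** 2))
    if x.std() == 0 or y.std() == 0:
        return AgreementReport(
            n=x.size,
            pearson_r=float("nan"),
            pearson_p=float("nan"),
            mae=mae,
            mse=mse,
            ccc=float("nan"),
            ccc_ci=(float("nan"), float("nan")),
            rma_slope=float("nan"),
            rma_intercept=float("nan"),
            paired_t_p=float("nan"),
            degenerate=True,
        )
    r, p = stats.pearsonr(x, y)
    ccc = concordance_correlation(x, y)
    slope, intercept = reduced_major_axis(x, y)
    if np.allclose(x, y):
        t_p = 1.0
    else:
        t_p = float(stats.ttest_rel(y, x).pvalue)
    return AgreementReport(
        n=x.size,
        pearson_r=float(r),
        pearson_p=float(p),
        mae=mae,
        mse=mse,
        ccc=ccc,
        ccc_ci=_ccc_ci(ccc, float(r), x, y),
        rma_slope=slope,
        rma_intercept=intercept,
        paired_t_p=t_p,
    )


@dataclass
class BlandAltmanReport:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    fraction_within: float

    def to_dict(self) -> dict:
        return asdict(self)


def bland_altman(estimates, references, k: float = 1.96) -> BlandAltmanReport:
    """Limits of agreement: mean difference +/- k * sample SD."""
    d = np.asarray(estimates, float) - np.asarray(references, float)
    if d.size < 2:
        raise ValueError("need at least 2 paired observations")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - k * sd, mean + k * sd
    within = float(np.mean((d >= lo) & (d <= hi)))
    return BlandAltmanReport(mean, sd, lo, hi, within)


def paired_error_comparison(errors_a, errors_b) -> float:
    """Two-sided Wilcoxon signed-rank p for paired error vectors.

    Exact distribution for n <= 25 untied samples; normal approximation
    with tie correction otherwise.  Zero differences are dropped; all-zero
    differences give p = 1.
    """
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    return float(
        stats.wilcoxon(d, zero_method="wilcox", method=method, correction=False).pvalue
    )


# ---------------------------------------------------------------------------
# health-status classification


@dataclass(frozen=True)
class HealthStatusRule:
    """One published cutoff; ``positive`` labels the poor-health class."""

    name: str
    variable: str  # "GFR" or "SRF"
    cutoff: float
    inclusive: bool  # True: value <= cutoff is positive; False: value < cutoff
    positive: str
    negative: str

    def is_positive(self, value: float) -> bool:
        return value <= self.cutoff if self.inclusive else value < self.cutoff


HEALTH_STATUS_RULES: dict[str, HealthStatusRule] = {
    r.name: r
    for r in (
        HealthStatusRule("impaired", "GFR", 30.0, True, "impaired", "normal"),
        HealthStatusRule("non_functioning", "GFR", 10.0, False, "non-functioning", "functioning"),
        HealthStatusRule("nephrectomy", "SRF", 15.0, False, "nephrectomy", "non-nephrectomy"),
        HealthStatusRule("lower_function", "SRF", 45.0, False, "lower", "not-lower"),
        HealthStatusRule("non_dominant", "SRF", 60.0, True, "non-dominant", "dominant"),
    )
}


def classify_health_status(value: float, rule: HealthStatusRule | str) -> str:
    if isinstance(rule, str):
        if rule not in HEALTH_STATUS_RULES:
            raise KeyError(f"unknown health-status rule {rule!r}")
        rule = HEALTH_STATUS_RULES[rule]
    return rule.positive if rule.is_positive(value) else rule.negative


# ---------------------------------------------------------------------------
# ROC / DeLong


def _structural_components(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the DeLong placement values V10 (per positive), V01 (per negative)."""
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > n) + 0.5 * np.sum(pos == n)) / pos.size for n in neg])
    return float(v10.mean()), v10, v01


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def roc_auc_delong(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC (Mann-Whitney estimator, half-credit ties) with a DeLong CI.

    ``labels`` are True for the positive (poor-health) class, and scores
    must be oriented so larger values indicate the positive class.
    """
    pos, neg = _split(scores, labels)
    auc, v10, v01 = _structural_components(pos, neg)
    var = (
        (np.var(v10, ddof=1) / pos.size if pos.size > 1 else 0.0)
        + (np.var(v01, ddof=1) / neg.size if neg.size > 1 else 0.0)
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return auc, (max(auc - half, 0.0), min(auc + half, 1.0))


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Paired DeLong test of AUC(a) vs AUC(b); returns (z, two-sided p)."""
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    auc_a, v10_a, v01_a = _structural_components(pos_a, neg_a)
    auc_b, v10_b, v01_b = _structural_components(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# diagnostic rates with exact CIs


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial CI from Beta quantiles, as a fraction."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass
class ClassificationReport:
    """Diagnostic performance for one health-status task.

    Rates are percentages with (k, n) counts and exact 95% CIs; the
    positive class is the poor-health status.
    """

    task: str
    auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    accuracy_counts: tuple[int, int]
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_counts: tuple[int, int]
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_counts: tuple[int, int]
    specificity_ci: tuple[float, float]
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _rate(k: int, n: int) -> tuple[float, tuple[int, int], tuple[float, float]]:
    if n == 0:
        return float("nan"), (0, 0), (float("nan"), float("nan"))
    lo, hi = clopper_pearson(k, n)
    return 100.0 * k / n, (k, n), (100.0 * lo, 100.0 * hi)


def diagnostic_metrics_cp(predicted, truth, task: str = "", auc: float = float("nan"), auc_ci=(float("nan"), float("nan"))) -> ClassificationReport:
    """Accuracy/sensitivity/specificity with Clopper-Pearson 95% CIs.

    ``predicted`` and ``truth`` are boolean arrays (True = positive
    class); an empty positive or negative class leaves the affected rate
    undefined (nan) with a note.
    """
    pred = np.asarray(predicted).astype(bool)
    true = np.asarray(truth).astype(bool)
    n = true.size
    tp = int(np.sum(pred & true))
    tn = int(np.sum(~pred & ~true))
    npos = int(true.sum())
    nneg = n - npos
    notes = []
    if npos == 0:
        notes.append("no positive cases: sensitivity undefined")
    if nneg == 0:
        notes.append("no negative cases: specificity undefined")
    acc, acc_k, acc_ci = _rate(tp + tn, n)
    sens, sens_k, sens_ci = _rate(tp, npos)
    spec, spec_k, spec_ci = _rate(tn, nneg)
    return ClassificationReport(
        task=task,
        auc=auc,
        auc_ci=tuple(auc_ci),
        accuracy=acc,
        accuracy_counts=acc_k,
        accuracy_ci=acc_ci,
        sensitivity=sens,
        sensitivity_counts=sens_k,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_counts=spec_k,
        specificity_ci=spec_ci,
        notes=notes,
    )


def summarize_tasks(reports: list[ClassificationReport]) -> dict[str, float]:
    """Unweighted mean row over tasks (nan-skipping for undefined rates)."""
    if not reports:
        raise ValueError("need at least one task report")

    def nanmean(values):
        values = [v for v in values if np.isfinite(v)]
        return float(np.mean(values)) if values else float("nan")

    return dict(
        auc=nanmean([r.auc for r in reports]),
        accuracy=nanmean([r.accuracy for r in reports]),
        sensitivity=nanmean([r.sensitivity for r in reports]),
        specificity=nanmean([r.specificity for r in reports]),
    )


# ---------------------------------------------------------------------------
# cohort baseline comparison


def cohort_baseline_comparison(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
) -> pd.DataFrame:
    """Per-variable two-group p-values.

    Continuous variables: two-sided Mann-Whitney U with tie correction;
    categorical: Pearson chi-square without continuity correction.
    Variables constant in both groups are flagged with a nan p-value.
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be non-empty")
    rows = []
    for var in continuous:
        a = group_a[var].dropna().to_numpy(float)
        b = group_b[var].dropna().to_numpy(float)
        if np.concatenate([a, b]).std() == 0:
            rows.append(dict(variable=var, test="mann-whitney", p=float("nan"), flag="constant"))
            continue
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(dict(variable=var, test="mann-whitney", p=p, flag=""))
    for var in categorical:
        a = group_a[var].dropna()
        b = group_b[var].dropna()
        cats = sorted(set(a) | set(b))
        if len(cats) < 2:
            rows.append(dict(variable=var, test="chi2", p=float("nan"), flag="constant"))
            continue
        tab = np.array(
            [[int((g == c).sum()) for c in cats] for g in (a, b)], dtype=float
        )
        p = float(stats.chi2_contingency(tab, correction=False)[1])
        rows.append(dict(variable=var, test="chi2", p=p, flag=""))
    return pd.DataFrame(rows)
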