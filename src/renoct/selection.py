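"""Two-stage feature filtering: ICC repeatability, then Spearman redundancy.

Stage 1 keeps features whose intraclass correlation between the
manual-segmentation and automatic-segmentation extractions is at least the
threshold (two-way random effects, absolute agreement, single measurement,
i.e. ICC(2,1)).  Stage 2 flags feature pairs with |Spearman rho| above the
threshold and, within each flagged pair, removes the member with the larger
mean |rho| against all other features.  Both stages are deterministic and
order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SelectionReport",
    "ICCRepeatabilityFilter",
    "SpearmanRedundancyFilter",
    "apply_redundancy_rule",
    "icc_2way_absolute",
    "icc_repeatability",
    "spearman_redundancy_filter",
]


@dataclass
class SelectionReport:
    """Audit trail of a selection stage."""

    stage: str
    threshold: float
    retained: list[str]
    removed: list[str]
    icc: dict[str, float] = field(default_factory=dict)
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    removal_log: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def apply_redundancy_rule(
    scc: pd.DataFrame, threshold: float
) -> tuple[list[str], list[dict], list[tuple[float, str, str]]]:
    """Apply the pairwise-redundancy removal rule to an |SCC| matrix.

    Pairs with |SCC| strictly above ``threshold`` are processed in
    descending |SCC| (ties broken by name); within each pair whose members
    are both still retained, the member with the larger mean |SCC| against
    all other original features is removed (name ties drop the
    lexicographically later feature).  Returns (retained, removal log,
    flagged pairs).
    """
    cols = list(scc.columns)
    rho = scc.to_numpy(float).copy()
    np.fill_diagonal(rho, 0.0)
    mean_scc = rho.sum(axis=1) / (len(cols) - 1)
    pairs = [
        (rho[i, j], cols[i], cols[j])
        for i in range(len(cols))
        for j in range(i + 1, len(cols))
        if rho[i, j] > threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    retained = set(cols)
    removal_log: list[dict] = []
    for val, a, b in pairs:
        if a not in retained or b not in retained:
            continue
        ma, mb = mean_scc[cols.index(a)], mean_scc[cols.index(b)]
        if ma > mb:
            drop = a
        elif mb > ma:
            drop = b
        else:
            drop = max(a, b)
        retained.discard(drop)
        removal_log.append(
            dict(feature=drop, mean_abs_scc=float(max(ma, mb)), pair=(a, b), pair_scc=float(val))
        )
    return [c for c in cols if c in retained], removal_log, pairs


def icc_2way_absolute(manual: np.ndarray, auto: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    Closed form from the two-way ANOVA mean squares with k = 2 raters:
    (MSR - MSE) / (MSR + MSE + 2/n (MSC - MSE)).
    """
    x = np.column_stack([np.asarray(manual, float), np.asarray(auto, float)])
    n, k = x.shape
    if n < 2:
        raise ValueError("ICC needs at least two subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom == 0:
        # both columns constant: agreement is exact or impossible
        return 1.0 if np.allclose(x[:, 0], x[:, 1]) else 0.0
    return float((msr - mse) / denom)


class ICCRepeatabilityFilter(BaseEstimator, TransformerMixin):
    """Drop features whose manual-vs-auto ICC falls below ``threshold``.

    The comparison is strict: ICC < threshold excluded, ICC == threshold
    retained.  Zero-variance features get ICC 1 if the two extractions are
    identical, else 0, and the case is logged.
    """

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, manual: pd.DataFrame, auto: pd.DataFrame) -> "ICCRepeatabilityFilter":
        if list(manual.columns) != list(auto.columns):
            raise ValueError("manual and auto tables must share columns")
        if manual.shape[0] != auto.shape[0]:
            raise ValueError("manual and auto tables must share kidneys (rows)")
        icc: dict[str, float] = {}
        notes: list[str] = []
        for col in manual.columns:
            m = manual[col].to_numpy(float)
            a = auto[col].to_numpy(float)
            if np.var(m) == 0 and np.var(a) == 0:
                val = 1.0 if np.allclose(m, a) else 0.0
                notes.append(f"zero-variance feature {col}: ICC set to {val}")
            else:
                val = icc_2way_absolute(m, a)
                if not np.isfinite(val):  # pragma: no cover - degenerate guard
                    val = 0.0
                    notes.append(f"non-finite ICC for {col}: set to 0")
            icc[col] = val
        retained = [c for c in manual.columns if icc[c] >= self.threshold]
        removed = [c for c in manual.columns if c not in set(retained)]
        self.icc_ = icc
        self.retained_ = retained
        self.report_ = SelectionReport(
            stage="icc",
            threshold=self.threshold,
            retained=retained,
            removed=removed,
            icc=icc,
            notes=notes,
        )
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table[self.retained_]


class SpearmanRedundancyFilter(BaseEstimator, TransformerMixin):
    """Remove the more globally correlated member of each |rho| > threshold pair.

    Pairs are processed in descending |rho| (ties broken by name); for a
    pair whose members are both still retained, each member's mean |rho|
    against all *other original* features decides the removal (larger mean
    goes; name ties drop the lexicographically later feature).
    """

    def __init__(self, threshold: float = 0.9):
        self.threshold = threshold

    def fit(self, table: pd.DataFrame, y=None) -> "SpearmanRedundancyFilter":
        cols = list(table.columns)
        if len(cols) < 2 or table.shape[0] < 3:
            raise ValueError("redundancy filter needs >= 2 features and >= 3 rows")
        notes: list[str] = []
        x = table.to_numpy(float)
        constant = [c for c, v in zip(cols, x.var(axis=0)) if v == 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = stats.spearmanr(x).statistic
        rho = np.atleast_2d(np.asarray(rho, float))
        if rho.shape != (len(cols), len(cols)):  # pragma: no cover - scipy contract
            raise RuntimeError("unexpected spearmanr output shape")
        rho = np.abs(rho)
        np.fill_diagonal(rho, 0.0)
        for c in constant:
            i = cols.index(c)
            rho[i, :] = 0.0
            rho[:, i] = 0.0
            notes.append(f"constant feature {c}: SCCs defined as 0")
        rho = np.nan_to_num(rho, nan=0.0)

        scc = pd.DataFrame(rho, index=cols, columns=cols)
        retained_list, removal_log, pairs = apply_redundancy_rule(scc, self.threshold)
        retained = set(retained_list)

        self.scc_ = scc
        self.mean_scc_ = dict(zip(cols, rho.sum(axis=1) / (len(cols) - 1)))
        self.retained_ = retained_list
        self.report_ = SelectionReport(
            stage="spearman",
            threshold=self.threshold,
            retained=self.retained_,
            removed=[c for c in cols if c not in retained],
            flagged_pairs=[(a, b, float(v)) for v, a, b in pairs],
            removal_log=removal_log,
            notes=notes,
        )
        # contract: no surviving pair may exceed the threshold
        sub = self.scc_.loc[self.retained_, self.retained_].to_numpy()
        assert not (sub > self.threshold).any(), "redundant pair survived selection"
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table[self.retained_]


def icc_repeatability(
    manual: pd.DataFrame, auto: pd.DataFrame, threshold: float = 0.9
) -> SelectionReport:
    """Functional wrapper around :class:`ICCRepeatabilityFilter`."""
    return ICCRepeatabilityFilter(threshold).fit(manual, auto).report_


def spearman_redundancy_filter(table: pd.DataFrame, threshold: float = 0.9) -> SelectionReport:
    """Functional wrapper around :class:`SpearmanRedundancyFilter`."""
    return SpearmanRedundancyFilter(threshold).fit(table).report_
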