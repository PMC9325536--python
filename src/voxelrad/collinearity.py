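"""Unsupervised multicollinearity reduction of a cohort feature table.

Two stages, both label-blind:

1. Pairwise Pearson pruning: starting from an absolute-correlation
   threshold of 1, as long as the Pearson correlation matrix of the
   surviving features is singular (|det| below tolerance) the threshold is
   decreased in steps of 0.001; within each round, every pair whose |R|
   exceeds the threshold is resolved (in decreasing |R| order, correlations
   re-evaluated after each removal) by dropping the member with the highest
   mean absolute correlation with all other features.
2. VIF pruning: the feature with the highest variance inflation factor
   VIF = 1 / (1 - R^2) — R^2 from the least-squares regression of that
   feature on all others, with intercept — is dropped iteratively until the
   maximum VIF falls below the threshold (default 10).

Ties (equal mean |R| or equal VIF) are broken by removing the feature later
in column order, so traces are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DET_TOL = 1e-12


def _corr_det(df: pd.DataFrame) -> float:
    """|det| of the Pearson correlation matrix; non-finite counts as
    singular."""
    with np.errstate(all="ignore"):
        d = np.linalg.det(df.corr().to_numpy())
    return abs(d) if np.isfinite(d) else 0.0


@dataclass
class CohortFeatureTable:
    """Patients x features matrix of aggregated ROI features with labels."""

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")
        if self.labels is not None:
            self.labels = self.labels.loc[self.values.index]
            counts = self.labels.value_counts()
            if (counts < 2).any():
                raise ValueError("need >= 2 patients per class")

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    def subset(self, features) -> "CohortFeatureTable":
        return CohortFeatureTable(self.values[list(features)], self.labels)


@dataclass
class PruneTrace:
    """Replayable record of the pruning decisions."""

    final_threshold: float = 1.0
    removed: list = field(default_factory=list)  # (feature, reason, statistic)

    def removed_names(self) -> list:
        return [name for name, _, _ in self.removed]


def _mean_abs_corr(corr: pd.DataFrame, feature: str) -> float:
    col = corr[feature].drop(index=feature).abs()
    return float(col.mean()) if len(col) else 0.0


def pairwise_prune(table: CohortFeatureTable,
                   det_tol: float = DET_TOL) -> tuple[CohortFeatureTable, PruneTrace]:
    """Remove features until the Pearson correlation matrix is nonsingular."""
    df = table.values.copy()
    trace = PruneTrace()
    variances = df.var(ddof=0)
    for name in df.columns[variances == 0]:
        trace.removed.append((name, "PAIRWISE", float("nan")))
    df = df.loc[:, variances > 0]
    if df.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant features")

    threshold = 1.0
    while True:
        if _corr_det(df) >= det_tol:
            break
        # resolve every pair above the current threshold, strongest first,
        # re-evaluating correlations after each removal
        while True:
            corr = df.corr()
            a = corr.abs().to_numpy()
            np.fill_diagonal(a, 0.0)
            if a.max() <= threshold:
                break
            r, c = np.unravel_index(np.argmax(a), a.shape)
            f1, f2 = corr.columns[r], corr.columns[c]
            m1, m2 = _mean_abs_corr(corr, f1), _mean_abs_corr(corr, f2)
            if m1 > m2:
                drop = f1
            elif m2 > m1:
                drop = f2
            else:  # tie: later column order
                drop = f2 if list(df.columns).index(f2) > list(df.columns).index(f1) else f1
            trace.removed.append((drop, "PAIRWISE", float(a[r, c])))
            df = df.drop(columns=drop)
            if df.shape[1] < 2:
                raise ValueError("pairwise pruning left fewer than 2 features")
        if _corr_det(df) >= det_tol:
            break
        threshold = round(threshold - 0.001, 10)
        if threshold <= 0:
            raise RuntimeError("threshold exhausted without reaching a "
                               "nonsingular correlation matrix")
    trace.final_threshold = threshold
    return CohortFeatureTable(df, table.labels), trace


def vif(table: CohortFeatureTable, feature: str) -> float:
    """Variance inflation factor of one feature against all the others."""
    df = table.values
    if df.shape[1] < 2:
        raise ValueError("VIF needs at least 2 features")
    if df.shape[0] <= df.shape[1]:
        raise ValueError("VIF undefined: need more patients than features")
    y = df[feature].to_numpy(dtype=np.float64)
    x = df.drop(columns=feature).to_numpy(dtype=np.float64)
    design = np.column_stack([np.ones(len(y)), x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError(f"feature {feature!r} has zero variance")
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return float(1.0 / (1.0 - r2))


def vif_prune(table: CohortFeatureTable, threshold: float = 10.0
              ) -> tuple[CohortFeatureTable, PruneTrace]:
    """Drop the highest-VIF feature until max VIF < threshold."""
    df = table.values.copy()
    trace = PruneTrace(final_threshold=threshold)
    while df.shape[1] >= 2:
        current = CohortFeatureTable(df, table.labels)
        vifs = np.array([vif(current, f) for f in df.columns])
        worst = float(np.nanmax(vifs))
        if worst < threshold:
            break
        # highest VIF; ties broken toward the later column
        candidates = np.flatnonzero(vifs == worst)
        drop = df.columns[candidates[-1]]
        trace.removed.append((drop, "VIF", worst))
        df = df.drop(columns=drop)
    return CohortFeatureTable(df, table.labels), trace


class CollinearityReducer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer chaining pairwise-Pearson and VIF pruning.

    Attributes (after fit)
    ----------------------
    selected_features_ : list of surviving column names
    pairwise_trace_, vif_trace_ : PruneTrace
    """

    def __init__(self, vif_threshold: float = 10.0, det_tol: float = DET_TOL):
        self.vif_threshold = vif_threshold
        self.det_tol = det_tol

    def fit(self, X: pd.DataFrame, y=None):
        table = CohortFeatureTable(pd.DataFrame(X))
        reduced, self.pairwise_trace_ = pairwise_prune(table, self.det_tol)
        reduced, self.vif_trace_ = vif_prune(reduced, self.vif_threshold)
        self.selected_features_ = reduced.feature_names
        self.n_features_in_ = table.values.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]
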