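"""Supervised risk modelling with LASSO logistic regression.

The scoring metric is the average stratified Brier score (ASB),

    SB_C1 = mean_{i: y=1} (y_i - P_i)^2,   SB_C0 = mean_{i: y=0} (y_i - P_i)^2,
    ASB   = 1 - (SB_C0 + SB_C1) / 2,

a calibration-aware accuracy giving equal weight to both classes: a perfect
model scores 1, an always-wrong model 0, a constant-0.5 model 0.75 and a
majority-class dummy 0.5.

The pipeline mirrors a small-cohort radiomics protocol: features surviving
multicollinearity reduction are grown greedily (forward selection) under
repeated stratified cross-validation of the ASB; the L1 regularization
strength C and the subset size are chosen on a grid; significance is
assessed with a label-permutation test of the whole pipeline; the retained
configuration is refit on 1000 stratified bootstrap resamples whose
coefficients are averaged (bagging) and whose out-of-bag samples provide
ROC AUC estimates comparable with conventional biomarkers.

All feature scaling inside CV folds and bootstrap resamples uses statistics
of the training portion only (population-SD z-scores).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ASBResult", "asb", "CVConfig", "LogisticModelSpec", "fit_lasso_logistic",
    "forward_select", "grid_search", "GridSearchResult", "permutation_test",
    "PermutationResult", "BaggedModel", "bag", "biomarker_oob_auc",
    "conventional_biomarkers", "RadiomicRiskClassifier", "DEFAULT_C_GRID",
]

#: 10 values for C from 0.1 to 100 on a log10 scale.
DEFAULT_C_GRID = tuple(np.logspace(-1, 2, 10))


# ----------------------------------------------------------------------
# ASB metric
# ----------------------------------------------------------------------

@dataclass
class ASBResult:
    sb_c1: float
    sb_c0: float
    asb: float


def asb(y, p) -> ASBResult:
    """Average stratified Brier score of predicted probabilities."""
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if y.shape != p.shape:
        raise ValueError("y and p must have the same shape")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    c1 = y == 1
    c0 = y == 0
    if not (c1.any() and c0.any()):
        raise ValueError("both classes must be present")
    sb1 = float(np.mean((y[c1] - p[c1]) ** 2))
    sb0 = float(np.mean((y[c0] - p[c0]) ** 2))
    return ASBResult(sb1, sb0, 1.0 - (sb0 + sb1) / 2.0)


# ----------------------------------------------------------------------
# model spec and single fits
# ----------------------------------------------------------------------

@dataclass
class LogisticModelSpec:
    """A fitted logistic decision function in standardized feature space.

    ``beta`` are coefficients of voxel-mappable features, ``beta_prime``
    of features with no voxel counterpart (shape/volume). ``scaling`` maps
    every named feature to the (mean, population SD) its coefficients
    assume.
    """

    beta0: float
    beta: dict
    beta_prime: dict
    C: float
    scaling: dict
    loss: str = "balanced_cross_entropy"

    def __post_init__(self):
        for name in list(self.beta) + list(self.beta_prime):
            if name not in self.scaling:
                raise ValueError(f"no scaling entry for feature {name!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")

    @property
    def feature_names(self) -> list:
        return list(self.beta) + list(self.beta_prime)

    def _z(self, df: pd.DataFrame, names) -> np.ndarray:
        cols = []
        for n in names:
            mu, sd = self.scaling[n]
            cols.append((df[n].to_numpy(dtype=np.float64) - mu) / sd)
        return np.column_stack(cols) if cols else np.zeros((len(df), 0))

    def decision(self, df: pd.DataFrame) -> np.ndarray:
        """D(G) = beta^T z + beta'^T z' + beta0 for each row."""
        d = np.full(len(df), self.beta0, dtype=np.float64)
        if self.beta:
            d += self._z(df, list(self.beta)) @ np.array(list(self.beta.values()))
        if self.beta_prime:
            d += self._z(df, list(self.beta_prime)) @ np.array(
                list(self.beta_prime.values()))
        return d

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(df)))

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, s: str) -> "LogisticModelSpec":
        d = json.loads(s)
        d["scaling"] = {k: tuple(v) for k, v in d["scaling"].items()}
        return cls(**d)


def _is_nonmappable(name: str) -> bool:
    return "shape_" in name


def _make_estimator(C: float, seed: int | None = 0) -> LogisticRegression:
    # deterministic coordinate-descent solver, L1 penalty, class-balanced loss
    import sklearn
    major, minor = (int(v) for v in sklearn.__version__.split(".")[:2])
    if (major, minor) >= (1, 8):  # penalty="l1" deprecated for l1_ratio=1
        return LogisticRegression(C=C, solver="liblinear", l1_ratio=1.0,
                                  class_weight="balanced", tol=1e-4,
                                  max_iter=100, random_state=seed)
    return LogisticRegression(penalty="l1", C=C, solver="liblinear",
                              class_weight="balanced", tol=1e-4,
                              max_iter=100, random_state=seed)


try:  # fast path for the inner CV/bootstrap loops: call the liblinear
    # binding directly (same solver/objective, none of the per-call
    # estimator overhead); falls back to the public estimator on any
    # version mismatch
    from sklearn.svm import _liblinear as _liblinear_binding
    from sklearn.svm._base import _get_liblinear_solver_type

    _L1R_LR = _get_liblinear_solver_type("ovr", "l1", "logistic_regression",
                                         False)
    _liblinear_binding.set_verbosity_wrap(0)
except Exception:  # pragma: no cover
    _liblinear_binding = None


def _liblinear_fit(z: np.ndarray, y: np.ndarray, C: float, seed: int = 0):
    """L1 balanced logistic fit (labels must be {0, 1});
    returns (coef, intercept)."""
    if _liblinear_binding is not None:
        try:
            zc = np.require(z, dtype=np.float64, requirements=["C"])
            yf = np.require(np.asarray(y, dtype=np.float64),
                            requirements="W")
            n1 = int(np.sum(y == 1))
            n0 = y.size - n1
            cw = np.array([y.size / (2.0 * n0), y.size / (2.0 * n1)])
            raw, _ = _liblinear_binding.train_wrap(
                zc, yf, False, _L1R_LR, 1e-4, 1.0, float(C), cw, 100,
                int(seed), 0.1, np.ones(y.size))
            return raw[0, :-1].copy(), float(raw[0, -1])
        except Exception:  # pragma: no cover - binding signature changed
            pass
    est = _make_estimator(C, seed)
    est.fit(z, y)
    return est.coef_.ravel(), float(est.intercept_[0])


def _zscore_train(x: np.ndarray):
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population SD
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd, mu, sd


def fit_lasso_logistic(df: pd.DataFrame, y, features, C: float,
                       seed: int = 0, nonmappable=None) -> LogisticModelSpec:
    """Fit one L1 logistic model on z-scored features (full-data scaling)."""
    features = list(features)
    x = df[features].to_numpy(dtype=np.float64)
    y = np.asarray(y, dtype=int)
    z, mu, sd = _zscore_train(x)
    est = _make_estimator(C, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        est.fit(z, y)
    if getattr(est, "n_iter_", np.array([0])).max() >= 100:
        warnings.warn("liblinear reached max_iter=100 without convergence; "
                      "coefficients returned as-is")
    coefs = est.coef_.ravel()
    if nonmappable is None:
        nonmappable = {f for f in features if _is_nonmappable(f)}
    beta = {f: float(c) for f, c in zip(features, coefs) if f not in nonmappable}
    beta_prime = {f: float(c) for f, c in zip(features, coefs)
                  if f in nonmappable}
    scaling = {f: (float(m), float(s)) for f, m, s in zip(features, mu, sd)}
    return LogisticModelSpec(float(est.intercept_[0]), beta, beta_prime, C,
                             scaling)


# ----------------------------------------------------------------------
# cross-validated selection
# ----------------------------------------------------------------------

@dataclass
class CVConfig:
    n_repeats: int = 200
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("need >= 2 folds")


def _cv_fold_plan(y: np.ndarray, cv: CVConfig) -> list:
    """Precompute (train, test) index pairs for every repeat x fold.

    The same plan is shared across candidate subsets and C values so
    configuration comparisons are paired.
    """
    plan = []
    for rep in range(cv.n_repeats):
        skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True,
                              random_state=cv.seed + rep)
        plan.append(list(skf.split(np.zeros(len(y)), y)))
    return plan


def _cv_asb(x: np.ndarray, y: np.ndarray, C: float, plan, seed: int = 0):
    """Mean/SD over repeats of the pooled out-of-fold ASB."""
    scores = np.empty(len(plan))
    for r, folds in enumerate(plan):
        pred = np.empty(len(y))
        for train, test in folds:
            zt, mu, sd = _zscore_train(x[train])
            coef, intercept = _liblinear_fit(zt, y[train], C, seed)
            zs = (x[test] - mu) / sd
            d = zs @ coef + intercept
            pred[test] = 1.0 / (1.0 + np.exp(-d))
        scores[r] = asb(y, pred).asb
    return float(scores.mean()), float(scores.std())


@dataclass
class SelectionStep:
    subset: tuple
    mean_asb: float
    sd_asb: float


def forward_select(df: pd.DataFrame, y, candidates, C: float, cv: CVConfig,
                   max_k: int | None = None, _plan=None) -> list:
    """Greedy forward selection maximizing cross-validated mean ASB.

    Returns the selection path: one SelectionStep per subset size, up to
    ``max_k`` features. Scaling is refit inside every training fold.
    """
    y = np.asarray(y, dtype=int)
    candidates = list(candidates)
    if max_k is None:
        max_k = len(candidates)
    plan = _cv_fold_plan(y, cv) if _plan is None else _plan
    selected: list = []
    path: list = []
    xcols = {f: df[f].to_numpy(dtype=np.float64) for f in candidates}
    while len(selected) < max_k and len(selected) < len(candidates):
        best = None
        for f in candidates:
            if f in selected:
                continue
            x = np.column_stack([xcols[g] for g in selected + [f]])
            mean, sd = _cv_asb(x, y, C, plan)
            if best is None or mean > best[1]:
                best = (f, mean, sd)
        selected.append(best[0])
        path.append(SelectionStep(tuple(selected), best[1], best[2]))
    return path


@dataclass
class GridSearchResult:
    results: dict                 # (C, k) -> SelectionStep
    best_mean_asb: float          # global maximum of the grid
    selected_C: float
    selected_subset: tuple
    selected_mean_asb: float
    selected_sd_asb: float


def grid_search(df: pd.DataFrame, y, candidates, cv: CVConfig,
                grid_C=None, max_k: int | None = None) -> GridSearchResult:
    """Joint grid over the regularization C and the subset size k.

    The retained configuration is picked by a one-SD parsimony rule: among
    all (C, k) whose mean ASB is within one SD (of the global best
    configuration) of the global best mean, take the smallest k, then the
    smallest C. This automates the manual "parsimonious and regularized"
    tradeoff reproducibly; callers may override by inspecting ``results``.
    """
    grid_C = list(DEFAULT_C_GRID) if grid_C is None else list(grid_C)
    if not grid_C:
        raise ValueError("empty C grid")
    y = np.asarray(y, dtype=int)
    plan = _cv_fold_plan(y, cv)
    results = {}
    for C in grid_C:
        path = forward_select(df, y, candidates, C, cv, max_k, _plan=plan)
        for step in path:
            results[(C, len(step.subset))] = step
    best_key = max(results, key=lambda k: results[k].mean_asb)
    best = results[best_key]
    floor = best.mean_asb - best.sd_asb
    eligible = [k for k, v in results.items() if v.mean_asb >= floor]
    sel_C, sel_k = min(eligible, key=lambda k: (k[1], k[0]))
    sel = results[(sel_C, sel_k)]
    return GridSearchResult(results, best.mean_asb, sel_C, sel.subset,
                            sel.mean_asb, sel.sd_asb)


# ----------------------------------------------------------------------
# permutation test
# ----------------------------------------------------------------------

@dataclass
class PermutationResult:
    null_scores: np.ndarray
    observed: float
    p_value: float


def permutation_test(df: pd.DataFrame, y, candidates, cv: CVConfig,
                     grid_C=None, n_perm: int = 200, seed: int = 0,
                     max_k: int | None = None,
                     observed: float | None = None) -> PermutationResult:
    """Label-permutation test of the whole selection + grid-search pipeline.

    Per permutation the labels are shuffled and the full grid search re-run;
    the best grid mean ASB is stored. The empirical p-value uses the
    plus-one estimator p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("need at least 1 permutation")
    y = np.asarray(y, dtype=int)
    if observed is None:
        observed = grid_search(df, y, candidates, cv, grid_C, max_k).best_mean_asb
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        null[b] = grid_search(df, yp, candidates, cv, grid_C,
                              max_k).best_mean_asb
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationResult(null, float(observed), float(p))


# ----------------------------------------------------------------------
# bagging and biomarker comparison
# ----------------------------------------------------------------------

def _stratified_boot_indices(rng: np.random.Generator, y: np.ndarray
                             ) -> np.ndarray:
    """Class-stratified resample with replacement (original class counts)."""
    idx = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


@dataclass
class BaggedModel:
    mean_spec: LogisticModelSpec
    coef_sd: dict
    n_boot: int
    oob_auc_samples: np.ndarray = field(repr=False, default=None)
    oob_auc_mean: float = float("nan")
    oob_auc_sd: float = float("nan")
    oob_auc_ci95: tuple = (float("nan"), float("nan"))

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        return self.mean_spec.predict_proba(df)


def bag(df: pd.DataFrame, y, features, C: float, n_boot: int = 1000,
        seed: int = 0, resample: bool = True) -> BaggedModel:
    """Bootstrap-aggregate the logistic fit over stratified resamples.

    Each bootstrap refits the z-scoring on the resample, fits the model,
    and evaluates ROC AUC on the out-of-bag patients. The final decision
    function averages the standardized-space coefficients over all fits;
    full-cohort scaling statistics are attached for deployment.
    """
    features = list(features)
    y = np.asarray(y, dtype=int)
    x = df[features].to_numpy(dtype=np.float64)
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_boot, len(features)))
    intercepts = np.empty(n_boot)
    aucs = []
    for b in range(n_boot):
        idx = _stratified_boot_indices(rng, y) if resample \
            else np.arange(len(y))
        zt, mu, sd = _zscore_train(x[idx])
        coefs[b], intercepts[b] = _liblinear_fit(zt, y[idx], C, seed)
        oob = np.setdiff1d(np.arange(len(y)), idx)
        if oob.size and np.unique(y[oob]).size == 2:
            zo = (x[oob] - mu) / sd
            d = zo @ coefs[b] + intercepts[b]
            aucs.append(roc_auc_score(y[oob], d))
    aucs = np.asarray(aucs, dtype=np.float64)

    z_full, mu_full, sd_full = _zscore_train(x)
    scaling = {f: (float(m), float(s))
               for f, m, s in zip(features, mu_full, sd_full)}
    mean_coef = coefs.mean(axis=0)
    beta = {f: float(c) for f, c in zip(features, mean_coef)
            if not _is_nonmappable(f)}
    beta_prime = {f: float(c) for f, c in zip(features, mean_coef)
                  if _is_nonmappable(f)}
    spec = LogisticModelSpec(float(intercepts.mean()), beta, beta_prime,
                             C, scaling)
    coef_sd = {f: float(s) for f, s in zip(features, coefs.std(axis=0))}
    model = BaggedModel(spec, coef_sd, n_boot, aucs)
    if aucs.size:
        model.oob_auc_mean = float(aucs.mean())
        model.oob_auc_sd = float(aucs.std())
        model.oob_auc_ci95 = tuple(np.percentile(aucs, [2.5, 97.5]))
    return model


def biomarker_oob_auc(values, y, n_boot: int = 1000, seed: int = 0
                      ) -> np.ndarray:
    """OOB ROC AUC distribution of one raw biomarker, using the same
    stratified resample stream as :func:`bag` at the same seed so model and
    biomarker comparisons are paired."""
    y = np.asarray(y, dtype=int)
    v = np.asarray(values, dtype=np.float64)
    if np.all(v == v[0]):
        warnings.warn("constant biomarker; OOB AUC fixed at 0.5")
    rng = np.random.default_rng(seed)
    aucs = []
    for b in range(n_boot):
        idx = _stratified_boot_indices(rng, y)
        oob = np.setdiff1d(np.arange(len(y)), idx)
        if oob.size and np.unique(y[oob]).size == 2:
            if np.all(v[oob] == v[oob][0]):
                aucs.append(0.5)
            else:
                aucs.append(roc_auc_score(y[oob], v[oob]))
    return np.asarray(aucs)


class RadiomicRiskClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style front end to the whole supervised pipeline.

    ``fit`` runs forward selection under repeated stratified CV of the ASB
    across the C grid, picks a configuration by the one-SD parsimony rule,
    and bags the retained model over stratified bootstrap resamples.
    Composes with :class:`voxelrad.collinearity.CollinearityReducer` in a
    sklearn ``Pipeline``.

    Attributes (after fit)
    ----------------------
    selected_features_ : tuple of retained feature names
    C_ : retained inverse regularization strength
    model_ : BaggedModel (coefficient means/SDs, OOB AUC distribution)
    cv_result_ : GridSearchResult
    """

    def __init__(self, grid_C=None, n_repeats: int = 200, n_folds: int = 5,
                 max_k: int | None = None, n_boot: int = 1000,
                 random_state: int = 0):
        self.grid_C = grid_C
        self.n_repeats = n_repeats
        self.n_folds = n_folds
        self.max_k = max_k
        self.n_boot = n_boot
        self.random_state = random_state

    def _frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=np.float64)
        cols = getattr(self, "feature_names_in_",
                       [f"f{i}" for i in range(X.shape[1])])
        return pd.DataFrame(X, columns=list(cols))

    def fit(self, X, y):
        df = self._frame(X)
        self.feature_names_in_ = np.asarray(df.columns)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        cv = CVConfig(self.n_repeats, self.n_folds, seed=self.random_state)
        self.cv_result_ = grid_search(df, y, df.columns, cv, self.grid_C,
                                      self.max_k)
        self.selected_features_ = self.cv_result_.selected_subset
        self.C_ = self.cv_result_.selected_C
        self.model_ = bag(df, y, list(self.selected_features_), self.C_,
                          n_boot=self.n_boot, seed=self.random_state)
        return self

    def predict_proba(self, X):
        p1 = self.model_.predict_proba(self._frame(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X):
        return self.model_.mean_spec.decision(self._frame(X))


def conventional_biomarkers(pet, roi, mtv_fraction: float = 0.4) -> dict:
    """ATV (ml), SUVmax, MTV (ml, SUV >= mtv_fraction * SUVmax) and
    TLG (MTV x its mean SUV) from a PET volume and ROI."""
    from .image import as_bool_mask
    mask = as_bool_mask(roi)
    suv = np.asarray(pet.values, dtype=np.float64)
    if mask.shape != suv.shape:
        raise ValueError("PET and ROI must share a grid")
    vox_ml = pet.voxel_volume_mm3 / 1000.0
    in_roi = suv[mask]
    suvmax = float(in_roi.max())
    hot = in_roi >= mtv_fraction * suvmax
    mtv = float(hot.sum() * vox_ml)
    tlg = float(mtv * in_roi[hot].mean()) if hot.any() else 0.0
    return {"ATV": float(mask.sum() * vox_ml), "SUVmax": suvmax,
            "MTV": mtv, "TLG": tlg}
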