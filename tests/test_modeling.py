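import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from voxelrad.modeling import (ASBResult, BaggedModel, CVConfig,
                               DEFAULT_C_GRID, LogisticModelSpec, asb, bag,
                               biomarker_oob_auc, conventional_biomarkers,
                               fit_lasso_logistic, forward_select,
                               grid_search, permutation_test,
                               _cv_fold_plan, _cv_asb,
                               _stratified_boot_indices, _zscore_train)


@pytest.fixture()
def labels_19_32():
    return np.r_[np.ones(19), np.zeros(32)]


class TestASB:
    def test_closed_form_anchors(self, labels_19_32):
        y = labels_19_32
        assert asb(y, np.full(51, 0.5)).asb == pytest.approx(0.75)
        assert asb(y, y).asb == pytest.approx(1.0)
        assert asb(y, 1 - y).asb == pytest.approx(0.0)
        assert asb(y, np.zeros(51)).asb == pytest.approx(0.5)  # majority: 0

    def test_components_and_bounds(self, labels_19_32):
        rng = np.random.default_rng(0)
        p = rng.random(51)
        res = asb(labels_19_32, p)
        assert 0 <= res.sb_c0 <= 1 and 0 <= res.sb_c1 <= 1
        assert res.asb == pytest.approx(1 - (res.sb_c0 + res.sb_c1) / 2)

    def test_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            asb(np.ones(5), np.full(5, 0.5))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            asb(np.array([0, 1]), np.array([0.5, 1.2]))


def scipy_l1_balanced_logistic(x, y, C):
    """Independent penalized-likelihood optimizer: minimizes
    sum_j |w_j| + C * sum_i cw_i log(1+exp(-t_i (x_i . w + b))) with the
    intercept penalized exactly as the coordinate-descent solver does,
    via a nonnegative split and L-BFGS-B."""
    n, p = x.shape
    xt = np.column_stack([x, np.ones(n)])
    t = 2.0 * y - 1.0
    n1 = y.sum()
    cw = np.where(y == 1, n / (2.0 * n1), n / (2.0 * (n - n1)))

    def obj(u):
        w = u[: p + 1] - u[p + 1:]
        z = t * (xt @ w)
        loss = np.logaddexp(0.0, -z)
        return u.sum() + C * np.sum(cw * loss)

    def grad(u):
        w = u[: p + 1] - u[p + 1:]
        z = t * (xt @ w)
        s = -t / (1.0 + np.exp(z))
        g = C * (xt.T @ (cw * s))
        return np.concatenate([1.0 + g, 1.0 - g])

    res = minimize(obj, np.zeros(2 * (p + 1)), jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * (p + 1)),
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    w = res.x[: p + 1] - res.x[p + 1:]
    return w[:p], w[p]


class TestLassoLogistic:
    def test_separable_feature_sign_and_fit_quality(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        df = pd.DataFrame({"good": y * 2.0 + rng.normal(0, 0.05, 20)})
        spec = fit_lasso_logistic(df, y, ["good"], C=10.0)
        assert spec.beta["good"] > 0
        assert asb(y, spec.predict_proba(df)).asb > 0.9

    def test_heavy_regularization_zeroes_coefficients(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        df = pd.DataFrame({"a": y + rng.normal(0, 1, 20),
                           "b": rng.normal(size=20)})
        spec = fit_lasso_logistic(df, y, ["a", "b"], C=1e-6)
        assert spec.beta["a"] == 0.0 and spec.beta["b"] == 0.0

    @pytest.mark.parametrize("C", [0.5, 2.0])
    def test_matches_independent_penalized_optimizer(self, C):
        """Cross-solver check on a 20-patient synthetic table."""
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(8, int), np.zeros(12, int)]
        x = rng.normal(size=(20, 3))
        x[:, 0] += 1.2 * y
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        spec = fit_lasso_logistic(df, y, ["a", "b", "c"], C=C)
        z, _, _ = _zscore_train(x)
        coef_ref, b_ref = scipy_l1_balanced_logistic(z, y, C)
        got = np.array([spec.beta[f] for f in ("a", "b", "c")])
        np.testing.assert_allclose(got, coef_ref, atol=1e-4)
        assert spec.beta0 == pytest.approx(b_ref, abs=1e-4)

    def test_shape_features_split_as_nonmappable(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(8, int), np.zeros(8, int)]
        df = pd.DataFrame({"PET_firstorder_Mean": y + rng.normal(0, 1, 16),
                           "shape_Elongation": rng.normal(size=16)})
        spec = fit_lasso_logistic(df, y, df.columns, C=1.0)
        assert "PET_firstorder_Mean" in spec.beta
        assert "shape_Elongation" in spec.beta_prime

    def test_spec_json_round_trip(self):
        spec = LogisticModelSpec(0.5, {"a": 1.0}, {"shape_x": -0.2}, 2.0,
                                 {"a": (0.0, 1.0), "shape_x": (1.0, 2.0)})
        back = LogisticModelSpec.from_json(spec.to_json())
        df = pd.DataFrame({"a": [0.3], "shape_x": [1.5]})
        assert back.predict_proba(df)[0] == pytest.approx(
            spec.predict_proba(df)[0])


class TestForwardSelection:
    def test_informative_feature_found_first(self):
        """One strong + nine noise candidates: the informative one leads
        the path in nearly every seeded replicate."""
        hits = 0
        cv = CVConfig(n_repeats=5, n_folds=5, seed=0)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.r_[np.ones(15, int), np.zeros(15, int)]
            x = rng.normal(size=(30, 10))
            x[:, 0] += 2.5 * y
            df = pd.DataFrame(x, columns=[f"f{i}" for i in range(10)])
            path = forward_select(df, y, df.columns, C=1.0, cv=cv, max_k=1)
            hits += path[0].subset == ("f0",)
        assert hits >= 9

    def test_max_k_bounds_path_length(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        df = pd.DataFrame(rng.normal(size=(20, 4)),
                          columns=list("abcd"))
        cv = CVConfig(n_repeats=2, n_folds=5, seed=0)
        assert len(forward_select(df, y, df.columns, 1.0, cv, max_k=1)) == 1
        assert len(forward_select(df, y, df.columns, 1.0, cv, max_k=3)) == 3

    def test_pure_noise_scores_near_baseline(self):
        """All-noise candidates: best single-feature CV ASB stays near the
        uninformative 0.75 anchor."""
        rng = np.random.default_rng(5)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        df = pd.DataFrame(rng.normal(size=(40, 5)),
                          columns=[f"n{i}" for i in range(5)])
        cv = CVConfig(n_repeats=10, n_folds=5, seed=0)
        path = forward_select(df, y, df.columns, C=1.0, cv=cv, max_k=1)
        assert path[0].mean_asb == pytest.approx(0.75, abs=0.1)

    def test_scaling_leak_changes_scores(self):
        """CV hygiene: deliberately z-scoring on the full table before CV
        yields different fold scores than in-fold scaling."""
        rng = np.random.default_rng(6)
        y = np.r_[np.ones(12, int), np.zeros(12, int)]
        x = rng.lognormal(size=(24, 1)) + 0.8 * y[:, None]
        cv = CVConfig(n_repeats=3, n_folds=4, seed=0)
        plan = _cv_fold_plan(y, cv)
        clean, _ = _cv_asb(x, y, 1.0, plan)
        leaked_x, _, _ = _zscore_train(x)

        def leaked_cv():
            from voxelrad.modeling import _liblinear_fit
            scores = []
            for folds in plan:
                pred = np.empty(len(y))
                for train, test in folds:
                    coef, b = _liblinear_fit(leaked_x[train], y[train], 1.0)
                    d = leaked_x[test] @ coef + b
                    pred[test] = 1 / (1 + np.exp(-d))
                scores.append(asb(y, pred).asb)
            return float(np.mean(scores))

        assert leaked_cv() != pytest.approx(clean, abs=1e-12)


class TestGridSearch:
    def test_default_grid_spans_tenth_to_hundred(self):
        assert len(DEFAULT_C_GRID) == 10
        assert DEFAULT_C_GRID[0] == pytest.approx(0.1)
        assert DEFAULT_C_GRID[-1] == pytest.approx(100.0)

    def test_dominant_configuration_selected_and_deterministic(self):
        rng = np.random.default_rng(7)
        y = np.r_[np.ones(12, int), np.zeros(12, int)]
        x = rng.normal(size=(24, 3))
        x[:, 0] += 3.0 * y
        df = pd.DataFrame(x, columns=list("abc"))
        cv = CVConfig(n_repeats=3, n_folds=4, seed=0)
        g1 = grid_search(df, y, df.columns, cv, grid_C=[0.5, 5.0], max_k=2)
        g2 = grid_search(df, y, df.columns, cv, grid_C=[0.5, 5.0], max_k=2)
        assert "a" in g1.selected_subset
        assert g1.selected_subset == g2.selected_subset
        assert g1.selected_C == g2.selected_C
        # the parsimony rule never picks a k larger than the global best's
        best_k = max(k for (_, k) in g1.results)
        assert len(g1.selected_subset) <= best_k


class TestPermutationTest:
    def _df(self, seed=8, strong=True):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(10, int), np.zeros(14, int)]
        x = rng.normal(size=(24, 3))
        if strong:
            x[:, 0] += 3.0 * y
        return pd.DataFrame(x, columns=list("abc")), y

    def test_plus_one_formula_bounds(self):
        df, y = self._df()
        cv = CVConfig(n_repeats=2, n_folds=4, seed=0)
        res = permutation_test(df, y, df.columns, cv, grid_C=[1.0],
                               n_perm=5, seed=0, max_k=1, observed=2.0)
        assert res.p_value == pytest.approx(1 / 6)  # above every null
        res = permutation_test(df, y, df.columns, cv, grid_C=[1.0],
                               n_perm=5, seed=0, max_k=1, observed=-1.0)
        assert res.p_value == 1.0                   # below every null

    def test_separable_data_significant(self):
        df, y = self._df()
        cv = CVConfig(n_repeats=3, n_folds=4, seed=0)
        gs = grid_search(df, y, df.columns, cv, grid_C=[1.0], max_k=1)
        res = permutation_test(df, y, df.columns, cv, grid_C=[1.0],
                               n_perm=19, seed=0, max_k=1,
                               observed=gs.best_mean_asb)
        assert res.p_value <= 0.1
        assert res.null_scores.shape == (19,)

    def test_invalid_n_perm(self):
        df, y = self._df()
        with pytest.raises(ValueError):
            permutation_test(df, y, df.columns, CVConfig(1, 2, seed=0),
                             n_perm=0)


class TestBagging:
    def test_no_resampling_reduces_to_single_fit(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        df = pd.DataFrame({"a": y + rng.normal(0, 0.5, 20),
                           "b": rng.normal(size=20)})
        model = bag(df, y, ["a", "b"], C=1.0, n_boot=1, seed=0,
                    resample=False)
        single = fit_lasso_logistic(df, y, ["a", "b"], C=1.0)
        assert model.coef_sd == {"a": 0.0, "b": 0.0}
        for f in ("a", "b"):
            assert model.mean_spec.beta[f] == pytest.approx(single.beta[f],
                                                            abs=2e-3)

    def test_oob_fraction_matches_closed_form(self):
        """Stratified bootstrap leaves ~(1-1/n)^n of each class out:
        ~0.366 overall for n=51 with 19 events."""
        y = np.r_[np.ones(19, int), np.zeros(32, int)]
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(1000):
            idx = _stratified_boot_indices(rng, y)
            fracs.append(1.0 - np.unique(idx).size / 51.0)
        expect = (19 * (1 - 1 / 19) ** 19 + 32 * (1 - 1 / 32) ** 32) / 51
        assert np.mean(fracs) == pytest.approx(expect, abs=0.03)
        assert np.mean(fracs) == pytest.approx(0.366, abs=0.03)

    def test_resample_preserves_class_counts(self):
        y = np.r_[np.ones(19, int), np.zeros(32, int)]
        rng = np.random.default_rng(1)
        idx = _stratified_boot_indices(rng, y)
        assert y[idx].sum() == 19 and len(idx) == 51

    def test_coefficient_spread_positive_under_noise(self):
        rng = np.random.default_rng(10)
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        df = pd.DataFrame({"a": y + rng.normal(0, 1.0, 30)})
        model = bag(df, y, ["a"], C=1.0, n_boot=100, seed=0)
        assert model.coef_sd["a"] > 0
        assert 0.0 <= model.oob_auc_mean <= 1.0
        assert model.oob_auc_ci95[0] <= model.oob_auc_mean \
            <= model.oob_auc_ci95[1]


class TestRiskClassifierEstimator:
    def _data(self, seed=12):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(12, int), np.zeros(16, int)]
        x = rng.normal(size=(28, 4))
        x[:, 0] += 2.5 * y
        return pd.DataFrame(x, columns=list("abcd")), y

    def test_fit_predict_in_pipeline_with_reducer(self):
        from sklearn.pipeline import Pipeline
        from voxelrad.collinearity import CollinearityReducer
        from voxelrad.modeling import RadiomicRiskClassifier
        df, y = self._data()
        df["a_dup"] = df["a"].copy()
        pipe = Pipeline([
            ("reduce", CollinearityReducer()),
            ("model", RadiomicRiskClassifier(grid_C=[1.0], n_repeats=3,
                                             max_k=2, n_boot=30)),
        ])
        pipe.fit(df, y)
        clf = pipe.named_steps["model"]
        assert "a" in clf.selected_features_ or \
            "a_dup" in clf.selected_features_
        proba = pipe.predict_proba(df)
        assert proba.shape == (28, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        acc = (pipe.predict(df) == y).mean()
        assert acc > 0.8

    def test_clone_and_get_params(self):
        from sklearn.base import clone
        from voxelrad.modeling import RadiomicRiskClassifier
        clf = RadiomicRiskClassifier(n_repeats=7, max_k=3)
        cloned = clone(clf)
        assert cloned.get_params()["n_repeats"] == 7
        assert cloned.get_params()["max_k"] == 3


class TestBiomarkers:
    def test_label_itself_gives_perfect_oob_auc(self):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        aucs = biomarker_oob_auc(y.astype(float), y, n_boot=50, seed=0)
        assert np.all(aucs == 1.0)

    def test_noise_biomarker_near_chance(self):
        """Averaged over independent noise draws (a single draw keeps its
        chance in-sample AUC, SD ~ 0.08 at n=50)."""
        rng = np.random.default_rng(11)
        y = np.r_[np.ones(25, int), np.zeros(25, int)]
        means = [np.mean(biomarker_oob_auc(rng.normal(size=50), y,
                                           n_boot=60, seed=k))
                 for k in range(20)]
        assert np.mean(means) == pytest.approx(0.5, abs=0.05)

    def test_constant_biomarker_warns(self):
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        with pytest.warns(UserWarning, match="constant"):
            biomarker_oob_auc(np.ones(10), y, n_boot=5, seed=0)

    def test_conventional_biomarkers_on_phantom(self, pet_case):
        from voxelrad.image import Modality
        bm = conventional_biomarkers(pet_case.images[Modality.PET],
                                     pet_case.roi)
        roi = pet_case.roi.values.astype(bool)
        assert bm["ATV"] == pytest.approx(roi.sum() * 2.5 ** 3 / 1000.0)
        assert bm["SUVmax"] == pytest.approx(
            pet_case.images[Modality.PET].values[roi].max())
        assert 0 < bm["MTV"] <= bm["ATV"]
        assert bm["TLG"] >= bm["MTV"] * 0.4 * bm["SUVmax"] * 0.9
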