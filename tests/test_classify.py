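"""Split plans, metrics, DeLong comparisons and the two-stage evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcrep.classify import (
    ModelSpec,
    auroc,
    build_features,
    confusion_metrics,
    default_model_specs,
    delong_test,
    final_fit_and_external_test,
    repeated_holdout_eval,
    stratified_split,
    variable_importance,
    _fit_and_score,
    _make_estimator,
)


def _labels(n_pos, n_neg):
    idx = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    return pd.Series(["diseased"] * n_pos + ["healthy"] * n_neg, index=idx)


class TestStratifiedSplit:
    def test_balanced_fifty_fifty_at_seventy_percent(self):
        plan = stratified_split(_labels(50, 50), fraction=0.7, seed=0)
        assert len(plan.train_ids) == 70 and len(plan.test_ids) == 30
        tr = set(plan.train_ids)
        assert sum(s.startswith("p") for s in tr) == 35

    def test_deterministic_and_disjoint(self):
        a = stratified_split(_labels(20, 30), seed=5)
        b = stratified_split(_labels(20, 30), seed=5)
        assert a == b
        assert not (set(a.train_ids) & set(a.test_ids))
        assert set(a.train_ids) | set(a.test_ids) == set(_labels(20, 30).index)

    def test_per_class_proportion_within_one_sample(self):
        for n_pos, n_neg in [(11, 23), (7, 9), (31, 15)]:
            plan = stratified_split(_labels(n_pos, n_neg), fraction=0.7, seed=1)
            tr = set(plan.train_ids)
            for cls, n in (("p", n_pos), ("n", n_neg)):
                got = sum(s.startswith(cls) for s in tr)
                assert abs(got - 0.7 * n) <= 1

    def test_tiny_class_errors(self):
        with pytest.raises(ValueError):
            stratified_split(_labels(1, 30))


class TestMetrics:
    def test_auroc_examples(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert auroc([1, 1, 1, 1], [0, 0, 1, 1]) == 0.5
        assert auroc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_auroc_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.normal(size=40)
            y = rng.integers(0, 2, size=40)
            if y.sum() in (0, 40):
                continue
            assert auroc(s, y) == pytest.approx(1.0 - auroc(-s, y), abs=1e-12)

    def test_auroc_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_confusion_closed_forms(self):
        perfect = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert all(v == 1.0 for v in perfect.values())
        chance = confusion_metrics([0.9, 0.1, 0.9, 0.1], [1, 1, 0, 0])
        assert chance["kappa"] == pytest.approx(0.0)

    def test_kappa_chance_level_under_random_predictions(self):
        rng = np.random.default_rng(1)
        ks = [
            confusion_metrics(rng.random(200), rng.integers(0, 2, 200))["kappa"]
            for _ in range(50)
        ]
        assert abs(np.mean(ks)) < 0.05


class TestDeLong:
    def test_self_comparison_p_one(self):
        s = [0.9, 0.2, 0.7, 0.4, 0.6]
        y = [1, 0, 1, 0, 1]
        a, b, z, p = delong_test(s, s, y)
        assert a == b
        assert z == 0.0 and p == 1.0

    def test_aurocs_match_shared_estimator(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 60)
        y[:5], y[-5:] = 1, 0
        sa, sb = rng.normal(size=60), rng.normal(size=60)
        a, b, _, _ = delong_test(sa, sb, y)
        assert a == pytest.approx(auroc(sa, y), abs=1e-12)
        assert b == pytest.approx(auroc(sb, y), abs=1e-12)

    def test_null_calibration_uniform_p(self):
        rng = np.random.default_rng(3)
        y = np.array([1] * 50 + [0] * 50)
        ps = [
            delong_test(rng.normal(size=100), rng.normal(size=100), y)[3]
            for _ in range(300)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            delong_test([0.1], [0.2], [1])


class TestFeaturesAndFits:
    def _spiky_data(self, n_per_class=30, n_inf=3, n_noise=5, seed=4):
        rng = np.random.default_rng(seed)
        labels = _labels(n_per_class, n_per_class)
        y = (labels == "diseased").to_numpy()
        cols = {}
        for j in range(n_inf):
            cols[j] = np.where(y, rng.random(len(y)) < 0.8, rng.random(len(y)) < 0.1) * 0.01
        for j in range(n_inf, n_inf + n_noise):
            cols[j] = (rng.random(len(y)) < 0.3) * 0.01
        ab = pd.DataFrame(cols, index=labels.index)
        return ab, labels

    def test_build_features_zero_fills_missing_clusters(self):
        ab, labels = self._spiky_data()
        X = build_features(ab, [0, 99])
        assert (X[99] == np.log10(1e-6)).all()

    def test_zero_feature_matrix_scores_half(self):
        ab, labels = self._spiky_data()
        X = build_features(ab, [])
        scores, model = _fit_and_score(
            ModelSpec("random_forest"), X, (labels == "diseased").to_numpy(), X, seed=0
        )
        assert model is None
        assert (scores == 0.5).all()

    def test_internal_holdout_strong_signal_high_auroc(self):
        ab, labels = self._spiky_data()
        X = build_features(ab, list(ab.columns))
        specs = default_model_specs(("penalized_logistic", "random_forest", "rbf_svm"))
        res = repeated_holdout_eval(X, labels, specs, repeats=3, seed=0)
        for fam, ms in res.items():
            assert ms.mean("auroc") >= 0.9, fam
            lo, hi = ms.ci("auroc")
            assert lo <= ms.mean("auroc") <= hi

    def test_all_six_families_run_externally(self):
        ab, labels = self._spiky_data()
        X = build_features(ab, list(ab.columns))
        plan = stratified_split(labels, fraction=0.7, seed=2)
        tr, te = list(plan.train_ids), list(plan.test_ids)
        metrics, scores, models = final_fit_and_external_test(
            X.loc[tr], labels.loc[tr], X.loc[te], labels.loc[te],
            default_model_specs(), seed=0,
        )
        assert set(metrics) == {
            "penalized_logistic", "random_forest", "rbf_svm",
            "neural_net", "gradient_boosting", "knn",
        }
        for fam, m in metrics.items():
            assert 0 <= m["auroc"] <= 1 and -1 <= m["kappa"] <= 1

    def test_determinism_at_fixed_seed(self):
        ab, labels = self._spiky_data()
        X = build_features(ab, list(ab.columns))
        specs = default_model_specs(("random_forest",))
        a = repeated_holdout_eval(X, labels, specs, repeats=2, seed=9)
        b = repeated_holdout_eval(X, labels, specs, repeats=2, seed=9)
        np.testing.assert_array_equal(
            a["random_forest"].values["auroc"], b["random_forest"].values["auroc"]
        )

    def test_leakage_guard_internal_metrics_ignore_test_labels(self):
        ab, labels = self._spiky_data()
        X = build_features(ab, list(ab.columns))
        plan = stratified_split(labels, fraction=0.7, seed=3)
        tr = list(plan.train_ids)
        specs = default_model_specs(("random_forest",))
        base = repeated_holdout_eval(X.loc[tr], labels.loc[tr], specs, repeats=2, seed=1)
        corrupted = labels.copy()
        corrupted.loc[list(plan.test_ids)] = "healthy"  # scramble held-out labels
        after = repeated_holdout_eval(X.loc[tr], corrupted.loc[tr], specs, repeats=2, seed=1)
        np.testing.assert_array_equal(
            base["random_forest"].values["auroc"], after["random_forest"].values["auroc"]
        )


class TestVariableImportance:
    def test_single_informative_feature_ranks_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            labels = _labels(30, 30)
            y = (labels == "diseased").to_numpy().astype(int)
            X = pd.DataFrame(rng.normal(size=(60, 6)), index=labels.index)
            X[0] = y + rng.normal(0, 0.3, 60)
            model = _make_estimator("random_forest", seed).fit(X.to_numpy(), y)
            imp = variable_importance(model, "random_forest", X, y, seed=seed)
            if imp.iloc[0]["feature"] == 0:
                hits += 1
        assert hits >= 9

    def test_constant_feature_zero_permutation_importance(self):
        rng = np.random.default_rng(7)
        labels = _labels(20, 20)
        y = (labels == "diseased").to_numpy().astype(int)
        X = pd.DataFrame({0: y + rng.normal(0, 0.2, 40), 1: np.zeros(40)},
                         index=labels.index)
        model = _make_estimator("knn", 0).fit(X.to_numpy(), y)
        imp = variable_importance(model, "knn", X, y, seed=0).set_index("feature")
        assert imp.loc[1, "importance"] == 0.0

    def test_normalization_maps_max_to_100(self):
        rng = np.random.default_rng(8)
        labels = _labels(20, 20)
        y = (labels == "diseased").to_numpy().astype(int)
        X = pd.DataFrame(rng.normal(size=(40, 4)), index=labels.index)
        X[2] = y * 2.0
        model = _make_estimator("penalized_logistic", 0).fit(X.to_numpy(), y)
        imp = variable_importance(model, "penalized_logistic", X, y)
        assert imp["importance"].max() == pytest.approx(100.0)
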