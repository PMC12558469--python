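"""Two-stage discrimination of diseased vs healthy samples from cluster features.

Feature values are each selected cluster's summed clone fraction per sample,
``log10(x + 1e-6)`` transformed (abundances are heavy-tailed) and standardized
on training statistics inside each model pipeline. Six model families are
evaluated: elastic-net-penalized logistic regression, random forest, RBF-kernel
SVM, a single-hidden-layer neural network, gradient boosting, and k-nearest
neighbours — each tuned over a small fixed grid by stratified 5-fold inner CV
maximizing AUROC.

Stage one is internal validation: repeated stratified 80/20 holdout inside the
training split, metrics summarized by mean and empirical percentile 95% CI
(with five repeats the interval is necessarily coarse). Stage two refits each
tuned model on the full training split and scores the untouched 30% test
split. Paired model comparisons use the fast DeLong test on placement values;
variable importance is model-native where the family defines one and
permutation-based otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "diseased"
FAMILIES = (
    "penalized_logistic",
    "random_forest",
    "rbf_svm",
    "neural_net",
    "gradient_boosting",
    "knn",
)


# ---------------------------------------------------------------------------
# split plan

@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    fraction: float
    seed: int


def stratified_split(labels: pd.Series, fraction: float = 0.70, seed: int = 0) -> SplitPlan:
    """Per-class sampling without replacement at ``fraction``; deterministic.

    ``labels`` maps sample_id → class. Train proportions deviate from the
    fraction by at most one sample per class.
    """
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("need two classes to split")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(classes):
        ids = sorted(labels[labels == cls].index)
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(round(fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        perm = rng.permutation(len(ids))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return SplitPlan(
        train_ids=tuple(sorted(train)),
        test_ids=tuple(sorted(test)),
        fraction=fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# model specs

@dataclass(frozen=True)
class ModelSpec:
    family: str
    grid: dict = field(default_factory=dict)
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


def default_model_specs(families=FAMILIES) -> list[ModelSpec]:
    """The six families with small fixed hyperparameter grids."""
    grids = {
        "penalized_logistic": {
            "clf__l1_ratio": [0.1, 0.5, 0.9],
            "clf__C": [0.1, 1.0, 10.0],
        },
        "random_forest": {"clf__max_features": ["sqrt", 0.33]},
        "rbf_svm": {"clf__C": [0.1, 1.0, 10.0]},
        "neural_net": {"clf__alpha": [1e-4, 1e-2, 1.0]},
        "gradient_boosting": {"clf__max_depth": [1, 3]},
        "knn": {"clf__n_neighbors": [5, 11, 21, 43]},
    }
    return [ModelSpec(family=f, grid=grids[f]) for f in families]


def _make_estimator(family: str, seed: int) -> Pipeline:
    if family == "penalized_logistic":
        # a float l1_ratio selects the elastic-net penalty under saga
        clf = LogisticRegression(solver="saga", l1_ratio=0.5, C=1.0, max_iter=5000)
    elif family == "random_forest":
        clf = RandomForestClassifier(n_estimators=500, random_state=seed)
    elif family == "rbf_svm":
        clf = SVC(kernel="rbf", probability=True, random_state=seed)
    elif family == "neural_net":
        clf = MLPClassifier(
            hidden_layer_sizes=(5,), max_iter=2000, random_state=seed
        )
    elif family == "gradient_boosting":
        clf = GradientBoostingClassifier(n_estimators=100, random_state=seed)
    elif family == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    else:  # pragma: no cover
        raise ValueError(family)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


# ---------------------------------------------------------------------------
# features

def build_features(abundance: pd.DataFrame, selected: list[int]) -> pd.DataFrame:
    """log10(x + 1e-6)-transformed abundances of the selected clusters.

    Clusters missing from the matrix columns (e.g. absent from a projection)
    are zero-filled with a warning before the transform.
    """
    X = pd.DataFrame(index=abundance.index)
    for cid in selected:
        if cid in abundance.columns:
            X[cid] = abundance[cid]
        else:
            logger.warning("cluster %s absent from abundance matrix; zero-filled", cid)
            X[cid] = 0.0
    return np.log10(X + 1e-6)


def _binary(labels: pd.Series) -> np.ndarray:
    return (labels == POSITIVE_CLASS).astype(int).to_numpy()


# ---------------------------------------------------------------------------
# metrics

def auroc(scores, labels) -> float:
    """AUROC in the Mann–Whitney midrank form: P(s+ > s−) + ½P(tie)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    r = stats.rankdata(scores)
    return float((r[y == 1].sum() - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy / sensitivity / specificity / Cohen's kappa at a score threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = tp + tn + fp + fn
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = 0.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return {
        "accuracy": p_o,
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "kappa": kappa,
    }


METRIC_NAMES = ("auroc", "accuracy", "sensitivity", "specificity", "kappa")


@dataclass
class MetricSet:
    """Mean and empirical 95% CI of each metric across repeats."""

    values: dict[str, np.ndarray]  # metric -> per-repeat values

    def mean(self, metric: str) -> float:
        return float(np.mean(self.values[metric]))

    def ci(self, metric: str) -> tuple[float, float]:
        v = self.values[metric]
        return (
            float(np.percentile(v, 2.5)),
            float(np.percentile(v, 97.5)),
        )

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for m in METRIC_NAMES:
            lo, hi = self.ci(m)
            rows.append({"metric": m, "mean": self.mean(m), "ci_lo": lo, "ci_hi": hi})
        return pd.DataFrame(rows).set_index("metric")

    def to_dict(self) -> dict:
        out = {}
        for m in METRIC_NAMES:
            lo, hi = self.ci(m)
            out[m] = {
                "mean": self.mean(m),
                "ci_lo": lo,
                "ci_hi": hi,
                "values": [float(v) for v in self.values[m]],
            }
        return out


def _all_metrics(scores, y) -> dict[str, float]:
    out = {"auroc": auroc(scores, y)}
    out.update(confusion_metrics(scores, y))
    return out


# ---------------------------------------------------------------------------
# model fitting

def _fit_and_score(
    spec: ModelSpec,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_eval: pd.DataFrame,
    seed: int,
) -> tuple[np.ndarray, object]:
    """Tune on the training block (inner CV), return eval scores + fitted model.

    With zero features every sample scores 0.5 (constant model): the honest
    behaviour when selection returns nothing.
    """
    if X_train.shape[1] == 0:
        return np.full(len(X_eval), 0.5), None
    est = _make_estimator(spec.family, seed)
    grid = dict(spec.grid)
    if spec.family == "knn" and "clf__n_neighbors" in grid:
        # neighbours cannot exceed the inner-CV training-fold size
        cap = max(1, (len(X_train) * (spec.inner_folds - 1)) // spec.inner_folds)
        ks = [k for k in grid["clf__n_neighbors"] if k <= cap]
        grid["clf__n_neighbors"] = ks or [cap]
    if grid:
        cv = StratifiedKFold(n_splits=spec.inner_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(est, grid, cv=cv, scoring="roc_auc", n_jobs=1)
        search.fit(X_train.to_numpy(), y_train)
        model = search.best_estimator_
    else:
        model = est.fit(X_train.to_numpy(), y_train)
    scores = model.predict_proba(X_eval.to_numpy())[:, 1]
    return scores, model


def repeated_holdout_eval(
    X: pd.DataFrame,
    labels: pd.Series,
    specs: list[ModelSpec],
    repeats: int = 5,
    inner_fraction: float = 0.8,
    seed: int = 0,
    max_redraws: int = 20,
) -> dict[str, MetricSet]:
    """Stage one: repeated stratified 80/20 holdout inside the training split."""
    labels = labels.reindex(X.index)
    results: dict[str, dict[str, list[float]]] = {
        s.family: {m: [] for m in METRIC_NAMES} for s in specs
    }
    for r in range(repeats):
        plan = None
        for attempt in range(max_redraws):
            cand = stratified_split(labels, fraction=inner_fraction, seed=seed * 1000 + r * 50 + attempt)
            y_eval = _binary(labels.loc[list(cand.test_ids)])
            if 0 < y_eval.sum() < len(y_eval):
                plan = cand
                break
        if plan is None:
            raise RuntimeError(f"could not draw a two-class holdout fold in {max_redraws} tries")
        tr = list(plan.train_ids)
        ev = list(plan.test_ids)
        y_tr = _binary(labels.loc[tr])
        y_ev = _binary(labels.loc[ev])
        for spec in specs:
            scores, _ = _fit_and_score(spec, X.loc[tr], y_tr, X.loc[ev], seed=seed + r)
            for m, v in _all_metrics(scores, y_ev).items():
                results[spec.family][m].append(v)
    return {
        fam: MetricSet(values={m: np.array(v) for m, v in d.items()})
        for fam, d in results.items()
    }


def final_fit_and_external_test(
    X_train: pd.DataFrame,
    labels_train: pd.Series,
    X_test: pd.DataFrame,
    labels_test: pd.Series,
    specs: list[ModelSpec],
    seed: int = 0,
) -> tuple[dict[str, dict[str, float]], dict[str, np.ndarray], dict[str, object]]:
    """Stage two: refit each tuned model on all training samples, score the test set.

    Returns ``(metrics, scores, fitted_models)`` keyed by family.
    """
    y_tr = _binary(labels_train.reindex(X_train.index))
    y_te = _binary(labels_test.reindex(X_test.index))
    metrics: dict[str, dict[str, float]] = {}
    scores_by_family: dict[str, np.ndarray] = {}
    models: dict[str, object] = {}
    for spec in specs:
        scores, model = _fit_and_score(spec, X_train, y_tr, X_test, seed=seed)
        metrics[spec.family] = _all_metrics(scores, y_te)
        scores_by_family[spec.family] = scores
        models[spec.family] = model
    return metrics, scores_by_family, models


# ---------------------------------------------------------------------------
# DeLong test

def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Midrank placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    pos_r = stats.rankdata(pos)
    neg_r = stats.rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two correlated AUROCs on the same samples.

    Returns ``(auroc_a, auroc_b, z, two_sided_p)``; a degenerate zero-variance
    difference (e.g. a model against itself) yields z = 0, p = 1.
    """
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    v10a, v01a, auc_a = _placements(a, y)
    v10b, v01b, auc_b = _placements(b, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    if var_diff <= 1e-16:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(min(1.0, p))


def delong_matrix(
    scores_by_family: dict[str, np.ndarray], labels
) -> pd.DataFrame:
    fams = sorted(scores_by_family)
    mat = pd.DataFrame(np.ones((len(fams), len(fams))), index=fams, columns=fams)
    for i, fa in enumerate(fams):
        for fb in fams[i + 1 :]:
            _, _, _, p = delong_test(scores_by_family[fa], scores_by_family[fb], labels)
            mat.loc[fa, fb] = p
            mat.loc[fb, fa] = p
    return mat


# ---------------------------------------------------------------------------
# variable importance

def variable_importance(
    model,
    family: str,
    X: pd.DataFrame,
    labels,
    seed: int = 0,
    n_shuffles: int = 10,
) -> pd.DataFrame:
    """Feature importance, normalized to [0, 100] with ranks (1 = most important).

    Model-native where the family defines one (absolute standardized
    coefficients; impurity decrease; absolute connection-weight sums), else
    permutation importance: mean AUROC drop over single-feature shuffles.
    """
    y = np.asarray(labels)
    features = list(X.columns)
    if model is None or not features:
        return pd.DataFrame(columns=["feature", "importance", "rank"])
    clf = model.named_steps["clf"]
    if family == "penalized_logistic":
        raw = np.abs(clf.coef_).ravel()
    elif family in ("random_forest", "gradient_boosting"):
        raw = clf.feature_importances_
    elif family == "neural_net":
        raw = (np.abs(clf.coefs_[0]) @ np.abs(clf.coefs_[1])).ravel()
    else:  # permutation importance on AUROC
        rng = np.random.default_rng(seed)
        base = auroc(model.predict_proba(X.to_numpy())[:, 1], y)
        raw = np.zeros(len(features))
        Xv = X.to_numpy().copy()
        for j in range(len(features)):
            drops = []
            col = Xv[:, j].copy()
            for _ in range(n_shuffles):
                Xv[:, j] = rng.permutation(col)
                drops.append(base - auroc(model.predict_proba(Xv)[:, 1], y))
            Xv[:, j] = col
            raw[j] = max(0.0, float(np.mean(drops)))
    mx = raw.max()
    importance = 100.0 * raw / mx if mx > 0 else np.zeros_like(raw)
    order = np.argsort(-importance, kind="stable")
    ranks = np.empty(len(features), dtype=int)
    ranks[order] = np.arange(1, len(features) + 1)
    return pd.DataFrame(
        {"feature": features, "importance": importance, "rank": ranks}
    ).sort_values("rank", ignore_index=True)
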