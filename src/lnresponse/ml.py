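"""Patient-grouped, class-balanced nested cross-validation scored by MCC.

Folds are built at the patient (group) level so that no patient's samples
ever span the train and test side of any split; groups are assigned whole
to folds by a greedy balancer that keeps per-class sample counts even.
Hyperparameters are tuned in an inner loop (10-fold, 5 repeats by default)
on mean inner MCC, the tuned model is refit on the outer training split,
and models are ranked by mean outer-fold Matthews correlation coefficient.
Classifier implementations come from scikit-learn (plus xgboost when
available); the fold construction, tuning loop and MCC accounting live
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import clone

__all__ = ["FoldPlan", "ModelReport", "make_grouped_stratified_folds",
           "mcc", "confusion_counts", "nested_cv", "default_model_grid",
           "small_model_grid"]


@dataclass
class FoldPlan:
    """Outer folds as (train_idx, test_idx) pairs over samples."""

    folds: List[Tuple[np.ndarray, np.ndarray]]
    groups: np.ndarray
    seed: int

    def to_dict(self) -> dict:
        return {"seed": int(self.seed),
                "folds": [{"train": train.tolist(), "test": test.tolist()}
                          for train, test in self.folds]}


@dataclass
class ModelReport:
    model: str
    fold_mcc: List[float]
    mean_mcc: float
    chosen_params: List[dict] = field(default_factory=list)
    flags: List[str] = field(default_factory=list)


def make_grouped_stratified_folds(labels: Sequence, groups: Sequence,
                                  k: int = 5, seed: int = 0) -> FoldPlan:
    """Assign groups whole to k folds, greedily balancing class counts.

    Groups are processed in decreasing size (seeded shuffle breaking ties)
    and each goes to the fold with the fewest samples of its majority
    class, then fewest samples overall.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if labels.shape != groups.shape:
        raise ValueError("labels and groups must align")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("expected exactly two classes")
    uniq = pd.unique(groups)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > uniq.size:
        raise ValueError(f"k={k} exceeds the {uniq.size} available groups")
    for cls in classes:
        if pd.unique(groups[labels == cls]).size < 2:
            raise ValueError(f"class {cls!r} confined to a single group")

    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)
    shuffled = uniq[order]
    sizes = np.array([(groups == g).sum() for g in shuffled])
    shuffled = shuffled[np.argsort(-sizes, kind="stable")]

    class_counts = np.zeros((k, classes.size))
    totals = np.zeros(k)
    assignment: Dict = {}
    for g in shuffled:
        mask = groups == g
        counts = np.array([(labels[mask] == c).sum() for c in classes])
        major = int(np.argmax(counts))
        keys = list(zip(class_counts[:, major], totals, range(k)))
        fold = min(range(k), key=lambda f: keys[f])
        assignment[g] = fold
        class_counts[fold] += counts
        totals[fold] += mask.sum()

    fold_of_sample = np.array([assignment[g] for g in groups])
    folds = []
    for f in range(k):
        test = np.flatnonzero(fold_of_sample == f)
        train = np.flatnonzero(fold_of_sample != f)
        folds.append((train, test))
        if np.unique(labels[train]).size < 2:
            warnings.warn(f"fold {f}: training split lost a class")
    return FoldPlan(folds=folds, groups=groups, seed=seed)


def confusion_counts(y_true: Sequence, y_pred: Sequence,
                     positive) -> Tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == positive) & (y_pred == positive)).sum())
    tn = int(((y_true != positive) & (y_pred != positive)).sum())
    fp = int(((y_true != positive) & (y_pred == positive)).sum())
    fn = int(((y_true == positive) & (y_pred != positive)).sum())
    return tp, tn, fp, fn


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    for v in (tp, tn, fp, fn):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def _mcc_from_labels(y_true, y_pred, positive) -> float:
    return mcc(*confusion_counts(y_true, y_pred, positive))


def _param_combinations(grid: Dict[str, Sequence]) -> List[dict]:
    if not grid:
        return [{}]
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in product(*grid.values())]


def nested_cv(features: pd.DataFrame, labels: Sequence, groups: Sequence,
              model_grid: Dict[str, dict], seed: int = 0,
              outer_k: int = 5, inner_k: int = 10, inner_repeats: int = 5,
              positive="non-responder") -> List[ModelReport]:
    """Nested grouped-stratified CV over a model grid, ranked by mean MCC.

    ``model_grid`` maps model name -> ``{"estimator": sklearn estimator,
    "param_grid": {param: values}}``.  Inner CV (``inner_k``-fold,
    ``inner_repeats`` repeats, grouped) picks the parameter combination
    with the highest mean inner MCC; the refit model is scored on the
    outer test fold.  Outer training splits that lose a class are skipped
    with a flag.
    """
    if not model_grid:
        raise ValueError("model grid is empty")
    X = np.asarray(features, float)
    y_raw = np.asarray(labels)
    # encode so the positive class is 1 (some estimators need integers)
    y = (y_raw == positive).astype(int)
    positive = 1
    g = np.asarray(groups)
    if not (len(X) == len(y) == len(g)):
        raise ValueError("features, labels and groups must align")
    plan = make_grouped_stratified_folds(y, g, k=outer_k, seed=seed)
    rng = np.random.default_rng(seed + 1)

    reports = []
    for name, spec in model_grid.items():
        est = spec["estimator"]
        combos = _param_combinations(spec.get("param_grid", {}))
        fold_scores, chosen, flags = [], [], []
        for fi, (train, test) in enumerate(plan.folds):
            if np.unique(y[train]).size < 2:
                flags.append(f"fold{fi}_single_class_skipped")
                continue
            inner_kk = min(inner_k, pd.unique(g[train]).size)
            combo_means = []
            for combo in combos:
                scores = []
                for rep in range(inner_repeats):
                    inner_seed = int(rng.integers(2 ** 31))
                    inner = make_grouped_stratified_folds(
                        y[train], g[train], k=inner_kk, seed=inner_seed)
                    for itr, ite in inner.folds:
                        if (np.unique(y[train][itr]).size < 2
                                or ite.size == 0):
                            continue
                        model = clone(est).set_params(**combo)
                        model.fit(X[train][itr], y[train][itr])
                        scores.append(_mcc_from_labels(
                            y[train][ite], model.predict(X[train][ite]),
                            positive))
                combo_means.append(np.mean(scores) if scores else -np.inf)
            best = combos[int(np.argmax(combo_means))]
            model = clone(est).set_params(**best)
            model.fit(X[train], y[train])
            fold_scores.append(_mcc_from_labels(
                y[test], model.predict(X[test]), positive))
            chosen.append(best)
        reports.append(ModelReport(
            model=name, fold_mcc=fold_scores,
            mean_mcc=float(np.mean(fold_scores)) if fold_scores else np.nan,
            chosen_params=chosen, flags=flags))
    reports.sort(key=lambda r: (np.isnan(r.mean_mcc), -r.mean_mcc))
    return reports


def small_model_grid(seed: int = 0) -> Dict[str, dict]:
    """A fast three-model grid for demos and calibration runs."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier

    return {
        "logistic": {"estimator": LogisticRegression(max_iter=2000),
                     "param_grid": {"C": [0.1, 1.0, 10.0]}},
        "random_forest": {
            "estimator": RandomForestClassifier(n_estimators=50,
                                                random_state=seed),
            "param_grid": {"max_depth": [3, None]}},
        "knn": {"estimator": KNeighborsClassifier(),
                "param_grid": {"n_neighbors": [3, 5]}},
    }


def default_model_grid(seed: int = 0) -> Dict[str, dict]:
    """The eleven-model classifier zoo (configurable; one entry per family:
    linear-logistic, discriminant, extreme gradient boosting, random
    forest, k-NN, linear/RBF kernel machines, neural net, naive Bayes,
    boosted trees, gradient-boosted additive)."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import (AdaBoostClassifier,
                                  GradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    grid = {
        "logistic": {"estimator": LogisticRegression(max_iter=2000),
                     "param_grid": {"C": [0.1, 1.0, 10.0]}},
        "lda": {"estimator": LinearDiscriminantAnalysis(), "param_grid": {}},
        "random_forest": {
            "estimator": RandomForestClassifier(n_estimators=100,
                                                random_state=seed),
            "param_grid": {"max_depth": [3, None]}},
        "knn": {"estimator": KNeighborsClassifier(),
                "param_grid": {"n_neighbors": [3, 5, 7]}},
        "svm_linear": {"estimator": SVC(kernel="linear"),
                       "param_grid": {"C": [0.1, 1.0, 10.0]}},
        "svm_rbf": {"estimator": SVC(kernel="rbf"),
                    "param_grid": {"C": [0.1, 1.0, 10.0]}},
        "mlp": {"estimator": MLPClassifier(max_iter=1000, random_state=seed),
                "param_grid": {"hidden_layer_sizes": [(16,), (32,)]}},
        "naive_bayes": {"estimator": GaussianNB(), "param_grid": {}},
        "adaboost_trees": {
            "estimator": AdaBoostClassifier(random_state=seed),
            "param_grid": {"n_estimators": [50, 100]}},
        "gradient_boosting": {
            "estimator": GradientBoostingClassifier(random_state=seed),
            "param_grid": {"n_estimators": [50, 100]}},
    }
    try:
        from xgboost import XGBClassifier
        grid["xgboost"] = {
            "estimator": XGBClassifier(eval_metric="logloss",
                                       random_state=seed),
            "param_grid": {"max_depth": [2, 4]}}
    except ImportError:  # keep the zoo usable without the optional extra
        pass
    return grid
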