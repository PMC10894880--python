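"""Cohort splitting, t-test feature filtering, and grid-searched classifiers.

The classifier zoo mirrors the usual WSI-signature line-up: RBF-kernel SVM
(defaults otherwise), random forest, extremely randomized trees, two
gradient-boosting families, and a 128/64/32 MLP.  Tree families share the
grid n_estimators in 10..50 step 5 crossed with max_depth in {2,3,4,5} —
note that this enumerates 36 configurations, although the source material
describes the same ranges as forming 40 search models.

Gradient-boosting note: the XGBoost and LightGBM libraries are not
available in the runtime, so those families are backed by scikit-learn's
``GradientBoostingClassifier`` and ``HistGradientBoostingClassifier``
(the same algorithm family with the same exposed grid).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = [
    "split_cohort",
    "assign_split",
    "ttest_filter",
    "ModelSpec",
    "FittedSignature",
    "grid_search_fit",
    "predict_documents",
    "MODEL_FAMILIES",
]

TREE_GRID = {"n_estimators": list(range(10, 51, 5)), "max_depth": [2, 3, 4, 5]}

MODEL_FAMILIES = ("SVM", "random_forest", "extratrees", "xgboost",
                  "lightgbm", "mlp")


def _train_size(n: int, train_fraction: float) -> int:
    # round-half-up so 519 -> 363 and ties go to the training side
    return int(math.floor(n * train_fraction + 0.5))


def split_cohort(
    cases: pd.DataFrame | Sequence,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify_by: str | None = "class_label",
):
    """Randomly split cases into train/test at the given fraction.

    The training partition gets ``round(n * train_fraction)`` cases exactly
    (519 at 0.7 -> 363/156; 400 -> 280/120).  When ``cases`` is a DataFrame
    with the ``stratify_by`` column, the per-class allocation is proportional
    (largest-remainder rounding to keep the total exact).  Returns
    ``(train, test)`` of the same type as the input.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    is_frame = isinstance(cases, pd.DataFrame)
    n = len(cases)
    if n < 2:
        raise ValueError("need at least 2 cases to split")
    rng = np.random.default_rng(seed)
    n_train = _train_size(n, train_fraction)

    if is_frame and stratify_by and stratify_by in cases.columns:
        strata = [np.flatnonzero((cases[stratify_by] == v).to_numpy())
                  for v in sorted(cases[stratify_by].unique())]
    else:
        strata = [np.arange(n)]

    # largest-remainder allocation of the exact training total across strata
    exact = [len(s) * train_fraction for s in strata]
    base = [min(int(math.floor(e)), len(s)) for e, s in zip(exact, strata)]
    short = n_train - sum(base)
    order = sorted(range(len(strata)),
                   key=lambda i: (-(exact[i] - base[i]), i))
    for i in order:
        if short <= 0:
            break
        if base[i] < len(strata[i]):
            base[i] += 1
            short -= 1
    # fall back to any stratum with spare capacity (tiny-group edge case)
    i = 0
    while short > 0 and i < len(strata):
        room = len(strata[i]) - base[i]
        take = min(room, short)
        base[i] += take
        short -= take
        i += 1

    train_idx: list[int] = []
    for s, k in zip(strata, base):
        picked = rng.permutation(s)[:k]
        train_idx.extend(int(j) for j in picked)
    train_mask = np.zeros(n, dtype=bool)
    train_mask[train_idx] = True

    if is_frame:
        return cases[train_mask].copy(), cases[~train_mask].copy()
    arr = list(cases)
    return ([arr[i] for i in range(n) if train_mask[i]],
            [arr[i] for i in range(n) if not train_mask[i]])


def assign_split(cohort: pd.DataFrame, train_fraction: float = 0.7,
                 seed: int = 0, stratify_by: str | None = "class_label",
                 ) -> pd.DataFrame:
    """Return a copy of the cohort with a ``split`` column filled in."""
    train, _ = split_cohort(cohort, train_fraction, seed, stratify_by)
    out = cohort.copy()
    out["split"] = np.where(out["case_id"].isin(train["case_id"]),
                            "train", "test")
    return out


def ttest_filter(features: pd.DataFrame, labels: Sequence,
                 alpha: float = 0.05) -> list[str]:
    """Keep features separating the label groups by Welch t-test at p < alpha.

    Binary labels use a single two-sided test; with more classes, the
    selection is the union of one-vs-rest selections.  Constant features are
    dropped with a warning.
    """
    y = np.asarray(labels)
    if len(y) != len(features):
        raise ValueError("labels length does not match feature rows")
    values = sorted(pd.unique(y))
    if len(values) < 2:
        raise ValueError("need at least two label groups")
    contrasts = ([(values[0],)] if len(values) == 2
                 else [(v,) for v in values])

    constant = [c for c in features.columns
                if features[c].nunique(dropna=False) <= 1]
    if constant:
        warnings.warn(f"dropping {len(constant)} constant feature(s)",
                      stacklevel=2)
    testable = [c for c in features.columns if c not in constant]

    selected: list[str] = []
    x = features[testable].to_numpy(dtype=float)
    for (v,) in contrasts:
        g1 = x[y == v]
        g0 = x[y != v]
        if len(g1) < 2 or len(g0) < 2:
            raise ValueError(f"group {v!r} has fewer than 2 documents")
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(g1, g0, equal_var=False, axis=0)
        p = np.nan_to_num(p, nan=1.0)
        for c, pv in zip(testable, p):
            if pv < alpha and c not in selected:
                selected.append(c)
    return [c for c in features.columns if c in selected]


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus its hyperparameter grid."""

    family: str = "SVM"
    grid: dict = field(default_factory=dict)
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {MODEL_FAMILIES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def effective_grid(self) -> list[dict]:
        grid = self.grid
        if not grid:
            grid = (TREE_GRID if self.family in
                    ("random_forest", "extratrees", "xgboost", "lightgbm")
                    else {})
        if not grid:
            return [{}]
        keys = sorted(grid)
        return [dict(zip(keys, combo))
                for combo in product(*(grid[k] for k in keys))]


def _make_estimator(family: str, params: dict, seed: int):
    if family == "SVM":
        return SVC(kernel="rbf", probability=True, random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "extratrees":
        return ExtraTreesClassifier(random_state=seed, **params)
    if family == "xgboost":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "lightgbm":
        p = dict(params)
        if "n_estimators" in p:        # HistGBM names the count max_iter
            p["max_iter"] = p.pop("n_estimators")
        return HistGradientBoostingClassifier(random_state=seed, **p)
    if family == "mlp":
        return MLPClassifier(hidden_layer_sizes=(128, 64, 32),
                             random_state=seed, max_iter=2000, **params)
    raise ValueError(family)


def _cv_auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    if len(classes) == 2:
        return roc_auc_score((y_true == classes[1]).astype(int), proba[:, 1])
    return roc_auc_score(y_true, proba, multi_class="ovr",
                         average="macro", labels=classes)


@dataclass
class FittedSignature:
    """A refit best model plus its provenance: grid table and columns."""

    model: object
    family: str
    best_params: dict
    cv_table: pd.DataFrame
    feature_names: list[str]
    classes: np.ndarray


def grid_search_fit(features: pd.DataFrame, labels: Sequence,
                    spec: ModelSpec = ModelSpec()) -> FittedSignature:
    """Exhaustive grid search by mean cross-validated AUC, then refit.

    Stratified K-fold within the training documents; every configuration's
    per-fold and mean AUC is recorded in the CV table.  The best
    configuration (ties: first in enumeration order) is refit on the full
    training set.
    """
    y = np.asarray(labels)
    classes = np.array(sorted(pd.unique(y)))
    counts = pd.Series(y).value_counts()
    if (counts < spec.cv_folds).any():
        raise ValueError(
            f"each class needs >= cv_folds={spec.cv_folds} documents; "
            f"got {counts.to_dict()}")
    x = features.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                          random_state=spec.seed)
    folds = list(skf.split(x, y))

    records = []
    for params in spec.effective_grid():
        fold_aucs = []
        for tr, va in folds:
            est = _make_estimator(spec.family, params, spec.seed)
            est.fit(x[tr], y[tr])
            proba = est.predict_proba(x[va])
            fold_aucs.append(_cv_auc(y[va], proba, classes))
        records.append({"params": params, "mean_auc": float(np.mean(fold_aucs)),
                        **{f"fold{i}_auc": a for i, a in enumerate(fold_aucs)}})
    cv_table = pd.DataFrame(records)
    best = cv_table["mean_auc"].idxmax()
    best_params = cv_table.loc[best, "params"]

    model = _make_estimator(spec.family, best_params, spec.seed)
    model.fit(x, y)
    return FittedSignature(model=model, family=spec.family,
                           best_params=dict(best_params), cv_table=cv_table,
                           feature_names=list(features.columns),
                           classes=classes)


def predict_documents(fitted: FittedSignature,
                      features: pd.DataFrame) -> pd.DataFrame:
    """Per-document class probabilities; feature columns must match exactly."""
    got = list(features.columns)
    want = fitted.feature_names
    if got != want:
        missing = [c for c in want if c not in got]
        extra = [c for c in got if c not in want]
        raise ValueError(
            "feature columns do not match training columns: "
            f"missing={missing[:5]}, extra={extra[:5]}, "
            f"order_ok={sorted(got) == sorted(want)}")
    proba = fitted.model.predict_proba(features.to_numpy(dtype=float))
    return pd.DataFrame(proba, index=features.index,
                        columns=[str(c) for c in fitted.model.classes_])
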