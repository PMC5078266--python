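"""SVM-RBF classification of subject groups from global graph metrics.

Feature vectors are the six global metrics per subject.  A soft-margin
SVM with Gaussian kernel K(x, y) = exp(-gamma ||x - y||^2) is tuned by
grid search over (C, gamma) with stratified K-fold cross-validation;
features are standardized (and undefined metric values mean-imputed)
inside each training fold, so no test-fold statistics leak into the
fit.  Reports carry per-class confusion counts plus support-weighted
precision, recall and F-measure, which is also the grid-search
objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

TASKS = {
    "HC-CIS": ("HC", "CIS"),
    "CIS-RR": ("CIS", "RR"),
    "RR-PP": ("RR", "PP"),
    "RR-SP": ("RR", "SP"),
    "SP-PP": ("SP", "PP"),
    "CIS-RR-SP": ("CIS", "RR", "SP"),
}


@dataclass(frozen=True)
class GridSpec:
    """Candidate (C, gamma) values and the fold count of the search."""

    C_values: tuple[float, ...]
    gamma_values: tuple[float, ...]
    k_folds: int = 10

    def __post_init__(self) -> None:
        if not self.C_values or not self.gamma_values:
            raise ValueError("grids must be non-empty")
        if min(self.C_values) <= 0 or min(self.gamma_values) <= 0:
            raise ValueError("C and gamma candidates must be positive")


def default_grid(k_folds: int = 10) -> GridSpec:
    """Powers of two spanning C in [2^-5, 2^15], gamma in [2^-15, 2^3], step 2^2."""
    return GridSpec(
        C_values=tuple(2.0 ** np.arange(-5, 16, 2)),
        gamma_values=tuple(2.0 ** np.arange(-15, 4, 2)),
        k_folds=k_folds,
    )


def standardize(
    train_rows: np.ndarray, apply_rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, tuple[np.ndarray, np.ndarray]]:
    """Center/scale features with training-set statistics only.

    Constant features get scale clamped to 1 (with a warning) so they
    pass through centered but unscaled.  Returns the transformed
    training rows, the transformed apply rows (same parameters), and
    the (location, scale) pair.
    """
    X = np.asarray(train_rows, dtype=float)
    if X.size == 0:
        raise ValueError("empty training set")
    loc = X.mean(axis=0)
    scale = X.std(axis=0)
    constant = scale == 0
    if constant.any():
        logger.warning("constant feature(s) at columns %s: scale clamped to 1", np.nonzero(constant)[0])
        scale = np.where(constant, 1.0, scale)
    out_apply = None
    if apply_rows is not None:
        out_apply = (np.asarray(apply_rows, dtype=float) - loc) / scale
    return (X - loc) / scale, out_apply, (loc, scale)


def rbf_kernel(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """Gaussian kernel exp(-gamma ||x - y||^2); 1 iff x == y."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return float(np.exp(-gamma * float(diff @ diff)))


@dataclass(frozen=True)
class SvmModel:
    """A fitted binary soft-margin RBF SVM in its dual representation.

    ``alpha`` are the Lagrange multipliers of the support vectors (all
    in [0, C]), ``sv_y`` their labels in {-1, +1}, and the decision
    value of a point is sum_i alpha_i y_i K(x_i, .) + b.
    """

    C: float
    gamma: float
    support_vectors: np.ndarray
    alpha: np.ndarray
    sv_y: np.ndarray
    b: float
    classes: tuple
    standardization: tuple[np.ndarray, np.ndarray] | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.standardization is not None:
            loc, scale = self.standardization
            X = (X - loc) / scale
        d2 = (
            (X**2).sum(axis=1)[:, None]
            + (self.support_vectors**2).sum(axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * d2)
        return K @ (self.alpha * self.sv_y) + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes[1], self.classes[0])

    def dual_feasibility(self, tol: float = 1e-6) -> dict[str, float]:
        """Box-constraint and equality-constraint residuals of the dual."""
        box = float(max(np.max(-self.alpha, initial=0.0), np.max(self.alpha - self.C, initial=0.0)))
        eq = float(abs(np.sum(self.alpha * self.sv_y)))
        return {"box_violation": max(box, 0.0), "equality_residual": eq, "tol": tol}

    def is_dual_feasible(self, tol: float = 1e-6) -> bool:
        r = self.dual_feasibility(tol)
        return r["box_violation"] <= tol and r["equality_residual"] <= tol


def train_svm(
    X: np.ndarray,
    y: Sequence,
    C: float,
    gamma: float,
    standardization: tuple[np.ndarray, np.ndarray] | None = None,
) -> SvmModel:
    """Fit a binary RBF SVM; both labels must be present.

    ``X`` is assumed already standardized (pass the parameters through
    ``standardization`` so ``predict`` can transform raw inputs).
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"binary SVM needs exactly 2 classes, got {list(classes)}")
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(np.asarray(X, dtype=float), y)
    signed = clf.dual_coef_[0]  # alpha_i * y_i over support vectors
    return SvmModel(
        C=C,
        gamma=gamma,
        support_vectors=clf.support_vectors_.copy(),
        alpha=np.abs(signed),
        sv_y=np.sign(signed),
        b=float(clf.intercept_[0]),
        classes=tuple(clf.classes_),
        standardization=standardization,
    )


def precision_recall_f(TP: int, FP: int, TN: int, FN: int) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R); undefined pieces are 0."""
    if min(TP, FP, TN, FN) < 0:
        raise ValueError("confusion counts must be nonnegative")
    P = TP / (TP + FP) if TP + FP > 0 else 0.0
    R = TP / (TP + FN) if TP + FN > 0 else 0.0
    F = 2 * P * R / (P + R) if P + R > 0 else 0.0
    return P, R, F


@dataclass(frozen=True)
class ClassificationReport:
    """Outcome of one task: chosen hyperparameters and P/R/F.

    Aggregates are support-weighted averages of the per-class one-vs-rest
    values; the per-class dict keeps each class as "positive" in turn
    (the positive-class convention is thereby explicit in every report).
    """

    task: str
    feature_set: tuple[str, ...]
    C: float
    gamma: float
    n: int
    counts: dict[str, dict[str, int]]
    per_class: dict[str, tuple[float, float, float]]
    precision: float
    recall: float
    f_measure: float
    cv_f_measure: float
    averaging: str = "weighted one-vs-rest"


def _aggregate(y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence) -> tuple[dict, dict, float, float, float]:
    counts, per_class = {}, {}
    P_w = R_w = F_w = 0.0
    n = len(y_true)
    for c in classes:
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        tn = int(np.sum((y_pred != c) & (y_true != c)))
        counts[str(c)] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
        P, R, F = precision_recall_f(tp, fp, tn, fn)
        per_class[str(c)] = (P, R, F)
        support = (tp + fn) / n
        P_w += support * P
        R_w += support * R
        F_w += support * F
    return counts, per_class, P_w, R_w, F_w


def grid_search_cv(
    X: np.ndarray,
    y: Sequence,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive (C, gamma) search scored by K-fold CV weighted F-measure.

    Standardization and mean imputation are fitted inside each training
    fold.  Returns the argmax pair and the full scored grid; the search
    is deterministic for a given seed.
    """
    grid = grid or default_grid()
    y = np.asarray(y)
    if len(y) < grid.k_folds:
        raise ValueError(f"n={len(y)} smaller than fold count {grid.k_folds}")
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="mean")),
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf")),
        ]
    )
    cv = StratifiedKFold(n_splits=grid.k_folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(
        pipe,
        {"svm__C": list(grid.C_values), "svm__gamma": list(grid.gamma_values)},
        scoring="f1_weighted",
        cv=cv,
        n_jobs=1,
    )
    gs.fit(np.asarray(X, dtype=float), y)
    table = pd.DataFrame(
        {
            "C": gs.cv_results_["param_svm__C"],
            "gamma": gs.cv_results_["param_svm__gamma"],
            "cv_f_measure": gs.cv_results_["mean_test_score"],
        }
    )
    return float(gs.best_params_["svm__C"]), float(gs.best_params_["svm__gamma"]), table


def run_task(
    cohort_metrics: pd.DataFrame,
    groups: Sequence[str] | str,
    features: Sequence[str] | str = "all",
    grid: GridSpec | None = None,
    seed: int = 0,
) -> ClassificationReport:
    """Grid-searched, cross-validated classification of a group subset.

    ``cohort_metrics`` is the tidy metric table (subject_id, group, six
    metric columns).  ``groups`` is a task name ("HC-CIS", ...) or an
    explicit label subset; ``features`` is "all" or a subset of the six
    metric names.  The report's P/R/F come from out-of-fold predictions
    at the best (C, gamma).
    """
    grid = grid or default_grid()
    if isinstance(groups, str):
        task_name = groups
        if groups not in TASKS:
            raise ValueError(f"unknown task {groups!r}; valid: {sorted(TASKS)}")
        groups = TASKS[task_name]
    else:
        groups = tuple(groups)
        task_name = "-".join(groups)
    known = set(cohort_metrics["group"].unique())
    bad = [g for g in groups if g not in known]
    if bad:
        raise ValueError(f"groups {bad} absent from table; present: {sorted(known)}")
    if features == "all":
        features = METRIC_NAMES
    elif isinstance(features, str):
        features = (features,)
    bad = [f for f in features if f not in METRIC_NAMES]
    if bad:
        raise ValueError(f"unknown metrics {bad}; valid: {list(METRIC_NAMES)}")
    sub = cohort_metrics[cohort_metrics["group"].isin(groups)]
    X = sub[list(features)].to_numpy(dtype=float)
    y = sub["group"].to_numpy()
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        logger.info("task %s: %d undefined feature values imputed in-fold", task_name, n_missing)
    k = grid.k_folds
    min_class = int(pd.Series(y).value_counts().min())
    if min_class < k:
        logger.warning("task %s: smallest class has %d members; folds reduced to %d", task_name, min_class, min_class)
        k = min_class
        grid = GridSpec(grid.C_values, grid.gamma_values, k)
    best_C, best_gamma, table = grid_search_cv(X, y, grid, seed=seed)
    pipe = Pipeline(
        [
            ("impute", SimpleImputer(strategy="mean")),
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=best_C, gamma=best_gamma)),
        ]
    )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = cross_val_predict(pipe, X, y, cv=cv, n_jobs=1)
    counts, per_class, P, R, F = _aggregate(y, y_pred, sorted(set(y)))
    return ClassificationReport(
        task=task_name,
        feature_set=tuple(features),
        C=best_C,
        gamma=best_gamma,
        n=len(y),
        counts=counts,
        per_class=per_class,
        precision=P,
        recall=R,
        f_measure=F,
        cv_f_measure=float(table["cv_f_measure"].max()),
    )


def task_report_table(reports: Sequence[ClassificationReport]) -> pd.DataFrame:
    """Wide report: rows = tasks, columns = feature set x {Precision, Recall, F-Measure}."""
    rows: dict[str, dict[str, float]] = {}
    for rep in reports:
        fs = "All" if tuple(rep.feature_set) == METRIC_NAMES else "+".join(rep.feature_set)
        row = rows.setdefault(rep.task, {})
        row[f"{fs}_Precision"] = rep.precision
        row[f"{fs}_Recall"] = rep.recall
        row[f"{fs}_F-Measure"] = rep.f_measure
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    out.index.name = "task"
    return out
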