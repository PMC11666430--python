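"""Five-learner cross-validated benchmark on the selected features.

Five screening models — logistic regression (LR), k-nearest neighbours
(KNN), gradient-boosted trees (GBDT), a one-hidden-layer neural network
(NN), and a random forest (RF) — are compared by k-fold cross-validation
(default k = 5).  Within each fold the model is fitted on the k-1 training
folds (min-max normalization and hyperparameter choice both happen inside
the training folds; hyperparameters by 3-fold inner CV), and predicts the
held-out fold.  Training-partition metrics are resubstitution on the
training folds, which is what makes heavily flexible learners (GBDT, RF)
show near-perfect training panels while their held-out panels drop — the
expected overfitting signature.

The logistic model is additionally refitted on all rows to report
per-feature coefficients and odds ratios exp(beta); those odds ratios feed
the index-construction rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler

from .metrics import (
    HIGHER,
    auc_ci,
    basic_metrics,
    cohen_kappa,
    confusion,
    roc_auc,
    select_cutoff,
    wilson_ci,
    youden,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LEARNERS",
    "default_grid",
    "small_grid",
    "FoldPlan",
    "ModelResult",
    "make_folds",
    "train_eval",
    "compare_models",
    "PANEL_COLUMNS",
]

LEARNERS = ("LR", "KNN", "GBDT", "NN", "RF")

PANEL_COLUMNS = ["Auc", "Accuracy", "Precision", "Recall", "Specificity",
                 "Youden index", "Kappa coefficient", "Cutoff"]


def _estimator(name: str, seed: int):
    if name == "LR":
        return LogisticRegression(max_iter=5000, random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "GBDT":
        return GradientBoostingClassifier(random_state=seed)
    if name == "NN":
        return MLPClassifier(max_iter=2000, random_state=seed)
    if name == "RF":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown learner {name!r}; expected one of {LEARNERS}")


def default_grid(name: str) -> dict:
    """Hyperparameter grid searched by inner cross-validation."""
    grids = {
        # C = 1e6 is effectively unpenalized; C = 1 a light L2 ridge
        "LR": {"clf__C": [1e6, 1.0]},
        "KNN": {"clf__n_neighbors": [3, 5, 7, 11, 15]},
        "RF": {"clf__n_estimators": [500], "clf__max_depth": [3, 5, None]},
        "GBDT": {"clf__n_estimators": [100, 300],
                 "clf__learning_rate": [0.05, 0.1],
                 "clf__max_depth": [2, 3]},
        "NN": {"clf__hidden_layer_sizes": [(4,), (8,), (16,)]},
    }
    return grids[name]


def small_grid(name: str) -> dict:
    """Single-point grids for quick runs."""
    grids = {
        "LR": {"clf__C": [1.0]},
        "KNN": {"clf__n_neighbors": [5]},
        "RF": {"clf__n_estimators": [100], "clf__max_depth": [5]},
        "GBDT": {"clf__n_estimators": [100], "clf__learning_rate": [0.1],
                 "clf__max_depth": [2]},
        "NN": {"clf__hidden_layer_sizes": [(8,)]},
    }
    return grids[name]


@dataclass
class FoldPlan:
    """Balanced random assignment of n subjects to folds 1..k."""

    assignments: np.ndarray
    k: int
    seed: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def __len__(self) -> int:
        return len(self.assignments)


def make_folds(n: int, k: int = 5, seed: int = 0) -> FoldPlan:
    """Random partition into k folds whose sizes differ by at most one."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} subjects into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    for fold, chunk in enumerate(np.array_split(order, k), start=1):
        assignments[chunk] = fold
    return FoldPlan(assignments=assignments, k=k, seed=seed)


@dataclass
class ModelResult:
    name: str
    fold_plan: FoldPlan
    oof_scores: pd.Series            # one held-out probability per subject
    train_scores: list[pd.Series]    # resubstitution scores, one per fold
    fold_cutoffs: list[float]
    fold_params: list[dict]
    final_model: Pipeline = field(repr=False, default=None)
    final_train_scores: pd.Series = field(repr=False, default=None)
    cutoff: float = float("nan")
    coefficients: dict[str, float] | None = None
    odds_ratios: dict[str, float] | None = None
    features: list[str] = field(default_factory=list)


def _fit_one(name: str, grid: dict, X: pd.DataFrame, y: np.ndarray, seed: int):
    pipe = Pipeline([("scale", MinMaxScaler()), ("clf", _estimator(name, seed))])
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=inner, scoring="roc_auc", n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_, search.best_params_


def train_eval(learner: str, table: pd.DataFrame, features: list[str],
               folds: FoldPlan, grid: dict | None = None,
               seed: int = 0, label: str = "label") -> ModelResult:
    """Cross-validated fit/predict for one learner.

    Per fold: fit on the other folds (scaling and hyperparameter selection
    inside), predict the held-out fold and the training folds; the fold's
    screening cutoff balances sensitivity/specificity on its training
    predictions.  A final refit on all rows provides external-cohort scores,
    the reported cutoff, and (for LR) coefficients and odds ratios.
    """
    if grid is None:
        grid = default_grid(learner)
    X = table[features]
    y = table[label].to_numpy()
    if len(X) != len(folds):
        raise ValueError("fold plan size does not match table")
    oof = pd.Series(np.nan, index=table.index, name=learner)
    train_scores, fold_cutoffs, fold_params = [], [], []
    for fold in range(1, folds.k + 1):
        test_idx = folds.fold_indices(fold)
        train_idx = np.flatnonzero(folds.assignments != fold)
        y_tr = y[train_idx]
        if y_tr.min() == y_tr.max():
            raise ValueError(
                f"fold {fold}: training partition contains a single class; "
                "use a different seed"
            )
        model, params = _fit_one(learner, grid, X.iloc[train_idx], y_tr, seed)
        p_test = model.predict_proba(X.iloc[test_idx])[:, 1]
        p_train = model.predict_proba(X.iloc[train_idx])[:, 1]
        oof.iloc[test_idx] = p_test
        tr = pd.Series(p_train, index=table.index[train_idx], name=f"fold{fold}")
        train_scores.append(tr)
        fold_cutoffs.append(select_cutoff(p_train, y_tr, HIGHER))
        fold_params.append(params)
    final_model, final_params = _fit_one(learner, grid, X, y, seed)
    final_train = pd.Series(final_model.predict_proba(X)[:, 1], index=table.index)
    result = ModelResult(
        name=learner,
        fold_plan=folds,
        oof_scores=oof,
        train_scores=train_scores,
        fold_cutoffs=fold_cutoffs,
        fold_params=fold_params,
        final_model=final_model,
        final_train_scores=final_train,
        cutoff=select_cutoff(final_train.to_numpy(), y, HIGHER),
        features=list(features),
    )
    if learner == "LR":
        clf = final_model.named_steps["clf"]
        coef = clf.coef_.ravel()
        result.coefficients = dict(zip(features, coef.tolist()))
        result.odds_ratios = {f: float(np.exp(b)) for f, b in zip(features, coef)}
    return result


def _fold_metrics(scores: np.ndarray, y: np.ndarray, cutoff: float) -> dict:
    c = confusion(scores, y, cutoff, HIGHER)
    accuracy, precision, recall, specificity = basic_metrics(c)
    return {
        "Auc": roc_auc(scores, y),
        "Accuracy": accuracy,
        "Precision": precision,
        "Recall": recall,
        "Specificity": specificity,
        "Youden index": youden(recall, specificity),
        "Kappa coefficient": cohen_kappa(c),
    }


def _panel_row(per_fold: list[dict], pooled_scores: np.ndarray,
               pooled_y: np.ndarray, cutoff: float, seed: int) -> dict:
    """Fold-mean point estimates; CIs from the pooled predictions."""
    row = {k: float(np.nanmean([m[k] for m in per_fold])) for k in per_fold[0]}
    c = confusion(pooled_scores, pooled_y, cutoff, HIGHER)
    row["Auc CI"] = auc_ci(pooled_scores, pooled_y)
    row["Accuracy CI"] = wilson_ci(c.tp + c.tn, c.n)
    row["Precision CI"] = wilson_ci(c.tp, c.tp + c.fp)
    row["Recall CI"] = wilson_ci(c.tp, c.tp + c.fn)
    row["Specificity CI"] = wilson_ci(c.tn, c.tn + c.fp)
    row["Cutoff"] = cutoff
    return row


def compare_models(results: list[ModelResult], table: pd.DataFrame,
                   external: pd.DataFrame | None = None,
                   label: str = "label", seed: int = 0) -> pd.DataFrame:
    """Performance panel per learner and partition, mirroring the standard
    training / held-out (test) / external layout.

    Point estimates are means over folds; confidence intervals are computed
    on the pooled predictions of the partition.  The external partition uses
    the final refit model and its training cutoff.
    """
    plans = {id(r.fold_plan) for r in results}
    if len(plans) > 1:
        raise ValueError("all results must share one fold plan")
    y = table[label].to_numpy()
    rows = []
    for r in results:
        if external is not None:
            missing = [f for f in r.features if f not in external.columns]
            if missing:
                raise ValueError(f"external cohort missing feature(s) {missing}")
        # training partition: resubstitution on the k-1 training folds
        per_fold_train = []
        for tr, cut in zip(r.train_scores, r.fold_cutoffs):
            idx = table.index.get_indexer(tr.index)
            per_fold_train.append(_fold_metrics(tr.to_numpy(), y[idx], cut))
        pooled_tr = np.concatenate([t.to_numpy() for t in r.train_scores])
        pooled_tr_y = np.concatenate(
            [y[table.index.get_indexer(t.index)] for t in r.train_scores]
        )
        row = _panel_row(per_fold_train, pooled_tr, pooled_tr_y, r.cutoff, seed)
        rows.append({"partition": "training", "model": r.name, **row})
        # held-out partition: out-of-fold predictions at each fold's cutoff
        per_fold_test = []
        for fold in range(1, r.fold_plan.k + 1):
            idx = r.fold_plan.fold_indices(fold)
            per_fold_test.append(
                _fold_metrics(r.oof_scores.iloc[idx].to_numpy(), y[idx],
                              r.fold_cutoffs[fold - 1])
            )
        row = _panel_row(per_fold_test, r.oof_scores.to_numpy(), y, r.cutoff, seed)
        rows.append({"partition": "test", "model": r.name, **row})
        if external is not None:
            p_ext = r.final_model.predict_proba(external[r.features])[:, 1]
            y_ext = external[label].to_numpy()
            m = _fold_metrics(p_ext, y_ext, r.cutoff)
            row = _panel_row([m], p_ext, y_ext, r.cutoff, seed)
            rows.append({"partition": "external", "model": r.name, **row})
    panel = pd.DataFrame(rows).set_index(["partition", "model"])
    ordered = PANEL_COLUMNS + [c for c in panel.columns if c not in PANEL_COLUMNS]
    return panel[ordered]
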