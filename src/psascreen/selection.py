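"""Feature screening: univariate AUC, correlation exclusion, and
cross-validated L1-penalized logistic selection.

The screen mirrors a common clinical-model workflow: each candidate
variable's direction-free univariate AUC flags potential (the flag is
advisory, not a hard filter), highly correlated pairs are deduplicated by
dropping the lower-AUC member, and an L1-penalized logistic regression with
k-fold cross-validated penalty choice (minimum or one-standard-error rule)
returns the variables with nonzero coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "univariate_auc",
    "correlation_matrix",
    "lasso_select",
    "screen_features",
    "FeatureScreener",
]


@dataclass
class SelectionConfig:
    """Thresholds and cross-validation settings for the screening pipeline."""

    auc_threshold: float = 0.6
    corr_threshold: float = 0.8
    n_penalties: int = 50
    cv: int = 10
    rule: str = "1se"  # or "min"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.auc_threshold < 1:
            raise ValueError("auc_threshold must lie in (0, 1)")
        if not 0 < self.corr_threshold <= 1:
            raise ValueError("corr_threshold must lie in (0, 1]")
        if self.cv < 2:
            raise ValueError("need at least 2 CV folds")
        if self.rule not in ("min", "1se"):
            raise ValueError("rule must be 'min' or '1se'")


@dataclass
class SelectionResult:
    aucs: dict[str, float]
    flagged: list[str]
    correlation: pd.DataFrame
    dropped_correlated: list[str]
    selected: list[str]
    penalty: float
    coefficients: dict[str, float]
    path: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "aucs": self.aucs,
            "flagged": self.flagged,
            "dropped_correlated": self.dropped_correlated,
            "selected": self.selected,
            "penalty": self.penalty,
            "coefficients": self.coefficients,
        }


def univariate_auc(table: pd.DataFrame, variable: str, label: str = "label",
                   directed: bool = True) -> float:
    """AUC of one raw variable as a score for label 1.

    Pairwise concordance with ties counted 1/2.  With ``directed=False`` the
    direction-free max(AUC, 1 - AUC) used for screening is returned.
    """
    y = table[label].to_numpy()
    u = np.unique(y)
    if not (len(u) == 2 and set(u) <= {0, 1}):
        raise ValueError("both outcome classes must be present")
    x = table[variable].to_numpy(dtype=float)
    r = rankdata(x)
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    auc = (r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc if directed else max(auc, 1.0 - auc))


def correlation_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pearson correlation matrix; constant variables get 0 off-diagonal."""
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    if len(table) < 3:
        raise ValueError("need at least 3 subjects")
    sub = table[variables].astype(float)
    constant = [v for v in variables if sub[v].nunique() <= 1]
    if constant:
        logger.warning("constant variable(s) %s: correlations reported as 0", constant)
    corr = sub.corr(method="pearson").fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _one_se_choice(cs: np.ndarray, mean_score: np.ndarray, se_score: np.ndarray,
                   rule: str) -> int:
    """Index of the chosen penalty on a path of C values (larger C = weaker).

    Scores are means over folds (higher is better).  The 1-SE rule takes the
    strongest penalty (smallest C) whose mean score is within one standard
    error of the best.
    """
    best = int(np.argmax(mean_score))
    if rule == "min":
        return best
    threshold = mean_score[best] - se_score[best]
    eligible = np.flatnonzero(mean_score >= threshold)
    return int(eligible[np.argmin(cs[eligible])])


def lasso_select(table: pd.DataFrame, candidates: list[str],
                 config: SelectionConfig | None = None,
                 label: str = "label") -> SelectionResult:
    """L1-penalized logistic selection over a cross-validated penalty path.

    Expects a min-max normalized table.  Fits the full descending penalty
    path, scores each penalty by k-fold cross-validated log-loss, picks the
    penalty by the configured rule, refits at that penalty on all rows and
    returns the variables with nonzero coefficients.  An empty selection is
    a warning, not an error.
    """
    config = config or SelectionConfig()
    if not candidates:
        raise ValueError("need at least one candidate variable")
    cols = sorted(candidates)  # column-order invariance
    X = table[cols].to_numpy(dtype=float)
    y = table[label].to_numpy()
    cs = np.logspace(-3, 2, config.n_penalties)
    cv = StratifiedKFold(n_splits=config.cv, shuffle=True, random_state=config.seed)
    path_model = LogisticRegressionCV(
        Cs=cs, cv=cv, l1_ratios=(1.0,), solver="liblinear",
        scoring="neg_log_loss", refit=False, max_iter=2000,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        path_model.fit(X, y)
    scores = np.asarray(path_model.scores_[1])  # folds x Cs (x l1_ratios)
    if scores.ndim == 3:
        scores = scores[:, :, 0]
    mean_score = scores.mean(axis=0)
    se_score = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
    choice = _one_se_choice(cs, mean_score, se_score, config.rule)
    c_chosen = float(cs[choice])
    final = LogisticRegression(
        l1_ratio=1.0, C=c_chosen, solver="liblinear", max_iter=2000,
        random_state=config.seed,
    ).fit(X, y)
    coefs = dict(zip(cols, final.coef_.ravel()))
    selected = [v for v in cols if coefs[v] != 0.0]
    if not selected:
        logger.warning("no variable survives the chosen penalty (C=%.4g)", c_chosen)
    path = pd.DataFrame({
        "C": cs, "mean_cv_log_loss": -mean_score, "se": se_score,
    })
    aucs = {v: univariate_auc(table, v, label, directed=False) for v in cols}
    return SelectionResult(
        aucs=aucs,
        flagged=[v for v in cols if aucs[v] > config.auc_threshold],
        correlation=correlation_matrix(table, cols) if len(cols) > 1 else pd.DataFrame(),
        dropped_correlated=[],
        selected=selected,
        penalty=1.0 / c_chosen,
        coefficients=coefs,
        path=path,
    )


def _correlation_dedup(corr: pd.DataFrame, aucs: dict[str, float],
                       threshold: float) -> list[str]:
    """Drop the lower-AUC member of every |r| >= threshold pair."""
    dropped: list[str] = []
    active = list(corr.columns)
    while True:
        worst = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                r = abs(corr.loc[a, b])
                if r >= threshold and (worst is None or r > worst[0]):
                    worst = (r, a, b)
        if worst is None:
            break
        _, a, b = worst
        loser = a if aucs[a] < aucs[b] else b if aucs[b] < aucs[a] else max(a, b)
        dropped.append(loser)
        active.remove(loser)
    return dropped


def screen_features(table: pd.DataFrame, config: SelectionConfig | None = None,
                    candidates: list[str] | None = None,
                    label: str = "label") -> SelectionResult:
    """AUC flagging, correlation exclusion, then penalized selection.

    The AUC flag is advisory: when no variable clears the threshold the
    penalized fit still runs on the full candidate set (with a warning).
    Correlation exclusion is a hard filter: from every pair with
    |r| >= threshold the lower-AUC member is dropped before the fit.
    """
    config = config or SelectionConfig()
    if candidates is None:
        candidates = [c for c in table.columns
                      if c not in ("label", "subject_id", "cohort", label)]
    cols = sorted(candidates)
    aucs = {v: univariate_auc(table, v, label, directed=False) for v in cols}
    flagged = [v for v in cols if aucs[v] > config.auc_threshold]
    if not flagged:
        logger.warning(
            "no variable clears the univariate AUC threshold %.2f; "
            "screen is advisory, penalized fit proceeds on all candidates",
            config.auc_threshold,
        )
    corr = correlation_matrix(table, cols) if len(cols) > 1 else pd.DataFrame()
    dropped = _correlation_dedup(corr, aucs, config.corr_threshold) if len(cols) > 1 else []
    survivors = [v for v in cols if v not in dropped]
    result = lasso_select(table, survivors, config, label)
    result.aucs = aucs
    result.flagged = flagged
    result.correlation = corr
    result.dropped_correlated = dropped
    return result


class FeatureScreener(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around :func:`screen_features`.

    Fitted attributes: ``aucs_``, ``correlation_``, ``selected_features_``,
    ``penalty_``, ``result_``.  ``transform`` restricts a table to the
    selected features (metadata columns preserved).
    """

    def __init__(self, auc_threshold: float = 0.6, corr_threshold: float = 0.8,
                 n_penalties: int = 50, cv: int = 10, rule: str = "1se",
                 seed: int = 0):
        self.auc_threshold = auc_threshold
        self.corr_threshold = corr_threshold
        self.n_penalties = n_penalties
        self.cv = cv
        self.rule = rule
        self.seed = seed

    def _config(self) -> SelectionConfig:
        return SelectionConfig(
            auc_threshold=self.auc_threshold, corr_threshold=self.corr_threshold,
            n_penalties=self.n_penalties, cv=self.cv, rule=self.rule,
            seed=self.seed,
        )

    def fit(self, X: pd.DataFrame, y=None):
        table = X.copy()
        if y is not None:
            table["label"] = np.asarray(y)
        result = screen_features(table, self._config())
        self.result_ = result
        self.aucs_ = result.aucs
        self.correlation_ = result.correlation
        self.selected_features_ = list(result.selected)
        self.penalty_ = result.penalty
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_features_")
        meta = [c for c in ("subject_id", "cohort", "label") if c in X.columns]
        return X[meta + self.selected_features_]

    def get_support(self) -> list[str]:
        check_is_fitted(self, "selected_features_")
        return list(self.selected_features_)
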