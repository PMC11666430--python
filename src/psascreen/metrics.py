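"""Evaluation machinery: cutoffs, confusion metrics, AUC CIs, calibration,
decision curves, and adjusted / spline logistic association analyses.

Conventions used throughout:

* AUC is the pairwise concordance probability with ties counted 1/2
  (equivalently the trapezoidal area under the empirical ROC curve).
* Index/score classification at a cutoff uses the strict rule: positive iff
  score > cutoff (or < cutoff for lower-indicates-positive orientation);
  equality is negative.
* The screening cutoff balances sensitivity and specificity: over the
  distinct observed scores it minimises |sensitivity - specificity|, with
  ties broken by larger Youden index, then smaller threshold.
* Decision-curve classification uses probability >= threshold (the standard
  net-benefit convention), intentionally different from the index rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "roc_auc",
    "auc_ci",
    "select_cutoff",
    "confusion",
    "basic_metrics",
    "youden",
    "cohen_kappa",
    "wilson_ci",
    "evaluate_scores",
    "calibration_curve",
    "decision_curve",
    "adjusted_logistic_or",
    "rcs_basis",
    "rcs_logistic",
]

HIGHER = "higher-indicates-PSA"
LOWER = "lower-indicates-PSA"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("confusion table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    """Table-style metric panel for one score set at one cutoff."""

    auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    accuracy_ci: tuple[float, float]
    precision: float
    precision_ci: tuple[float, float]
    recall: float
    recall_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    youden: float
    kappa: float
    kappa_ci: tuple[float, float]
    cutoff: float
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        d = {}
        for k in ("auc", "accuracy", "precision", "recall", "specificity",
                  "youden", "kappa", "cutoff"):
            d[k] = getattr(self, k)
        for k in ("auc_ci", "accuracy_ci", "precision_ci", "recall_ci",
                  "specificity_ci", "kappa_ci"):
            lo, hi = getattr(self, k)
            d[k] = [lo, hi]
        if self.counts is not None:
            d["counts"] = {"tp": self.counts.tp, "fp": self.counts.fp,
                           "tn": self.counts.tn, "fn": self.counts.fn}
        return d


def _check_two_classes(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if not (len(u) == 2 and set(u) <= {0, 1}):
        raise ValueError("labels must contain both classes 0 and 1")


def roc_auc(scores, labels) -> float:
    """Pairwise-concordance AUC (ties 1/2) via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    r = rankdata(scores)
    n_pos = int((labels == 1).sum())
    n_neg = len(labels) - n_pos
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong structural-components variance."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    tz = rankdata(np.concatenate([x, y]))
    tx = rankdata(x)
    ty = rankdata(y)
    v01 = (tz[:m] - tx) / n          # placement of each positive among negatives
    v10 = 1.0 - (tz[m:] - ty) / m    # placement of each negative among positives
    auc = float(v01.mean())
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return auc, s01 / m + s10 / n


def auc_ci(scores, labels, method: str = "delong", level: float = 0.95,
           seed: int = 0, n_boot: int = 1000) -> tuple[float, float]:
    """Two-sided AUC confidence interval, clipped to [0, 1].

    ``delong`` uses the structural-components variance estimator; ``bootstrap``
    the percentile interval over stratified resamples.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    if method == "delong":
        auc, var = _delong_variance(scores, labels)
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(max(var, 0.0))
        return (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))
    if method == "bootstrap":
        if n_boot < 1000:
            raise ValueError("bootstrap requires at least 1000 resamples")
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            ip = rng.choice(pos, size=len(pos), replace=True)
            ineg = rng.choice(neg, size=len(neg), replace=True)
            idx = np.concatenate([ip, ineg])
            aucs[b] = roc_auc(scores[idx], labels[idx])
        alpha = 1 - level
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
        return (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))
    raise ValueError(f"unknown CI method {method!r}")


def _sens_spec(scores: np.ndarray, labels: np.ndarray, cutoff: float,
               orientation: str) -> tuple[float, float]:
    if orientation == HIGHER:
        pred = scores > cutoff
    else:
        pred = scores < cutoff
    pos = labels == 1
    sens = pred[pos].mean() if pos.any() else np.nan
    spec = (~pred[~pos]).mean() if (~pos).any() else np.nan
    return float(sens), float(spec)


def select_cutoff(scores, labels, orientation: str = HIGHER) -> float:
    """Cutoff balancing sensitivity and specificity.

    Candidates are the distinct observed scores.  The winner minimises
    |sens - spec|; ties go to the larger Youden index, then the smaller
    threshold.  Degenerate inputs (all scores equal) return the single
    candidate with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) == 0:
        raise ValueError("empty scores")
    _check_two_classes(labels)
    candidates = np.unique(scores)
    best = None
    for c in candidates:
        sens, spec = _sens_spec(scores, labels, c, orientation)
        key = (abs(sens - spec), -(sens + spec - 1.0), c)
        if best is None or key < best[0]:
            best = (key, c)
    if len(candidates) == 1:
        logger.warning("degenerate score distribution: single candidate cutoff")
    return float(best[1])


def confusion(scores, labels, cutoff: float, orientation: str = HIGHER) -> ConfusionCounts:
    """Confusion counts at a cutoff under the strict classification rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) == 0:
        raise ValueError("empty scores")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = scores > cutoff if orientation == HIGHER else scores < cutoff
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def _ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting NaN", what)
        return float("nan")
    return num / den


def basic_metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, specificity) from a confusion table."""
    accuracy = (c.tp + c.tn) / c.n
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    return accuracy, precision, recall, specificity


def youden(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def cohen_kappa(c: ConfusionCounts) -> float:
    """Chance-corrected agreement between screening calls and true labels."""
    n = c.n
    p_o = (c.tp + c.tn) / n
    p_yes = ((c.tp + c.fp) / n) * ((c.tp + c.fn) / n)
    p_no = ((c.tn + c.fn) / n) * ((c.tn + c.fp) / n)
    p_e = p_yes + p_no
    if p_e == 1.0:
        logger.warning("degenerate marginals (p_e = 1); reporting kappa 0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def wilson_ci(count: int, nobs: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a proportion; (nan, nan) when undefined."""
    if nobs == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(count, nobs, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def _kappa_bootstrap_ci(scores, labels, cutoff, orientation, level, seed, n_boot=1000):
    rng = np.random.default_rng(seed)
    n = len(scores)
    kappas = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if lab.min() == lab.max():
            kappas[b] = np.nan
            continue
        kappas[b] = cohen_kappa(confusion(scores[idx], lab, cutoff, orientation))
    alpha = 1 - level
    lo, hi = np.nanquantile(kappas, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def evaluate_scores(scores, labels, cutoff: float | None = None,
                    orientation: str = HIGHER, ci_method: str = "delong",
                    level: float = 0.95, seed: int = 0) -> EvaluationReport:
    """Full metric panel (AUC+CI, accuracy/precision/recall/specificity with
    Wilson CIs, Youden, kappa with bootstrap CI, cutoff) for one score set.

    When ``cutoff`` is None it is selected on these scores (training-style
    evaluation); pass the training cutoff for held-out/external panels.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    if cutoff is None:
        cutoff = select_cutoff(scores, labels, orientation)
    c = confusion(scores, labels, cutoff, orientation)
    accuracy, precision, recall, specificity = basic_metrics(c)
    auc = roc_auc(scores if orientation == HIGHER else -scores, labels)
    return EvaluationReport(
        auc=auc,
        auc_ci=auc_ci(scores if orientation == HIGHER else -scores, labels,
                      method=ci_method, level=level, seed=seed),
        accuracy=accuracy,
        accuracy_ci=wilson_ci(c.tp + c.tn, c.n, level),
        precision=precision,
        precision_ci=wilson_ci(c.tp, c.tp + c.fp, level),
        recall=recall,
        recall_ci=wilson_ci(c.tp, c.tp + c.fn, level),
        specificity=specificity,
        specificity_ci=wilson_ci(c.tn, c.tn + c.fp, level),
        youden=youden(recall, specificity),
        kappa=cohen_kappa(c),
        kappa_ci=_kappa_bootstrap_ci(scores, labels, cutoff, orientation, level, seed),
        cutoff=float(cutoff),
        counts=c,
    )


def calibration_curve(probabilities, labels, bins: int = 10) -> pd.DataFrame:
    """Mean predicted probability vs observed event rate in equal-width bins."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    rows = []
    for b in range(bins):
        sel = idx == b
        if not sel.any():
            continue
        rows.append({
            "mean_predicted": float(p[sel].mean()),
            "observed_rate": float(y[sel].mean()),
            "count": int(sel.sum()),
        })
    return pd.DataFrame(rows)


def decision_curve(probabilities, labels, thresholds) -> pd.DataFrame:
    """Net benefit NB(t) = TP/n - (FP/n) * t/(1-t), with treat-all/none refs.

    Classification at each threshold probability t is positive iff
    probability >= t.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(p)
    prevalence = y.mean()
    rows = []
    for t in thresholds:
        pred = p >= t
        tp = float((pred & (y == 1)).sum())
        fp = float((pred & (y == 0)).sum())
        odds = t / (1 - t)
        rows.append({
            "threshold": float(t),
            "net_benefit": tp / n - (fp / n) * odds,
            "treat_all": prevalence - (1 - prevalence) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


def _logit_fit(X: np.ndarray, y: np.ndarray):
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise PerfectSeparationError("logit did not converge")
            return res, False
        except (PerfectSeparationError, np.linalg.LinAlgError):
            logger.warning("separation detected; refitting with an L2 penalty")
            res = model.fit_regularized(
                method="l1", alpha=np.full(X.shape[1], 1e-4), disp=0, maxiter=500
            )
            return res, True


def adjusted_logistic_or(table: pd.DataFrame, exposure: str,
                         covariates: list[str], label: str = "label",
                         level: float = 0.95) -> dict:
    """Covariate-adjusted odds ratio per unit of a continuous exposure.

    Maximum-likelihood logistic fit of the label on exposure + covariates;
    returns exp of the exposure coefficient with a Wald interval and p-value.
    Constant covariates are dropped with a warning; separation triggers a
    penalized refit (flagged in the output).
    """
    keep = []
    for cov in covariates:
        if table[cov].nunique() <= 1:
            logger.warning("covariate %r is constant; dropped", cov)
        else:
            keep.append(cov)
    cols = [exposure] + keep
    X = sm.add_constant(table[cols].to_numpy(dtype=float))
    y = table[label].to_numpy(dtype=float)
    res, penalized = _logit_fit(X, y)
    beta = res.params[1]
    se = np.asarray(res.bse)[1] if hasattr(res, "bse") else np.nan
    z = stats.norm.ppf(0.5 + level / 2)
    return {
        "or": float(np.exp(beta)),
        "ci": (float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        "p": float(res.pvalues[1]) if hasattr(res, "pvalues") else float("nan"),
        "beta": float(beta),
        "covariates": keep,
        "penalized": penalized,
    }


_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (linear term excluded).

    Returns the k-2 nonlinear basis columns of the natural cubic spline with
    the given knots: linear beyond the boundary knots, continuous second
    derivative, normalized by (t_k - t_1)^2.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.maximum(u, 0.0) ** 3

    cols = []
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def rcs_logistic(table: pd.DataFrame, exposure: str, covariates: list[str],
                 knots: int = 4, label: str = "label",
                 grid: np.ndarray | None = None) -> dict:
    """Adjusted dose-response curve for an exposure via restricted cubic splines.

    Fits label ~ rcs(exposure) + covariates, normalizes the curve to OR = 1
    at the exposure median, and tests nonlinearity by a likelihood-ratio
    comparison against the linear-exposure model.
    """
    if knots not in _KNOT_QUANTILES:
        raise ValueError(f"knots must be one of {sorted(_KNOT_QUANTILES)}")
    x = table[exposure].to_numpy(dtype=float)
    if len(np.unique(x)) < knots:
        raise ValueError("exposure has fewer distinct values than knots")
    knot_pos = np.quantile(x, _KNOT_QUANTILES[knots])
    y = table[label].to_numpy(dtype=float)
    covs = table[covariates].to_numpy(dtype=float) if covariates else np.empty((len(x), 0))

    spline = rcs_basis(x, knot_pos)
    X_full = sm.add_constant(np.column_stack([x, spline, covs]))
    X_lin = sm.add_constant(np.column_stack([x, covs]))
    res_full, _ = _logit_fit(X_full, y)
    res_lin, _ = _logit_fit(X_lin, y)
    lr = 2 * (res_full.llf - res_lin.llf)
    p_nonlinear = float(stats.chi2.sf(max(lr, 0.0), df=knots - 2))

    if grid is None:
        grid = np.linspace(np.quantile(x, 0.01), np.quantile(x, 0.99), 100)
    grid = np.asarray(grid, dtype=float)
    ref = float(np.median(x))
    basis_grid = np.column_stack([grid, rcs_basis(grid, knot_pos)])
    basis_ref = np.column_stack([[ref], rcs_basis(np.array([ref]), knot_pos)])
    beta = np.asarray(res_full.params)[1:1 + 1 + (knots - 2)]
    log_or = basis_grid @ beta - (basis_ref @ beta)[0]
    return {
        "grid": grid,
        "odds_ratio": np.exp(log_or),
        "reference": ref,
        "knots": knot_pos,
        "p_nonlinear": p_nonlinear,
        "lr_statistic": float(lr),
    }
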