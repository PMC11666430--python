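"""Evaluation metrics against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from psascreen.metrics import (
    HIGHER,
    LOWER,
    ConfusionCounts,
    adjusted_logistic_or,
    auc_ci,
    basic_metrics,
    calibration_curve,
    cohen_kappa,
    confusion,
    decision_curve,
    evaluate_scores,
    rcs_basis,
    rcs_logistic,
    roc_auc,
    select_cutoff,
    youden,
)


def brute_force_auc(scores, labels):
    """All-pairs concordance with ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def brute_force_cutoff(scores, labels, orientation=HIGHER):
    """Exhaustive enumeration over observed-score candidates."""
    best = None
    for c in sorted(set(scores)):
        pred = [(s > c) if orientation == HIGHER else (s < c) for s in scores]
        pos = [p for p, y in zip(pred, labels) if y == 1]
        neg = [p for p, y in zip(pred, labels) if y == 0]
        sens = sum(pos) / len(pos)
        spec = sum(not p for p in neg) / len(neg)
        key = (abs(sens - spec), -(sens + spec - 1.0), c)
        if best is None or key < best[0]:
            best = (key, c)
    return best[1]


class TestRocAuc:
    def test_scores_equal_labels(self):
        assert roc_auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_four_pair_example(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    def test_matches_brute_force_and_sklearn(self, rng):
        for _ in range(100):
            n = rng.integers(4, 31)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.2, 0.5, 0.7, 1.3], size=n)
            got = roc_auc(scores, labels)
            assert got == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert got == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestAucCi:
    def test_perfect_separation_clipped(self):
        labels = np.r_[np.zeros(20), np.ones(20)]
        scores = np.r_[np.zeros(20), np.ones(20)]
        lo, hi = auc_ci(scores, labels, method="bootstrap", seed=1)
        assert hi == 1.0

    def test_delong_bootstrap_agree_on_large_sample(self, rng):
        n = 1500
        labels = np.r_[np.zeros(n), np.ones(n)]
        scores = np.r_[rng.normal(0, 1, n), rng.normal(1, 1, n)]
        d_lo, d_hi = auc_ci(scores, labels, method="delong")
        b_lo, b_hi = auc_ci(scores, labels, method="bootstrap", seed=2)
        assert max(d_lo, b_lo) < min(d_hi, b_hi)  # intervals overlap
        assert abs(d_lo - b_lo) < 0.02 and abs(d_hi - b_hi) < 0.02

    def test_bootstrap_requires_1000_resamples(self):
        with pytest.raises(ValueError, match="1000"):
            auc_ci([0, 1], [0, 1], method="bootstrap", n_boot=10)


class TestSelectCutoff:
    def test_separable_returns_smallest_balancing_candidate(self):
        cut = select_cutoff([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert cut == 0.2

    def test_small_example_by_enumeration(self):
        # candidates {1,2,3,5,6,9}: cutoff 3 balances sens=spec=2/3 exactly
        scores = [3, 5, 9, 1, 2, 6]
        labels = [1, 1, 1, 0, 0, 0]
        cut = select_cutoff(scores, labels)
        assert cut == brute_force_cutoff(scores, labels) == 3

    def test_degenerate_scores_return_single_candidate(self):
        assert select_cutoff([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1]) == 2.0

    def test_matches_enumeration_oracle(self, rng):
        for trial in range(200):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)
            orientation = HIGHER if trial % 2 == 0 else LOWER
            assert select_cutoff(scores, labels, orientation) == \
                brute_force_cutoff(scores.tolist(), labels.tolist(), orientation)


class TestConfusionAndMetrics:
    def test_strict_rule_counts(self):
        c = confusion([20, 15, 5, 19], [1, 1, 0, 0], cutoff=18)
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_empty_scores_error(self):
        with pytest.raises(ValueError):
            confusion([], [], cutoff=1.0)

    def test_basic_metrics_hand_example(self):
        acc, prec, rec, spec = basic_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert acc == pytest.approx(0.8)
        assert prec == pytest.approx(0.75)
        assert rec == pytest.approx(0.75)
        assert spec == pytest.approx(5 / 6)

    def test_perfect_table(self):
        assert basic_metrics(ConfusionCounts(tp=4, fp=0, tn=6, fn=0)) == (1, 1, 1, 1)

    def test_undefined_precision_flagged_nan(self):
        _, prec, _, _ = basic_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=2))
        assert np.isnan(prec)

    @pytest.mark.parametrize("sens,spec,expected", [
        (1, 1, 1), (0.5, 0.5, 0.0), (0.78, 0.81, 0.59),
    ])
    def test_youden(self, sens, spec, expected):
        assert youden(sens, spec) == pytest.approx(expected)

    def test_kappa_hand_examples(self):
        assert cohen_kappa(ConfusionCounts(tp=10, fp=0, tn=10, fn=0)) == 1.0
        assert cohen_kappa(ConfusionCounts(tp=25, fp=25, tn=25, fn=25)) == 0.0
        assert cohen_kappa(ConfusionCounts(tp=30, fn=10, fp=20, tn=40)) == \
            pytest.approx(0.4)

    def test_metrics_agree_with_independent_recomputation(self, rng):
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(0, 50, 4)
            if tp + fp + tn + fn == 0:
                continue
            c = ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
            n = c.n
            acc, prec, rec, spec = basic_metrics(c)
            assert acc == pytest.approx((tp + tn) / n, abs=1e-12)
            if tp + fp:
                assert prec == pytest.approx(tp / (tp + fp), abs=1e-12)
            if tp + fn and tn + fp:
                assert youden(rec, spec) == pytest.approx(
                    tp / (tp + fn) + tn / (tn + fp) - 1, abs=1e-12)
            # kappa against sklearn on an expanded prediction vector
            y_true = [1] * (tp + fn) + [0] * (tn + fp)
            y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
            if len(set(y_true)) == 2 or len(set(y_pred)) == 2:
                expected = cohen_kappa_score(y_true, y_pred)
                assert cohen_kappa(c) == pytest.approx(expected, abs=1e-12)


class TestCalibration:
    def test_well_calibrated_probabilities(self, rng):
        p = rng.random(100_000)
        y = rng.random(100_000) < p
        curve = calibration_curve(p, y.astype(int), bins=10)
        assert curve["count"].sum() == 100_000
        assert (curve["mean_predicted"] - curve["observed_rate"]).abs().max() < 0.02

    def test_all_zero(self):
        curve = calibration_curve([0.0, 0.0], [0, 0])
        assert len(curve) == 1
        assert curve.iloc[0]["mean_predicted"] == 0.0
        assert curve.iloc[0]["observed_rate"] == 0.0

    def test_constant_half(self, rng):
        y = rng.integers(0, 2, 10_000)
        curve = calibration_curve(np.full(10_000, 0.5), y)
        assert len(curve) == 1
        assert curve.iloc[0]["observed_rate"] == pytest.approx(y.mean())


class TestDecisionCurve:
    def test_formula_arithmetic(self):
        p = np.r_[np.full(30, 0.9), np.full(20, 0.9), np.full(50, 0.1)]
        y = np.r_[np.ones(30), np.zeros(20), np.zeros(50)]
        out = decision_curve(p, y, [0.25])
        assert out["net_benefit"].iloc[0] == pytest.approx(0.3 - 0.2 * (1 / 3))

    def test_everyone_positive_at_tiny_threshold(self, rng):
        y = rng.integers(0, 2, 1000)
        out = decision_curve(np.ones(1000), y, [1e-6])
        assert out["net_benefit"].iloc[0] == pytest.approx(y.mean(), abs=1e-4)

    def test_no_positive_predictions(self):
        out = decision_curve(np.zeros(100), np.r_[np.ones(30), np.zeros(70)],
                             [0.1, 0.5, 0.9])
        assert (out["net_benefit"] == 0).all()
        assert (out["treat_none"] == 0).all()

    def test_treat_all_crosses_zero_at_prevalence(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        out = decision_curve(np.ones(100), y, [0.3])
        assert out["treat_all"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_threshold_outside_unit_interval(self):
        with pytest.raises(ValueError):
            decision_curve([0.5], [1], [1.5])


class TestEvaluateScores:
    def test_report_invariants(self, small_study):
        nhanes, _ = small_study
        from psascreen.indices import compute_index, get_index

        scores = compute_index(get_index("PSAII"), nhanes).to_numpy()
        rep = evaluate_scores(scores, nhanes["label"].to_numpy(), seed=0)
        for rate in (rep.accuracy, rep.recall, rep.specificity, rep.auc):
            assert 0 <= rate <= 1
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
        assert -1 <= rep.kappa <= 1
        assert rep.counts.n == len(nhanes)


class TestAdjustedLogistic:
    def test_null_exposure_covers_one(self):
        covered = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 10_000
            x = rng.normal(size=n)
            z = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(-1 + 0.5 * z)))
            y = (rng.random(n) < p).astype(int)
            df = pd.DataFrame({"label": y, "x": x, "z": z})
            out = adjusted_logistic_or(df, "x", ["z"])
            covered += out["ci"][0] <= 1.0 <= out["ci"][1]
        assert covered >= 18  # ≥90% of 20 null runs

    def test_recovers_planted_log_odds(self):
        rng = np.random.default_rng(123)
        n = 10_000
        x = rng.normal(10, 5, n)
        z = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-2 + 0.1 * x + 0.3 * z)))
        y = (rng.random(n) < p).astype(int)
        df = pd.DataFrame({"label": y, "x": x, "z": z})
        out = adjusted_logistic_or(df, "x", ["z"])
        assert out["beta"] == pytest.approx(0.1, abs=0.02)

    def test_constant_covariate_dropped(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"label": rng.integers(0, 2, 200),
                           "x": rng.normal(size=200),
                           "c": np.ones(200)})
        out = adjusted_logistic_or(df, "x", ["c"])
        assert out["covariates"] == []


class TestRcsLogistic:
    def test_basis_is_linear_beyond_boundary_knots(self):
        knots = [0.0, 1.0, 2.0, 3.0]
        x = np.linspace(4, 8, 50)
        basis = rcs_basis(x, knots)
        # beyond the last knot every column is affine in x
        for j in range(basis.shape[1]):
            slopes = np.diff(basis[:, j]) / np.diff(x)
            assert np.allclose(slopes, slopes[0], atol=1e-8)

    def test_reference_or_is_one(self, small_study):
        nhanes, _ = small_study
        from psascreen.indices import compute_index, get_index

        df = nhanes.copy()
        df["psaii"] = compute_index(get_index("PSAII"), nhanes)
        ref = float(df["psaii"].median())
        out = rcs_logistic(df, "psaii", ["age", "sex"], knots=4,
                           grid=np.array([ref / 2, ref, ref * 2]))
        assert out["reference"] == ref
        assert out["odds_ratio"][1] == pytest.approx(1.0, abs=1e-12)

    def test_null_nonlinearity_not_systematically_rejected(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            x = rng.normal(size=n)
            p = 1 / (1 + np.exp(-(0.8 * x)))
            y = (rng.random(n) < p).astype(int)
            df = pd.DataFrame({"label": y, "x": x})
            out = rcs_logistic(df, "x", [], knots=4)
            rejections += out["p_nonlinear"] < 0.05
        assert rejections <= 4

    def test_monotone_generator_gives_increasing_curve(self):
        rng = np.random.default_rng(77)
        n = 4000
        x = rng.lognormal(1.0, 1.0, n)
        p = 1 / (1 + np.exp(-(-2 + 0.4 * np.log(x + 1))))
        y = (rng.random(n) < p).astype(int)
        df = pd.DataFrame({"label": y, "x": x})
        out = rcs_logistic(df, "x", [], knots=4)
        grid, curve = out["grid"], out["odds_ratio"]
        inner = (grid >= np.quantile(x, 0.05)) & (grid <= np.quantile(x, 0.95))
        assert (np.diff(curve[inner]) > -1e-6).all()

    def test_too_few_distinct_values(self):
        df = pd.DataFrame({"label": [0, 1, 0, 1], "x": [1.0, 1.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="distinct"):
            rcs_logistic(df, "x", [], knots=4)
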