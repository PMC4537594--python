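"""Serum statistics and panel-model tests against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from ionpanel import synth
from ionpanel.panel import (
    DEFAULT_LAMBDA_GRID,
    PanelModel,
    alpha_sensitivity,
    bootstrap_validate,
    correlate_score_covariate,
    evaluate_panel,
    finalize_panel,
    fit_penalized_logistic,
    roc_auc,
    select_penalty_bootstrap,
    sensitivity_at_specificity,
    serum_plasma_concordance,
    summarize_marker,
)

MARKERS = list(synth.MARKER_NAMES)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def allpairs_auc(scores, labels):
    """(#concordant + 0.5 * #ties) / (n1 * n0) over every case-control pair."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def ks_bruteforce(a, b):
    """Supremum ECDF difference over every evaluation point."""
    pts = np.concatenate([a, b])
    return max(
        abs((a <= t).mean() - (b <= t).mean()) for t in pts
    )


def newton_logistic(X, y, ridge=0.0, iters=200):
    """IRLS for (optionally ridge-penalized) logistic regression; intercept free."""
    Z = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Z.shape[1])
    P = np.eye(Z.shape[1]) * ridge
    P[0, 0] = 0.0
    for _ in range(iters):
        p = expit(Z @ beta)
        g = Z.T @ (y - p) - P @ beta
        W = p * (1 - p)
        H = (Z * W[:, None]).T @ Z + P
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


# ---------------------------------------------------------------------------
# Marker summaries / ROC
# ---------------------------------------------------------------------------

class TestMarkerSummary:
    def test_identical_groups(self, rng):
        vals = rng.uniform(size=50)
        s = summarize_marker(vals, vals.copy())
        assert s.ks_statistic == pytest.approx(0.0, abs=1e-12)
        assert s.auc == pytest.approx(0.5)

    def test_disjoint_supports(self, rng):
        s = summarize_marker(rng.uniform(10, 11, 30), rng.uniform(0, 1, 40))
        assert s.ks_statistic == pytest.approx(1.0)
        assert s.auc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_ks_matches_bruteforce_ecdf(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=8), rng.normal(0.5, 1.2, size=8)
        s = summarize_marker(a, b)
        assert s.ks_statistic == pytest.approx(ks_bruteforce(a, b), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_marker(np.array([]), np.array([1.0]))


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1]))
        assert roc.auc == pytest.approx(1.0)

    def test_interleaved_hand_value(self):
        roc = roc_auc(np.array([1, 2, 3, 4.0]), np.array([0, 1, 0, 1]))
        assert roc.auc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_allpairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels).auc == pytest.approx(
            allpairs_auc(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_curve_monotone(self, rng):
        roc = roc_auc(rng.normal(size=100), rng.integers(0, 2, 100))
        assert (np.diff(roc.sensitivity) >= 0).all()
        assert (np.diff(roc.specificity) <= 0).all()

    def test_permutation_null_mean_near_half(self, rng):
        scores = rng.normal(size=100)
        labels = np.r_[np.ones(40, int), np.zeros(60, int)]
        aucs = []
        for _ in range(200):
            perm = rng.permutation(labels)
            aucs.append(roc_auc(scores, perm).auc)
        assert 0.45 < np.mean(aucs) < 0.55


class TestSensitivityAtSpecificity:
    def test_perfect_separation_everywhere(self):
        roc = roc_auc(np.array([1, 2, 10, 11.0]), np.array([0, 0, 1, 1]))
        for target in (0.1, 0.5, 0.9):
            assert sensitivity_at_specificity(roc, target) == 1.0

    def test_chance_line_at_large_n(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, 4000)
        roc = roc_auc(scores, labels)
        assert sensitivity_at_specificity(roc, 0.9) == pytest.approx(0.1, abs=0.03)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_threshold_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=6), 1)
        labels = np.array([0, 0, 0, 1, 1, 1])
        roc = roc_auc(scores, labels)
        target = 0.6
        # scan every threshold: classify score >= t as positive
        best = 0.0
        for t in np.unique(scores):
            sens = (scores[labels == 1] >= t).mean()
            spec = (scores[labels == 0] < t).mean()
            if spec >= target:
                best = max(best, sens)
        assert sensitivity_at_specificity(roc, target) == pytest.approx(best)


# ---------------------------------------------------------------------------
# Penalized logistic regression
# ---------------------------------------------------------------------------

class TestPenalizedFit:
    def test_unpenalized_matches_newton_oracle(self, rng):
        n = 120
        X = rng.normal(size=(n, 3))
        y = (rng.uniform(size=n) < expit(X @ [1.0, -0.5, 0.2] + 0.3)).astype(int)
        fit = fit_penalized_logistic(X, y, lam=0.0, tol=1e-12)
        beta = newton_logistic(X, y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-6)
        assert np.allclose(fit.coef, beta[1:], atol=1e-6)

    def test_heavy_penalty_gives_intercept_only_model(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        fit = fit_penalized_logistic(X, y, lam=1e6)
        assert np.all(fit.coef == 0.0)
        assert fit.intercept == pytest.approx(logit(y.mean()), abs=1e-9)

    def test_ridge_matches_penalized_newton_oracle(self, rng):
        # alpha = 0: objective is NLL + lam/2 * ||beta_std||^2 on the
        # standardized design; compare in that parameterization
        n = 200
        X = rng.normal(size=(n, 2))
        y = (rng.uniform(size=n) < expit(X @ [0.8, -0.6])).astype(int)
        lam = 3.0
        fit = fit_penalized_logistic(X, y, lam=lam, alpha=0.0, tol=1e-12)
        Xs = (X - X.mean(0)) / X.std(0)
        beta = newton_logistic(Xs, y, ridge=lam)
        assert np.allclose(fit.coef_std, beta[1:], atol=1e-6)

    def test_zero_variance_column_dropped(self, rng):
        X = np.column_stack([rng.normal(size=50), np.full(50, 7.0)])
        y = (X[:, 0] > 0).astype(int)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_penalized_logistic(X, y, lam=1.0)
        assert fit.coef[1] == 0.0

    def test_l1_norm_monotone_along_path(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        norms = [
            np.abs(fit_penalized_logistic(X, y, lam, 0.5).coef_std).sum()
            for lam in DEFAULT_LAMBDA_GRID
        ]
        assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))


class TestPenaltySelection:
    def test_oob_fraction_matches_closed_form(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        n = len(y)
        sel = select_penalty_bootstrap(
            X, y, lambda_grid=np.array([50.0]), n_bootstrap=1000, seed=2
        )
        # a subject is out-of-bag with probability (1 - 1/n)^n, so the
        # unique in-bag coverage is the complementary 1 - (1 - 1/n)^n
        expected_oob = (1.0 - 1.0 / n) ** n
        assert sel.mean_oob_fraction == pytest.approx(expected_oob, abs=0.01)
        assert 1.0 - sel.mean_oob_fraction == pytest.approx(
            1.0 - (1.0 - 1.0 / n) ** n, abs=0.01
        )

    def test_huge_lambda_gives_chance_oob_auc(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        sel = select_penalty_bootstrap(
            X, y, lambda_grid=np.array([1e6]), n_bootstrap=50, seed=3
        )
        assert sel.mean_oob_auc[0] == pytest.approx(0.5, abs=1e-9)

    def test_reproducible_given_seed(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        grid = np.array([1.0, 10.0])
        a = select_penalty_bootstrap(X, y, grid, n_bootstrap=30, seed=7)
        b = select_penalty_bootstrap(X, y, grid, n_bootstrap=30, seed=7)
        assert a.chosen_lambda == b.chosen_lambda
        assert np.array_equal(a.mean_oob_auc, b.mean_oob_auc)

    def test_empty_grid_rejected(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        with pytest.raises(ValueError):
            select_penalty_bootstrap(X, y, np.array([]), n_bootstrap=5)


class TestFinalPanel:
    def test_separable_toy_retains_both_markers(self):
        rng = np.random.default_rng(0)
        n = 40
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        X = np.column_stack([y * 4 + rng.normal(0, 0.3, 2 * n),
                             y * 3 + rng.normal(0, 0.3, 2 * n)])
        sel = select_penalty_bootstrap(X, y, np.array([0.5]), n_bootstrap=20, seed=1)
        model = finalize_panel(X, y, sel, 0.5, ["m1", "m2"])
        assert model.included_markers == ["m1", "m2"]
        assert roc_auc(model.score(X), y).auc == pytest.approx(1.0)

    def test_duplicated_marker_leaves_scores_stable(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        lam = 5.0
        single = fit_penalized_logistic(X, y, lam, 0.5, tol=1e-10)
        Xdup = np.column_stack([X, X[:, 0]])
        dup = fit_penalized_logistic(Xdup, y, lam, 0.5, tol=1e-10)
        s1 = X @ single.coef + single.intercept
        s2 = Xdup @ dup.coef + dup.intercept
        assert np.corrcoef(s1, s2)[0, 1] > 0.999
        assert np.allclose(s1, s2, atol=0.05 * s1.std())

    def test_serialization_round_trip_bit_exact(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        sel = select_penalty_bootstrap(X, y, np.array([2.0]), n_bootstrap=10, seed=4)
        model = finalize_panel(X, y, sel, 0.5, MARKERS)
        restored = PanelModel.from_json(model.to_json())
        assert np.array_equal(model.score(X), restored.score(X))

    def test_all_zero_model_rejected(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        sel = select_penalty_bootstrap(X, y, np.array([1e6]), n_bootstrap=5, seed=5)
        with pytest.raises(ValueError, match="degenerate"):
            finalize_panel(X, y, sel, 0.5, MARKERS)

    def test_sign_recovery_at_study_size(self):
        # markers at published-calibration marginals plus a known linear
        # log-odds signal: fitted signs must match the truth in >= 95 % of runs
        hits = trials = 0
        beta_true = np.array([0.8, 0.7, 0.6, 0.5, 0.6, 0.7, 0.9, 0.5])
        for run in range(20):
            rng = np.random.default_rng(200 + run)
            params = synth.default_marker_params()
            z = rng.standard_normal((283, 8))
            eta = z @ beta_true
            y = (rng.uniform(size=283) < expit(eta - eta.mean())).astype(int)
            X = np.column_stack(
                [
                    np.exp(mu + sigma * z[:, j])
                    for j, (mu, sigma) in enumerate(
                        params[m]["control"] for m in MARKERS[:8]
                    )
                ]
            )
            fit = fit_penalized_logistic(X, y, lam=1.0, alpha=0.5)
            trials += 1
            hits += int(np.all(np.sign(fit.coef_std) == 1.0))
        assert hits >= 19


class TestBootstrapValidation:
    def test_optimism_corrected_auc_below_apparent(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        fit = fit_penalized_logistic(X, y, 1.0, 0.5)
        apparent = roc_auc(fit.decision(X), y).auc
        validated = bootstrap_validate(X, y, 1.0, 0.5, n_bootstrap=30, seed=6)
        assert 0.5 < validated <= apparent + 0.01


class TestEvaluation:
    def test_training_evaluation_is_definitional(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        sel = select_penalty_bootstrap(X, y, np.array([1.0]), n_bootstrap=10, seed=8)
        model = finalize_panel(X, y, sel, 0.5, MARKERS)
        rep = evaluate_panel(model, small_cohort)
        assert rep["auc"] == pytest.approx(roc_auc(model.score(small_cohort), y).auc)

    def test_all_controls_subgroup_equals_overall(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        sel = select_penalty_bootstrap(X, y, np.array([1.0]), n_bootstrap=10, seed=9)
        model = finalize_panel(X, y, sel, 0.5, MARKERS)
        rep = evaluate_panel(
            model, small_cohort, subgroups={"all": (y == 0)}
        )
        assert rep["subgroup_auc"]["all"] == pytest.approx(rep["auc"])

    def test_binormal_prediction(self):
        # one log-normal marker with known case shift: AUC has the closed
        # form Phi(delta_mu / sqrt(s1^2 + s0^2)) on the log scale
        from scipy.stats import norm
        rng = np.random.default_rng(10)
        mu0, s0, mu1, s1 = 0.0, 1.0, 0.9, 1.0
        n = 4000
        x = np.r_[np.exp(mu0 + s0 * rng.standard_normal(n)),
                  np.exp(mu1 + s1 * rng.standard_normal(n))]
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        predicted = norm.cdf((mu1 - mu0) / np.hypot(s0, s1))
        assert roc_auc(x, y).auc == pytest.approx(predicted, abs=0.02)


class TestCorrelations:
    def test_self_and_anti_correlation(self, rng):
        s = rng.normal(size=20)
        assert correlate_score_covariate(s, s)[0] == pytest.approx(1.0)
        assert correlate_score_covariate(s, -s)[0] == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        s = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        c = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        num = ((s - s.mean()) * (c - c.mean())).sum()
        den = np.sqrt(((s - s.mean()) ** 2).sum() * ((c - c.mean()) ** 2).sum())
        r, _ = correlate_score_covariate(s, c)
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            correlate_score_covariate(rng.normal(size=10), np.full(10, 3.0))

    def test_concordance_perfect_and_null(self):
        perfect = synth.generate_paired_serum_plasma(12, 0.0, seed=1)
        r = serum_plasma_concordance(perfect)
        assert np.allclose(r, 1.0)
        rng = np.random.default_rng(2)
        rows = []
        for m in ("A", "B"):
            for i in range(10):
                rows.append((f"S{i}", m, rng.lognormal(), rng.lognormal()))
        indep = pd.DataFrame(rows, columns=["subject_id", "marker", "serum", "plasma"])
        assert (serum_plasma_concordance(indep).abs() < 0.9).all()

    def test_independent_pairs_null_distribution(self):
        # |r| of independent pairs at n = 10 follows the t(8) null:
        # P(|r| > r_crit(0.05)) should be about 5 %
        from scipy.stats import t as tdist
        rng = np.random.default_rng(3)
        n, hits, runs = 10, 0, 1000
        tcrit = tdist.ppf(0.975, n - 2)
        rcrit = np.sqrt(tcrit**2 / (tcrit**2 + n - 2))
        for _ in range(runs):
            r = np.corrcoef(rng.normal(size=n), rng.normal(size=n))[0, 1]
            hits += abs(r) > rcrit
        assert 0.02 < hits / runs < 0.09


class TestAlphaSensitivity:
    def test_reports_one_row_per_alpha(self, small_cohort):
        X = small_cohort[MARKERS].to_numpy(float)
        y = (small_cohort.label == "case").to_numpy().astype(int)
        table = alpha_sensitivity(
            X, y, alphas=(0.5, 1.0), lambda_grid=np.array([1.0, 10.0]),
            n_bootstrap=10, seed=11, marker_names=MARKERS,
        )
        assert list(table["alpha"]) == [0.5, 1.0]
        assert (table["n_included"] >= 1).all()
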