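"""Serum verification statistics and multi-marker panel modelling.

Marker-level verification reports the classical descriptive battery for a
case/control serum study: group medians and interquartile ranges (ng/mL),
the two-sample Kolmogorov-Smirnov statistic, and the single-marker AUC.

The multi-marker panel is a penalized logistic regression of disease status
on marker concentrations with an elastic-net penalty

    NLL(beta) + lambda * [alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2]

(intercept unpenalized; markers standardized internally, coefficients
reported back on the ng/mL scale). The penalty weight lambda is selected by
bootstrap resampling: for each draw the model is fitted on the in-bag
sample at every grid value and scored by AUC on the out-of-bag subjects;
the lambda maximizing the mean out-of-bag AUC wins (ties go to the larger,
more parsimonious lambda). Markers whose coefficient is shrunk exactly to
zero at the chosen lambda drop out of the final panel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "MarkerSummary",
    "RocCurve",
    "LogisticFit",
    "PenaltySelection",
    "PanelModel",
    "summarize_marker",
    "roc_auc",
    "sensitivity_at_specificity",
    "fit_penalized_logistic",
    "select_penalty_bootstrap",
    "finalize_panel",
    "bootstrap_validate",
    "evaluate_panel",
    "correlate_score_covariate",
    "serum_plasma_concordance",
    "DEFAULT_LAMBDA_GRID",
]

#: Default penalty grid (log-spaced). The spec of the selection procedure
#: leaves the grid open; this range spans effectively-unpenalized through
#: all-zero fits for cohorts of a few hundred subjects.
DEFAULT_LAMBDA_GRID: np.ndarray = np.logspace(-1.0, 2.0, 13)


# ---------------------------------------------------------------------------
# Marker-level statistics
# ---------------------------------------------------------------------------

@dataclass
class MarkerSummary:
    marker: str
    median_case: float
    iqr_case: tuple[float, float]
    median_control: float
    iqr_control: tuple[float, float]
    ks_statistic: float
    ks_pvalue: float
    auc: float


def summarize_marker(
    values_case: np.ndarray, values_control: np.ndarray, marker: str = ""
) -> MarkerSummary:
    """Median/IQR per group, two-sample KS test, and single-marker AUC.

    Cases are the positive class and higher values are treated as more
    case-like (the convention of the verification tables).
    """
    case = np.asarray(values_case, dtype=float)
    control = np.asarray(values_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    ks = stats.ks_2samp(case, control, method="asymp")
    scores = np.concatenate([case, control])
    labels = np.concatenate([np.ones(case.size), np.zeros(control.size)])
    return MarkerSummary(
        marker=marker,
        median_case=float(np.median(case)),
        iqr_case=tuple(np.percentile(case, [25, 75])),
        median_control=float(np.median(control)),
        iqr_control=tuple(np.percentile(control, [25, 75])),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        auc=roc_auc(scores, labels).auc,
    )


@dataclass
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie correction."""
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve over every distinct threshold plus rank-based AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    thresholds = np.r_[np.inf, s[distinct]]
    sens = np.r_[0.0, tp / n1]
    spec = np.r_[1.0, 1.0 - fp / n0]
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=_auc_rank(scores, labels),
    )


def sensitivity_at_specificity(roc: RocCurve, target_specificity: float) -> float:
    """Highest sensitivity among achievable operating points with spec >= target.

    No interpolation between operating points: the returned value is
    attained by an actual threshold.
    """
    if not 0.0 < target_specificity < 1.0:
        raise ValueError("target specificity must lie in (0, 1)")
    ok = roc.specificity >= target_specificity
    return float(roc.sensitivity[ok].max())


# ---------------------------------------------------------------------------
# Penalized logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    coef: np.ndarray            # original (ng/mL) scale, zeros preserved
    intercept: float
    coef_std: np.ndarray        # standardized scale
    mean: np.ndarray
    sd: np.ndarray
    lam: float
    alpha: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, keep] = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, mean, sd, keep


def fit_penalized_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 20_000,
) -> LogisticFit:
    """Elastic-net logistic regression at a fixed penalty weight.

    Markers are standardized internally (penalization is scale-dependent);
    coefficients are reported back on the original concentration scale. The
    intercept is never penalized. ``lam = 0`` gives the unpenalized fit.
    Zero-variance columns are dropped with a warning (coefficient 0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    Xs, mean, sd, keep = _standardize(X)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s)")
    if lam == 0:
        est = LogisticRegression(
            C=np.inf, solver="lbfgs", tol=tol, max_iter=max_iter
        )
    else:
        # scikit-learn's objective is sum-loss + (1/C)[alpha*L1 + (1-alpha)/2*L2],
        # identical to ours with C = 1/lam.
        est = LogisticRegression(
            solver="saga",
            C=1.0 / lam,
            l1_ratio=alpha,
            tol=tol,
            max_iter=max_iter,
            random_state=0,
        )
    est.fit(Xs[:, keep], y)
    coef_std = np.zeros(X.shape[1])
    coef_std[keep] = est.coef_.ravel()
    if np.all(coef_std == 0.0):
        # penalty-dominated limit: the unpenalized intercept's profile optimum
        # is the logit of the case prevalence (saga's step size collapses here)
        prev = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        est.intercept_ = np.array([np.log(prev / (1 - prev))])
    coef = np.zeros(X.shape[1])
    coef[keep] = coef_std[keep] / sd[keep]
    intercept = float(est.intercept_[0]) - float(
        np.sum(coef_std[keep] * mean[keep] / sd[keep])
    )
    return LogisticFit(
        coef=coef, intercept=intercept, coef_std=coef_std,
        mean=mean, sd=sd, lam=float(lam), alpha=float(alpha),
    )


@dataclass
class PenaltySelection:
    lambda_grid: np.ndarray
    mean_oob_auc: np.ndarray
    sd_oob_auc: np.ndarray
    chosen_lambda: float
    n_bootstrap: int
    n_skipped: int
    mean_oob_fraction: float
    seed: int


def select_penalty_bootstrap(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    alpha: float = 0.5,
    n_bootstrap: int = 10_000,
    seed: int = 0,
    tol: float = 1e-4,
) -> PenaltySelection:
    """Select the penalty weight by mean out-of-bag AUC over bootstrap draws.

    Each draw resamples n subjects with replacement, fits the elastic-net
    path on the in-bag sample and scores the out-of-bag subjects; draws
    whose in-bag or out-of-bag subset is single-class are skipped and
    counted. Ties in the mean OOB AUC go to the larger lambda. The default
    bootstrap count follows the published procedure (10,000); it is
    config-reducible for small studies and demos.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    lambda_grid = np.sort(np.asarray(
        DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float
    ))
    if lambda_grid.size == 0:
        raise ValueError("lambda_grid must be non-empty")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    n = len(y)
    rng = np.random.default_rng(seed)
    aucs: list[np.ndarray] = []
    oob_fractions: list[float] = []
    n_skipped = 0
    # warm-started path estimator reused across lambdas within a draw
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        oob_fractions.append(oob.size / n)
        if oob.size == 0 or len(np.unique(y[idx])) < 2 or len(np.unique(y[oob])) < 2:
            n_skipped += 1
            continue
        Xb, yb = X[idx], y[idx]
        Xs, mean, sd, keep = _standardize(Xb)
        Xoob = np.zeros_like(X[oob])
        Xoob[:, keep] = (X[oob][:, keep] - mean[keep]) / sd[keep]
        est = LogisticRegression(
            solver="saga", l1_ratio=alpha,
            tol=tol, max_iter=5_000, warm_start=True, C=1.0,
            random_state=0,
        )
        draw_auc = np.empty(lambda_grid.size)
        for j in range(lambda_grid.size - 1, -1, -1):  # large lambda first
            est.C = 1.0 / lambda_grid[j]
            est.fit(Xs[:, keep], yb)
            scores = Xoob[:, keep] @ est.coef_.ravel() + est.intercept_[0]
            draw_auc[j] = _auc_rank(scores, y[oob])
        aucs.append(draw_auc)
    if not aucs:
        raise ValueError("every bootstrap draw was single-class; cohort too small")
    auc_mat = np.vstack(aucs)
    mean_auc = auc_mat.mean(axis=0)
    best = np.flatnonzero(mean_auc == mean_auc.max())[-1]
    return PenaltySelection(
        lambda_grid=lambda_grid,
        mean_oob_auc=mean_auc,
        sd_oob_auc=auc_mat.std(axis=0),
        chosen_lambda=float(lambda_grid[best]),
        n_bootstrap=n_bootstrap,
        n_skipped=n_skipped,
        mean_oob_fraction=float(np.mean(oob_fractions)),
        seed=seed,
    )


@dataclass
class PanelModel:
    """Final fitted marker panel with its selection metadata."""

    markers: list[str]
    coef: dict[str, float]          # ng/mL scale; zeros kept for transparency
    intercept: float
    lam: float
    alpha: float
    scaling: dict[str, tuple[float, float]]  # marker -> (mean, sd)
    seed: int = 0
    n_bootstrap: int = 0

    @property
    def included_markers(self) -> list[str]:
        return [m for m in self.markers if self.coef[m] != 0.0]

    def score(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.markers].to_numpy(dtype=float)
        beta = np.array([self.coef[m] for m in self.markers])
        return np.asarray(X, dtype=float) @ beta + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "markers": self.markers,
                "coefficients": self.coef,
                "intercept": self.intercept,
                "lambda": self.lam,
                "alpha": self.alpha,
                "scaling": {m: list(v) for m, v in self.scaling.items()},
                "seed": self.seed,
                "n_bootstrap": self.n_bootstrap,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PanelModel":
        d = json.loads(text)
        return cls(
            markers=d["markers"],
            coef={m: float(c) for m, c in d["coefficients"].items()},
            intercept=float(d["intercept"]),
            lam=float(d["lambda"]),
            alpha=float(d["alpha"]),
            scaling={m: tuple(v) for m, v in d["scaling"].items()},
            seed=int(d.get("seed", 0)),
            n_bootstrap=int(d.get("n_bootstrap", 0)),
        )


def finalize_panel(
    X: np.ndarray,
    y: np.ndarray,
    selection: PenaltySelection,
    alpha: float = 0.5,
    marker_names: list[str] | None = None,
    tol: float = 1e-8,
) -> PanelModel:
    """Refit on the full training set at the chosen penalty weight."""
    X = np.asarray(X, dtype=float)
    marker_names = marker_names or [f"marker_{j}" for j in range(X.shape[1])]
    fit = fit_penalized_logistic(X, y, selection.chosen_lambda, alpha, tol=tol)
    if np.all(fit.coef == 0.0):
        raise ValueError("degenerate model: every marker coefficient is zero")
    return PanelModel(
        markers=list(marker_names),
        coef={m: float(c) for m, c in zip(marker_names, fit.coef)},
        intercept=fit.intercept,
        lam=selection.chosen_lambda,
        alpha=float(alpha),
        scaling={m: (float(mu), float(s)) for m, mu, s in
                 zip(marker_names, fit.mean, fit.sd)},
        seed=selection.seed,
        n_bootstrap=selection.n_bootstrap,
    )


def alpha_sensitivity(
    X: np.ndarray,
    y: np.ndarray,
    alphas: np.ndarray | list[float] = (0.1, 0.25, 0.5, 0.75, 0.9, 1.0),
    lambda_grid: np.ndarray | None = None,
    n_bootstrap: int = 200,
    seed: int = 0,
    marker_names: list[str] | None = None,
) -> pd.DataFrame:
    """How the selected panel depends on the elastic-net mixing parameter.

    For each alpha the full selection + final fit is repeated; the table
    reports the chosen lambda, the retained marker set, and its size. The
    mixing parameter is not identified by the selection procedure itself,
    so this is the diagnostic to run when marker inclusion is the question.
    """
    X = np.asarray(X, dtype=float)
    marker_names = marker_names or [f"marker_{j}" for j in range(X.shape[1])]
    rows = []
    for a in alphas:
        sel = select_penalty_bootstrap(
            X, y, lambda_grid=lambda_grid, alpha=a,
            n_bootstrap=n_bootstrap, seed=seed,
        )
        model = finalize_panel(X, y, sel, a, marker_names)
        rows.append(
            {
                "alpha": float(a),
                "chosen_lambda": sel.chosen_lambda,
                "n_included": len(model.included_markers),
                "included": ";".join(model.included_markers),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_validate(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 0.5,
    n_bootstrap: int = 200,
    seed: int = 0,
    tol: float = 1e-4,
) -> float:
    """Optimism-corrected bootstrap estimate of the training AUC.

    Harrell's procedure: refit on each bootstrap resample, measure the AUC
    drop from the resample to the original data, and subtract the average
    drop (optimism) from the apparent AUC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    full = fit_penalized_logistic(X, y, lam, alpha, tol=tol)
    apparent = _auc_rank(full.decision(X), y)
    rng = np.random.default_rng(seed)
    optimism = []
    n = len(y)
    while len(optimism) < n_bootstrap:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        fit = fit_penalized_logistic(X[idx], y[idx], lam, alpha, tol=tol)
        optimism.append(
            _auc_rank(fit.decision(X[idx]), y[idx]) - _auc_rank(fit.decision(X), y)
        )
    return float(apparent - np.mean(optimism))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_panel(
    model: PanelModel,
    cohort: pd.DataFrame,
    subgroups: dict[str, pd.Series] | None = None,
    specificity_target: float = 0.9,
) -> dict:
    """Overall and control-subgroup AUCs plus sensitivity at fixed specificity.

    ``subgroups`` maps a name to a boolean mask over *control* rows; each
    subgroup AUC compares all cases against that control subset. Empty
    subgroups are skipped with a warning.
    """
    y = (cohort["label"] == "case").to_numpy().astype(int)
    scores = model.score(cohort)
    roc = roc_auc(scores, y)
    report = {
        "n_cases": int(y.sum()),
        "n_controls": int((1 - y).sum()),
        "auc": roc.auc,
        "sensitivity_at_specificity": {
            str(specificity_target): sensitivity_at_specificity(roc, specificity_target)
        },
        "subgroup_auc": {},
    }
    if subgroups:
        is_case = y == 1
        for name, mask in subgroups.items():
            mask = np.asarray(mask).astype(bool)
            sel = is_case | (~is_case & mask)
            if (~is_case & mask).sum() == 0:
                warnings.warn(f"subgroup {name!r} is empty; skipped")
                continue
            report["subgroup_auc"][name] = roc_auc(scores[sel], y[sel]).auc
    return report


def correlate_score_covariate(
    scores: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation (r, p) between panel scores and a covariate.

    Pairs with a missing covariate are dropped; at least 3 complete pairs
    are required and the covariate must not be constant.
    """
    scores = np.asarray(scores, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    ok = ~(np.isnan(scores) | np.isnan(covariate))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(covariate[ok]) == 0:
        raise ValueError("covariate is constant; correlation undefined")
    r, p = stats.pearsonr(scores[ok], covariate[ok])
    return float(r), float(p)


def serum_plasma_concordance(paired: pd.DataFrame) -> pd.Series:
    """Per-marker Pearson r between paired serum and plasma concentrations."""
    out = {}
    for marker, sub in paired.groupby("marker", sort=True):
        if len(sub) < 3:
            raise ValueError(f"marker {marker}: need >= 3 paired subjects")
        r, _ = correlate_score_covariate(
            sub["serum"].to_numpy(), sub["plasma"].to_numpy()
        )
        out[marker] = r
    return pd.Series(out, name="pearson_r")
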