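"""Statistical layer: per-metric one-tailed t-tests, elastic-net regularized
logistic regression with the 1-SE lambda rule, the LOOCV alpha-sweep, the
exploratory full-data fit, a linear-SVM separating hyperplane, and accuracy
bookkeeping."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import _enet
from .io_core import CohortTable, ValidationError

__all__ = [
    "TTestResult",
    "onetail_ttest",
    "RegressionModel",
    "fit_elastic_net_logistic",
    "lambda_max",
    "lambda_path",
    "select_lambda_1se",
    "SweepResult",
    "loocv_sweep",
    "exploratory_fit",
    "HyperplaneModel",
    "svm_hyperplane",
    "accuracy_from_counts",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    p: float
    direction: str  # 'A>B', 'B>A', or 'none'
    flagged: bool = False


def onetail_ttest(
    group_a: np.ndarray, group_b: np.ndarray, direction: str | None = None
) -> TTestResult:
    """Unpaired pooled-variance t-test, one-tailed.

    With ``direction=None`` the tail follows the *observed* mean difference
    (identical groups give p = 0.5); note that under the null this doubles the
    nominal rejection rate relative to a tail fixed a priori, which can be
    requested with ``direction='A>B'`` or ``'B>A'``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    na, nb = len(a), len(b)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(t=0.0, p=0.5, direction="none", flagged=True)
        return TTestResult(
            t=np.inf if diff > 0 else -np.inf,
            p=0.0,
            direction="A>B" if diff > 0 else "B>A",
            flagged=True,
        )
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    df = na + nb - 2
    if direction is None:
        p = float(stats.t.sf(abs(t), df))
        direction = "A>B" if diff > 0 else ("B>A" if diff < 0 else "none")
    elif direction == "A>B":
        p = float(stats.t.sf(t, df))
    elif direction == "B>A":
        p = float(stats.t.sf(-t, df))
    else:
        raise ValidationError(f"unknown direction {direction!r}")
    return TTestResult(t=float(t), p=p, direction=direction)


# ---------------------------------------------------------------------------
# elastic-net logistic regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionModel:
    intercept: float
    coef: np.ndarray                 # on the original feature scale
    alpha: float
    lam: float
    feature_names: list[str]
    mean_: np.ndarray                # standardization used at fit time
    scale_: np.ndarray
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    @property
    def retained(self) -> list[str]:
        return [n for n, c in zip(self.feature_names, self.coef) if abs(c) > 1e-10]

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.coef) > 1e-10))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.atleast_2d(np.asarray(X, dtype=float)) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef": dict(zip(self.feature_names, self.coef.tolist())),
            "alpha": self.alpha,
            "lambda": self.lam,
            "retained": self.retained,
            "converged": self.converged,
        }


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValidationError("X must be (N, p) with matching y")
    if len(y) < 2:
        raise ValidationError("need N >= 2 observations")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValidationError("y must contain both binary classes")
    return X, y


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def fit_elastic_net_logistic(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    feature_names: list[str] | None = None,
    max_outer: int = 200,
    tol: float = 1e-10,
) -> RegressionModel:
    """Minimize (1/N)*Deviance + lam*P_alpha(beta) by IRLS + cyclic coordinate
    descent; features standardized internally, coefficients returned on the
    original scale, intercept unpenalized."""
    X, y = _validate_xy(X, y)
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must be in [0, 1]")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    Xs, mu, sd = _standardize(X)
    ybar = y.mean()
    b0 = float(np.log(ybar / (1.0 - ybar)))
    beta = np.zeros(X.shape[1])
    b0, beta, trace, converged = _enet.cd_solve(
        Xs, y, float(alpha), float(lam), b0, beta, max_outer, tol
    )
    if not converged and lam == 0.0:
        warnings.warn(
            "unpenalized logistic fit did not converge (possible complete separation)",
            RuntimeWarning,
        )
    coef = beta / sd
    intercept = b0 - float(np.dot(beta, mu / sd))
    return RegressionModel(
        intercept=float(intercept),
        coef=coef,
        alpha=float(alpha),
        lam=float(lam),
        feature_names=list(feature_names),
        mean_=mu,
        scale_=sd,
        objective_trace=np.asarray(trace),
        converged=bool(converged),
    )


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest lambda at which all penalized coefficients are exactly zero
    (KKT bound at the null model, standardized design)."""
    X, y = _validate_xy(X, y)
    Xs, _, _ = _standardize(X)
    score = np.abs(Xs.T @ (y - y.mean())) * 2.0 / len(y)
    return float(score.max() / max(alpha, 1e-3))


def lambda_path(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 100,
    ratio: float | None = None,
) -> np.ndarray:
    """Descending log-spaced lambda sequence from lambda_max; the floor ratio
    defaults to 1e-2 when N < p (near-separable regime) and 1e-4 otherwise."""
    if ratio is None:
        ratio = 1e-2 if len(X) < 2 * X.shape[1] else 1e-4
    lmax = lambda_max(X, y, alpha)
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _make_folds(y: np.ndarray, n_folds: int | None, seed: int) -> tuple[np.ndarray, int]:
    """Fold ids; LOO for small N, stratified K-fold otherwise.  Folds whose
    training part is single-class trigger a logged reshuffle."""
    N = len(y)
    if n_folds is None:
        n_folds = N if N <= 40 else 10
    if n_folds >= N:
        return np.arange(N), N
    from sklearn.model_selection import StratifiedKFold

    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        ids = np.empty(N, dtype=np.int64)
        ok = True
        for f, (tr, te) in enumerate(skf.split(np.zeros((N, 1)), y)):
            ids[te] = f
            if len(np.unique(y[tr])) < 2:
                ok = False
        if ok:
            if attempt > 0:
                log.warning("reshuffled CV folds (seed %d)", seed + attempt)
            return ids, n_folds
    raise ValidationError("could not build CV folds with both classes in every training set")


def select_lambda_1se(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_folds: int | None = None,
    seed: int = 0,
    n_lambda: int = 100,
    full_output: bool = False,
):
    """Largest lambda whose cross-validated deviance is within one standard
    error of the path minimum."""
    X, y = _validate_xy(X, y)
    lams = lambda_path(X, y, alpha, n_lambda)
    fold_ids, n_folds_eff = _make_folds(y, n_folds, seed)
    dev = _enet.cv_path_deviance(
        np.ascontiguousarray(X), y, float(alpha), lams, fold_ids, n_folds_eff, 40, 1e-7
    )  # (L, N) per-observation held-out deviance
    if n_folds_eff == len(y):
        cv_mean = dev.mean(axis=1)
        cv_se = dev.std(axis=1, ddof=1) / np.sqrt(len(y))
    else:
        fold_means = np.column_stack(
            [dev[:, fold_ids == f].mean(axis=1) for f in range(n_folds_eff)]
        )
        cv_mean = fold_means.mean(axis=1)
        cv_se = fold_means.std(axis=1, ddof=1) / np.sqrt(n_folds_eff)
    i_min = int(np.argmin(cv_mean))
    threshold = cv_mean[i_min] + cv_se[i_min]
    candidates = np.where(cv_mean <= threshold)[0]
    lam = float(lams[candidates[0]])  # lams descend: first qualifying = largest
    if full_output:
        return lam, {"lambdas": lams, "cv_mean": cv_mean, "cv_se": cv_se, "i_min": i_min}
    return lam


# ---------------------------------------------------------------------------
# LOOCV alpha-sweep / exploratory fit
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    alphas: np.ndarray
    n_false: np.ndarray            # false LOOCV predictions per alpha (nan = failed)
    n_false_bridge: np.ndarray     # subjects with y=1 predicted 0
    n_false_nobridge: np.ndarray
    n_retained: np.ndarray         # nonzero coefficients of the full-data 1-SE fit
    threshold: float = 0.5

    def best(self) -> tuple[float, int]:
        i = int(np.nanargmin(self.n_false))
        return float(self.alphas[i]), int(self.n_false[i])

    def to_dict(self) -> dict:
        return {
            "alphas": self.alphas.tolist(),
            "n_false": self.n_false.tolist(),
            "n_false_bridge": self.n_false_bridge.tolist(),
            "n_false_nobridge": self.n_false_nobridge.tolist(),
            "n_retained": self.n_retained.tolist(),
            "threshold": self.threshold,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def loocv_sweep(
    cohort: CohortTable,
    alpha_grid: np.ndarray | None = None,
    threshold: float = 0.5,
    n_folds: int | None = None,
    seed: int = 0,
    n_lambda: int = 100,
) -> SweepResult:
    """For every alpha: leave-one-out predictions (inner 1-SE lambda selection
    on each training set), rounded at ``threshold``; plus the retained-variable
    count of the full-data fit at that alpha."""
    cohort.require_both_classes()
    X, y = cohort.X, cohort.y
    N = len(y)
    if N < 3:
        raise ValidationError("LOOCV sweep needs N >= 3")
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    alphas = np.asarray(alpha_grid, dtype=float)
    n_false = np.full(len(alphas), np.nan)
    n_fb = np.full(len(alphas), np.nan)
    n_fn = np.full(len(alphas), np.nan)
    n_ret = np.full(len(alphas), np.nan)
    for ia, alpha in enumerate(alphas):
        try:
            false_b = false_n = 0
            for i in range(N):
                mask = np.ones(N, dtype=bool)
                mask[i] = False
                Xtr, ytr = X[mask], y[mask]
                if len(np.unique(ytr)) < 2:
                    raise ValidationError("training fold single-class")
                lam = select_lambda_1se(Xtr, ytr, alpha, n_folds=n_folds, seed=seed,
                                        n_lambda=n_lambda)
                model = fit_elastic_net_logistic(Xtr, ytr, alpha, lam,
                                                 feature_names=cohort.feature_names)
                pred = int(model.predict_proba(X[i])[0] >= threshold)
                if pred != y[i]:
                    if y[i] == 1:
                        false_b += 1
                    else:
                        false_n += 1
            lam_full = select_lambda_1se(X, y, alpha, n_folds=n_folds, seed=seed,
                                         n_lambda=n_lambda)
            full = fit_elastic_net_logistic(X, y, alpha, lam_full,
                                            feature_names=cohort.feature_names)
            n_false[ia] = false_b + false_n
            n_fb[ia] = false_b
            n_fn[ia] = false_n
            n_ret[ia] = full.n_nonzero
        except Exception as exc:  # keep sweeping; record the failure
            log.warning("alpha=%.2f aborted: %s", alpha, exc)
    return SweepResult(
        alphas=alphas,
        n_false=n_false,
        n_false_bridge=n_fb,
        n_false_nobridge=n_fn,
        n_retained=n_ret,
        threshold=threshold,
    )


def exploratory_fit(
    cohort: CohortTable,
    alpha: float = 0.9,
    n_folds: int | None = None,
    seed: int = 0,
) -> RegressionModel:
    """Single full-data fit at a fixed alpha with the 1-SE lambda."""
    cohort.require_both_classes()
    X, y = cohort.X, cohort.y
    lam = select_lambda_1se(X, y, alpha, n_folds=n_folds, seed=seed)
    return fit_elastic_net_logistic(X, y, alpha, lam, feature_names=cohort.feature_names)


# ---------------------------------------------------------------------------
# SVM hyperplane & accuracy
# ---------------------------------------------------------------------------

@dataclass
class HyperplaneModel:
    w: np.ndarray
    b: float
    margin: float
    feature_names: list[str]
    n_misclassified: int

    def to_dict(self) -> dict:
        return {
            "w": dict(zip(self.feature_names, self.w.tolist())),
            "b": self.b,
            "margin": self.margin,
            "n_misclassified": self.n_misclassified,
        }


def svm_hyperplane(
    features: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    C: float = 1.0,
) -> HyperplaneModel:
    """Soft-margin linear SVM on two selected metrics."""
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValidationError("svm_hyperplane expects exactly 2 features")
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes required for SVM")
    if feature_names is None:
        feature_names = ["f0", "f1"]
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    w = clf.coef_[0].astype(float)
    if np.linalg.norm(w) == 0:
        raise ValidationError("degenerate SVM solution (zero weight vector)")
    return HyperplaneModel(
        w=w,
        b=float(clf.intercept_[0]),
        margin=float(2.0 / np.linalg.norm(w)),
        feature_names=list(feature_names),
        n_misclassified=int(np.sum(clf.predict(X) != y)),
    )


def accuracy_from_counts(n_false: int, n_total: int) -> float:
    """Percent correct, to one decimal (e.g. 4 false of 26 -> 84.6)."""
    if n_total <= 0:
        raise ValidationError("n_total must be > 0")
    if not 0 <= n_false <= n_total:
        raise ValidationError("need 0 <= n_false <= n_total")
    return round(100.0 * (n_total - n_false) / n_total, 1)
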