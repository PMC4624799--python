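import numpy as np
import pandas as pd
import pytest

from herniaquant import _enet
from herniaquant.io_core import CohortTable, ValidationError
from herniaquant.outcome_models import (
    accuracy_from_counts,
    exploratory_fit,
    fit_elastic_net_logistic,
    lambda_max,
    lambda_path,
    loocv_sweep,
    onetail_ttest,
    select_lambda_1se,
    svm_hyperplane,
)
from herniaquant.synthetic_data import make_cohort

GAUSS_PROFILE = {m: (0.0, -2.0, 2.0, 0.0, -2.0, 2.0, "normal") for m in "ABCDEFGHIJKLMNOPQRST"}


def _logistic_instance(rng, n=40, p=5, beta=None):
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.r_[1.5, -2.0, np.zeros(p - 2)]
    prob = 1.0 / (1.0 + np.exp(-(X @ beta)))
    y = (rng.random(n) < prob).astype(float)
    if len(np.unique(y)) < 2:  # pragma: no cover - essentially impossible
        y[0] = 1 - y[0]
    return X, y


class TestOnetailTTest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        r = onetail_ttest(a, a.copy())
        assert r.t == 0.0
        assert r.p == 0.5

    def test_direction_reported(self, rng):
        r = onetail_ttest(rng.normal(5, 1, 20), rng.normal(0, 1, 20))
        assert r.direction == "A>B"
        assert r.p < 1e-6

    def test_zero_variance_flagged(self):
        r = onetail_ttest(np.ones(3), np.ones(4))
        assert r.flagged and r.p == 0.5

    def test_matches_scipy_halved_twosided(self, rng):
        from scipy import stats

        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 17)
        r = onetail_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert r.p == pytest.approx(ref.pvalue / 2, rel=1e-9)
        assert abs(r.t) == pytest.approx(abs(ref.statistic), rel=1e-9)

    def test_table_calibrated_power(self):
        # strong shape-metric separation -> mostly significant; null-like
        # separation (metric L) -> mostly not
        sig = 0
        null_sig = 0
        reps = 20
        for seed in range(reps):
            tab = make_cohort(9, 17, seed=seed)
            y = tab.y
            a = tab.frame["A"].to_numpy()
            l = tab.frame["L"].to_numpy()
            sig += onetail_ttest(a[y == 1], a[y == 0]).p < 0.05
            null_sig += onetail_ttest(l[y == 1], l[y == 0]).p < 0.05
        assert sig >= 0.7 * reps
        assert null_sig <= 0.5 * reps


class TestElasticNetFit:
    def test_lambda0_matches_independent_newton_solver(self, rng):
        import statsmodels.api as sm

        X, y = _logistic_instance(rng)
        model = fit_elastic_net_logistic(X, y, alpha=0.5, lam=0.0)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton")
        ours = np.r_[model.intercept, model.coef]
        assert np.abs(ours - ref.params).max() < 1e-5

    def test_null_model_at_lambda_max(self, rng):
        X, y = _logistic_instance(rng)
        lmax = lambda_max(X, y, 1.0)
        model = fit_elastic_net_logistic(X, y, alpha=1.0, lam=lmax * 1.000001)
        assert np.all(model.coef == 0.0)
        prev = y.mean()
        assert model.intercept == pytest.approx(np.log(prev / (1 - prev)), abs=1e-8)

    def test_objective_matches_grid_search_oracle(self, rng):
        # p=2, N=12 constructed instance; brute-force refine over (b0, b1, b2)
        X = rng.normal(size=(12, 2))
        y = np.r_[np.ones(5), np.zeros(7)]
        alpha, lam = 0.7, 0.15
        model = fit_elastic_net_logistic(X, y, alpha, lam)
        Xs = (X - X.mean(0)) / X.std(0)

        def obj(b0, b1, b2):
            return _enet.objective(Xs, y, b0, np.array([b1, b2]), alpha, lam)

        center = np.array([0.0, 0.0, 0.0])
        width = 3.0
        best = np.inf
        for _ in range(6):
            grid = [np.linspace(c - width, c + width, 13) for c in center]
            vals = np.array(
                [[b0, b1, b2, obj(b0, b1, b2)]
                 for b0 in grid[0] for b1 in grid[1] for b2 in grid[2]]
            )
            i = np.argmin(vals[:, 3])
            center, best = vals[i, :3], vals[i, 3]
            width /= 4.0
        ours = _enet.objective(
            Xs, y, model.intercept + float(model.coef @ X.mean(0)),
            model.coef * X.std(0), alpha, lam,
        )
        assert ours <= best + 1e-3

    def test_objective_trace_non_increasing(self, rng):
        X, y = _logistic_instance(rng, n=30)
        model = fit_elastic_net_logistic(X, y, alpha=0.5, lam=0.05)
        assert np.all(np.diff(model.objective_trace) <= 1e-12)

    def test_negative_lambda_rejected(self, rng):
        X, y = _logistic_instance(rng)
        with pytest.raises(ValidationError):
            fit_elastic_net_logistic(X, y, alpha=0.5, lam=-0.1)

    def test_separation_at_lambda0_flagged(self):
        X = np.r_[np.full((5, 1), -2.0), np.full((5, 1), 2.0)] + np.arange(10)[:, None] * 1e-3
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.warns(RuntimeWarning, match="separation"):
            fit_elastic_net_logistic(X, y, alpha=0.5, lam=0.0, max_outer=30)

    def test_penalty_properties_exact(self, rng):
        # P_0 = 0.5*||b||_2^2, P_1 = ||b||_1, linear in alpha
        beta = rng.normal(size=6)

        def pen(alpha):
            return alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * (beta**2).sum()

        assert pen(0.0) == 0.5 * (beta**2).sum()
        assert pen(1.0) == np.abs(beta).sum()
        a1, a2 = 0.3, 0.8
        mid = pen((a1 + a2) / 2)
        assert mid == pytest.approx((pen(a1) + pen(a2)) / 2, rel=1e-12)

    def test_matches_sklearn_elasticnet_logistic(self, rng):
        # secondary cross-check of the penalized path against saga
        from sklearn.linear_model import LogisticRegression

        X, y = _logistic_instance(rng, n=200, p=6)
        Xs = (X - X.mean(0)) / X.std(0)
        alpha, lam = 0.5, 0.1
        ours = fit_elastic_net_logistic(Xs, y, alpha, lam)
        # sklearn minimizes sum(-ll) + penalty with C/ l1_ratio parametrization:
        # (1/N)(-2 ll) + lam*[a|b|+ (1-a)/2 b^2]  <=>  C = 2/(N*lam)
        skl = LogisticRegression(
            solver="saga", l1_ratio=alpha,
            C=2.0 / (len(y) * lam), max_iter=20000, tol=1e-10,
        ).fit(Xs, y)
        assert np.abs(ours.coef - skl.coef_[0]).max() < 1e-3


class TestLambdaSelection:
    def test_1se_lambda_geq_min_lambda(self, rng):
        X, y = _logistic_instance(rng, n=60, p=8)
        lam_1se, info = select_lambda_1se(X, y, 0.9, full_output=True)
        lam_min = info["lambdas"][info["i_min"]]
        assert lam_1se >= lam_min

    def test_pure_noise_yields_null_model(self, rng):
        nulls = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(40, 10))
            y = np.r_[np.ones(15), np.zeros(25)]
            lam = select_lambda_1se(X, y, 0.9, seed=seed)
            model = fit_elastic_net_logistic(X, y, 0.9, lam)
            nulls += model.n_nonzero == 0
        assert nulls >= 9

    def test_support_recovery_strong_signal(self):
        hits = 0
        discarded = []
        beta_true = np.zeros(20)
        beta_true[1] = beta_true[4] = 2.0
        for seed in range(5):
            tab = make_cohort(100, 100, effect_profile=GAUSS_PROFILE,
                              beta_true=beta_true, outcome="logistic", seed=seed)
            lam = select_lambda_1se(tab.X, tab.y, 0.9, seed=seed)
            model = fit_elastic_net_logistic(tab.X, tab.y, 0.9, lam,
                                             feature_names=tab.feature_names)
            retained = set(model.retained)
            hits += {"B", "E"}.issubset(retained)
            discarded.append(18 - len(retained - {"B", "E"}))
        assert hits >= 4
        assert np.mean(discarded) >= 0.8 * 18


class TestLoocvSweep:
    def test_separable_cohort_zero_false(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.normal(8, 0.5, size=(9, 3)), rng.normal(-8, 0.5, size=(17, 3))]
        frame = pd.DataFrame(X, columns=["B", "E", "G"])
        frame["bridge"] = np.r_[np.ones(9, int), np.zeros(17, int)]
        sweep = loocv_sweep(CohortTable(frame), alpha_grid=np.array([0.3, 0.9]))
        assert np.all(sweep.n_false == 0)

    def test_bridge_class_error_concentration(self):
        grid = np.array([0.3, 0.6, 0.9])
        bridge_err = nobridge_err = 0.0
        for seed in range(2):
            tab = make_cohort(9, 17, seed=seed)
            sweep = loocv_sweep(tab, alpha_grid=grid, seed=seed)
            bridge_err += np.nansum(sweep.n_false_bridge)
            nobridge_err += np.nansum(sweep.n_false_nobridge)
        assert bridge_err > nobridge_err

    def test_prediction_invariant_to_subject_order(self):
        tab = make_cohort(6, 8, seed=3)
        grid = np.array([0.8])
        s1 = loocv_sweep(tab, alpha_grid=grid)
        perm = np.random.default_rng(1).permutation(len(tab.y))
        shuffled = CohortTable(tab.frame.iloc[perm].reset_index(drop=True))
        s2 = loocv_sweep(shuffled, alpha_grid=grid)
        assert s1.n_false[0] == s2.n_false[0]

    def test_ridge_retains_all(self):
        tab = make_cohort(9, 17, seed=1)
        sweep = loocv_sweep(tab, alpha_grid=np.array([0.0]))
        assert sweep.n_retained[0] == 20


class TestExploratoryFit:
    def test_ridge_has_no_exact_zeros(self):
        tab = make_cohort(9, 17, seed=2)
        model = exploratory_fit(tab, alpha=0.0)
        assert np.all(model.coef != 0.0)

    def test_sparser_at_higher_alpha_on_average(self):
        diffs = []
        for seed in range(5):
            tab = make_cohort(9, 17, seed=seed)
            hi = exploratory_fit(tab, alpha=0.9, seed=seed).n_nonzero
            lo = exploratory_fit(tab, alpha=0.1, seed=seed).n_nonzero
            diffs.append(lo - hi)
        assert np.mean(diffs) >= 0

    def test_recovers_planted_pair(self):
        beta_true = np.zeros(20)
        beta_true[1] = beta_true[4] = 2.0  # metrics B and E
        hits = 0
        for seed in range(5):
            tab = make_cohort(26, 26, effect_profile=GAUSS_PROFILE,
                              beta_true=2 * beta_true, outcome="logistic", seed=seed)
            model = exploratory_fit(tab, alpha=0.9, seed=seed)
            hits += {"B", "E"}.issubset(set(model.retained))
        assert hits >= 4


class TestSVM:
    def test_two_point_geometry(self):
        X = np.array([[1.0, 1.0], [-1.0, -1.0]])
        y = np.array([1, 0])
        model = svm_hyperplane(X, y)
        # hyperplane through the origin, normal along the class difference
        assert model.b == pytest.approx(0.0, abs=1e-6)
        w = model.w / np.linalg.norm(model.w)
        assert np.allclose(np.abs(w), [np.sqrt(0.5)] * 2, atol=1e-6)
        assert model.n_misclassified == 0

    def test_separable_margin_vs_angular_oracle(self, rng):
        X = np.r_[rng.normal([3, 3], 0.3, size=(10, 2)), rng.normal([-3, -3], 0.3, size=(12, 2))]
        y = np.r_[np.ones(10, int), np.zeros(12, int)]
        model = svm_hyperplane(X, y, C=1000.0)
        assert model.n_misclassified == 0
        # brute force over hyperplane angles on a 1-degree grid
        best = 0.0
        for deg in range(180):
            t = np.deg2rad(deg)
            n = np.array([np.cos(t), np.sin(t)])
            proj = X @ n
            gap = proj[y == 1].min() - proj[y == 0].max()
            gap2 = proj[y == 0].min() - proj[y == 1].max()
            best = max(best, gap, gap2)
        assert model.margin == pytest.approx(best, rel=0.02)

    def test_table_calibrated_misclassifies_some_bridge(self):
        misses = []
        for seed in range(5):
            tab = make_cohort(9, 17, seed=seed)
            X = tab.frame[["B", "E"]].to_numpy(float)
            model = svm_hyperplane(X, tab.y)
            misses.append(model.n_misclassified)
        assert np.mean(misses) > 0
        assert np.mean(misses) < 9

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            svm_hyperplane(np.zeros((4, 2)), np.ones(4, int))

    def test_wrong_feature_count_rejected(self):
        with pytest.raises(ValidationError):
            svm_hyperplane(np.zeros((4, 3)), np.r_[np.ones(2), np.zeros(2)])


class TestAccuracy:
    def test_printed_worked_examples(self):
        assert accuracy_from_counts(4, 26) == 84.6
        assert accuracy_from_counts(6, 26) == 76.9

    def test_zero_false(self):
        assert accuracy_from_counts(0, 7) == 100.0

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            accuracy_from_counts(5, 0)
        with pytest.raises(ValidationError):
            accuracy_from_counts(9, 8)


class TestLambdaPath:
    def test_descending_and_bounded(self, rng):
        X, y = _logistic_instance(rng, n=50, p=6)
        lams = lambda_path(X, y, 0.8)
        assert np.all(np.diff(lams) < 0)
        assert lams[0] == pytest.approx(lambda_max(X, y, 0.8))
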