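"""SVM: kernel, SMO solver vs QP oracle, Platt scaling, year-pair models."""

import numpy as np
import pytest

from ckdtraj.cohort import CohortConfig, generate_cohort
from ckdtraj.io import records_to_frame
from ckdtraj.staging import stage_cohort
from ckdtraj.svm import (
    RiskSVM,
    SplitProtocol,
    platt_calibrate,
    possibility_heatmap,
    rbf_kernel,
    run_model_year,
    smo_train,
)


class TestKernel:
    def test_self_similarity_is_one(self, rng):
        for _ in range(5):
            x = rng.normal(size=4)
            assert rbf_kernel(x, x, gamma=0.7) == pytest.approx(1.0)

    def test_closed_form(self):
        assert rbf_kernel([0.0, 0.0], [1.0, 0.0], gamma=1.0) \
            == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=3), rng.normal(size=3)
            assert rbf_kernel(x, y, 0.3) == pytest.approx(rbf_kernel(y, x, 0.3))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            rbf_kernel([1.0], [1.0, 2.0], 1.0)


def _qp_oracle(X, y, C, gamma):
    """Solve the C-SVC dual with scipy SLSQP (independent of the SMO path)."""
    from scipy.optimize import minimize

    n = len(y)
    K = rbf_kernel(X, X, gamma)
    Q = K * np.outer(y, y)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - np.ones(n)

    res = minimize(neg_dual, x0=np.full(n, C / 2), jac=grad,
                   bounds=[(0.0, C)] * n,
                   constraints=[{"type": "eq", "fun": lambda a: a @ y,
                                 "jac": lambda a: y}],
                   method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    return -res.fun


class TestSmo:
    def test_two_point_analytic_solution(self):
        """For points x=0 (y=-1), x=1 (y=+1) the dual has the closed form
        alpha1 = alpha2 = 1/(2(1-K(0,1))) and midpoint boundary."""
        X = np.array([[0.0], [1.0]])
        y = np.array([-1, 1])
        gamma = 1.0
        m = smo_train(X, y, C=1e6, gamma=gamma)
        k01 = np.exp(-gamma)
        expected_alpha = 1.0 / (1.0 - k01)
        assert len(m.support_vectors) == 2
        assert np.abs(m.dual_coefs) == pytest.approx(
            [expected_alpha] * 2, rel=1e-3)
        assert m.decision_function([[0.5]])[0] == pytest.approx(0.0, abs=1e-6)
        assert list(m.predict([[0.0], [1.0]])) == [-1, 1]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_dual_objective_matches_qp_oracle(self, seed):
        """SMO dual objective within 1e-4 of the SLSQP QP solution, and
        predictions agree on a grid (20-point random problems)."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 2))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=20) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        C, gamma = 1.0, 0.5
        m = smo_train(X, y, C=C, gamma=gamma, tol=1e-6)
        qp_obj = _qp_oracle(X, y, C, gamma)
        assert m.dual_objective == pytest.approx(qp_obj, abs=1e-4)

    def test_predictions_match_sklearn(self):
        """Cross-check decisions against an independent SVC implementation."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 0] * X[:, 1] > 0, 1, -1)
        C, gamma = 2.0, 0.8
        m = smo_train(X, y, C=C, gamma=gamma, tol=1e-6)
        sk = SVC(C=C, gamma=gamma, kernel="rbf").fit(X, y)
        grid = rng.normal(size=(50, 2))
        assert np.array_equal(m.predict(grid),
                              sk.predict(grid).astype(int))

    def test_xor_pattern_separable_with_rbf(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        m = smo_train(X, y, C=10.0, gamma=1.0)
        assert np.array_equal(m.predict(X), y)

    def test_kkt_conditions_hold(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.where(X[:, 0] > 0.2, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        C = 1.5
        m = smo_train(X, y, C=C, gamma=0.7, tol=1e-6)
        alpha = np.abs(m.dual_coefs)
        assert np.all(alpha >= -1e-10)
        assert np.all(alpha <= C + 1e-10)
        assert abs(m.dual_coefs.sum()) < 1e-8  # sum alpha_i y_i = 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            smo_train(np.zeros((3, 1)), np.array([1, 1, 1]))


class TestPlatt:
    def test_symmetric_values_give_half_at_zero(self, rng):
        g = rng.normal(1, 0.5, 500)
        f = np.concatenate([g, -g])        # exactly mirror-symmetric
        y = np.array([1] * 500 + [-1] * 500)
        a, b = platt_calibrate(f, y)
        p0 = 1.0 / (1.0 + np.exp(b))
        assert p0 == pytest.approx(0.5, abs=0.01)
        assert a < 0

    def test_monotone_in_decision_value(self, rng):
        f = rng.normal(size=300)
        y = np.where(f + rng.normal(scale=0.5, size=300) > 0, 1, -1)
        a, b = platt_calibrate(f, y)
        fs = np.linspace(-3, 3, 50)
        ps = 1.0 / (1.0 + np.exp(a * fs + b))
        assert np.all(np.diff(ps) > 0)

    def test_recovers_known_sigmoid(self, rng):
        """Data generated from p = 1/(1+exp(-2 f)) at n=2000 recovers
        (a, b) = (-2, 0) within 0.2."""
        f = rng.uniform(-4, 4, 2000)
        p = 1.0 / (1.0 + np.exp(-2.0 * f))
        y = np.where(rng.random(2000) < p, 1, -1)
        a, b = platt_calibrate(f, y)
        assert a == pytest.approx(-2.0, abs=0.2)
        assert b == pytest.approx(0.0, abs=0.2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            platt_calibrate([0.1, 0.2], [1, 1])


@pytest.fixture(scope="module")
def staged_cohort():
    df = records_to_frame(generate_cohort(CohortConfig(n_subjects=1500,
                                                       seed=6)))
    return stage_cohort(df)


def _deterministic_staged(staged, comparison_year=2012):
    """Plant outcome <=> comparison-year category >= high: set the final
    year's category to very_high exactly for those subjects."""
    st = staged.copy()
    cmp_cat = st.loc[st["year"] == comparison_year] \
        .set_index("subject_id")["category"]
    final_idx = st.index[st["year"] == 2016]
    planted = st.loc[final_idx, "subject_id"].map(cmp_cat)
    # subjects without a comparison-year record keep their real category
    sel = final_idx[planted.notna().to_numpy()]
    st.loc[sel, "category"] = np.where(planted.loc[sel] >= 2, 3, 0)
    return st


class TestRunModelYear:
    def test_learnable_rule_low_test_error(self, staged_cohort):
        st = _deterministic_staged(staged_cohort)
        tr, te, model = run_model_year(st, 2009, 2012,
                                       SplitProtocol(seed=1), C=10.0)
        assert te <= 0.02

    def test_label_shuffle_gives_majority_rate(self, staged_cohort):
        """Permutation baseline: with the final-year categories shuffled
        across subjects, test error is within 3 SE of the minority rate."""
        st = staged_cohort.copy()
        rng = np.random.default_rng(99)
        final_mask = st["year"] == 2016
        vals = st.loc[final_mask, "category"].to_numpy()
        st.loc[final_mask, "category"] = rng.permutation(vals)
        tr, te, model = run_model_year(st, 2009, 2012,
                                       SplitProtocol(seed=2))
        from ckdtraj.svm import _features_and_labels
        X, y, _ = _features_and_labels(st, 2009, 2012, 2016,
                                       "very_high_at_end", "ordinal")
        minority = min((y == 1).mean(), (y == -1).mean())
        n_test = len(y) - int(round(2 / 3 * len(y)))
        se = np.sqrt(minority * (1 - minority) / n_test)
        assert te <= minority + 3 * se + 0.02

    def test_same_seed_reproducible(self, staged_cohort):
        r1 = run_model_year(staged_cohort, 2009, 2012, SplitProtocol(seed=5))
        r2 = run_model_year(staged_cohort, 2009, 2012, SplitProtocol(seed=5))
        assert r1[0] == r2[0]
        assert r1[1] == r2[1]

    def test_split_integrity(self, staged_cohort):
        from ckdtraj.svm import _features_and_labels, _stratified_split
        X, y, _ = _features_and_labels(staged_cohort, 2009, 2012, 2016,
                                       "very_high_at_end", "ordinal")
        rng = np.random.default_rng(3)
        tr, te = _stratified_split(y, 2 / 3, rng)
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == len(y)
        # stratification: positive rate preserved within 1 subject/stratum
        n_pos_tr = (y[tr] == 1).sum()
        assert abs(n_pos_tr - (y == 1).sum() * 2 / 3) <= 1


def _rule_grid_staged(n_per_combo=40):
    """Staged frame covering all 16 (baseline, comparison) category pairs
    uniformly, with outcome planted as comparison-year category >= high."""
    import pandas as pd

    rows = []
    sid = 0
    for c0 in range(4):
        for c1 in range(4):
            for _ in range(n_per_combo):
                final = 3 if c1 >= 2 else 0
                rows += [(sid, 2009, c0), (sid, 2012, c1), (sid, 2016, final)]
                sid += 1
    df = pd.DataFrame(rows, columns=["subject_id", "year", "category"])
    df["g"] = df["category"]       # placeholder coords, unused by the SVM
    df["p"] = 0
    df["a"] = 0
    df["egfr"] = np.nan
    return df


class TestPossibilityHeatmap:
    def test_deterministic_rule_separates_grid(self):
        st = _rule_grid_staged()
        _, _, model = run_model_year(st, 2009, 2012,
                                     SplitProtocol(seed=1), C=10.0)
        grid = possibility_heatmap(model)
        assert grid.shape == (4, 4)
        assert np.all(grid >= 0.0) and np.all(grid <= 1.0)
        assert np.all(grid[:, 2:] > 0.5)   # high / very_high comparison year
        assert np.all(grid[:, :2] < 0.5)

    def test_pure_function(self, staged_cohort):
        _, _, model = run_model_year(staged_cohort, 2009, 2012,
                                     SplitProtocol(seed=4))
        assert np.array_equal(possibility_heatmap(model),
                              possibility_heatmap(model))

    def test_uncalibrated_model_rejected(self):
        m = smo_train(np.array([[0.0], [1.0]]), np.array([-1, 1]), C=1.0)
        with pytest.raises(ValueError, match="calibrat"):
            possibility_heatmap(m)


class TestRiskSVMApi:
    def test_fit_returns_results_with_summary(self, staged_cohort):
        res = RiskSVM(staged_cohort, 2009, 2012,
                      protocol=SplitProtocol(seed=8)).fit()
        assert 0.0 <= res.training_error <= 1.0
        assert 0.0 <= res.test_error <= 1.0
        text = res.summary()
        assert "test error" in text
        assert "2012" in text
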