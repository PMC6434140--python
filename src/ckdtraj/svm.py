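"""C-support vector classification trained by sequential minimal
optimization (SMO), with Platt-scaled outcome probabilities.

The dual problem

    max_a  Σ a_i - 1/2 Σ_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.   0 <= a_i <= C,  Σ a_i y_i = 0

with the Gaussian RBF kernel K(x, z) = exp(-gamma ||x - z||²) is solved by
repeatedly optimizing the maximal-violating pair (the working-set
selection of LIBSVM's WSS1), which is deterministic.  Decision values are
mapped to outcome "possibilities" by Platt's sigmoid
p = 1 / (1 + exp(A f + B)) fitted by regularized maximum likelihood with
target smoothing.

The study protocol splits subjects 2/3 train : 1/3 test (stratified by
outcome), estimates the training error as the mean 3-fold
cross-validation misclassification rate on the training split, and the
test error on the held-out third.  Features are the ordinal-encoded
prognostic categories (0-3) at the baseline and comparison years; the
calibrated model evaluated on the 16 category pairs gives the possibility
heat map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .staging import PrognosticCategory, outcome
from .trajectory import year_pair

__all__ = ["SVMModel", "SplitProtocol", "rbf_kernel", "smo_train",
           "platt_calibrate", "run_model_year", "possibility_heatmap",
           "RiskSVM", "RiskSVMResults"]


def rbf_kernel(x, y, gamma: float):
    """Gaussian RBF kernel exp(-gamma ||x - y||^2).

    Accepts single vectors or 2-D arrays (pairwise Gram matrix).
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    scalar = xa.ndim == 1 and ya.ndim == 1
    xa, ya = np.atleast_2d(xa), np.atleast_2d(ya)
    if xa.shape[1] != ya.shape[1]:
        raise ValueError(
            f"dimension mismatch: {xa.shape[1]} vs {ya.shape[1]}")
    sq = (np.sum(xa * xa, axis=1)[:, None] + np.sum(ya * ya, axis=1)[None, :]
          - 2.0 * xa @ ya.T)
    k = np.exp(-gamma * np.maximum(sq, 0.0))
    return float(k[0, 0]) if scalar else k


@dataclass
class SVMModel:
    """Trained C-SVC with everything needed to reproduce its decision
    function: support vectors, signed dual coefficients (alpha_i y_i),
    bias, kernel width and box constraint; Platt sigmoid parameters are
    present after calibration."""

    support_vectors: np.ndarray
    dual_coefs: np.ndarray          # alpha_i * y_i, signed
    bias: float
    gamma: float
    C: float
    platt_a: float | None = None
    platt_b: float | None = None
    dual_objective: float = float("nan")

    def decision_function(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = rbf_kernel(X, self.support_vectors, self.gamma)
        k = np.atleast_2d(k)
        return k @ self.dual_coefs + self.bias

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0.0, 1, -1)

    def predict_possibility(self, X) -> np.ndarray:
        """Platt-calibrated probability of the positive class."""
        if self.platt_a is None or self.platt_b is None:
            raise ValueError("model is not calibrated; fit Platt scaling first")
        f = self.decision_function(X)
        return 1.0 / (1.0 + np.exp(self.platt_a * f + self.platt_b))


def smo_train(features, labels, C: float = 1.0, gamma: float | None = None,
              tol: float = 1e-3, seed: int = 0,
              max_iter: int = 200_000) -> SVMModel:
    """Solve the C-SVC dual by SMO with maximal-violating-pair selection.

    ``labels`` must be in {-1, +1} with both classes present.  ``gamma``
    defaults to 1 / (n_features * Var(X)).  The optimizer is
    deterministic; ``seed`` is accepted for interface uniformity.
    Terminates when the maximal KKT violation m(a) - M(a) <= tol.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be 2-D and match labels")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be -1/+1")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate labels: both classes required")
    n = len(y)
    if gamma is None:
        var = X.var()
        gamma = 1.0 / (X.shape[1] * var) if var > 0 else 1.0 / X.shape[1]

    K = rbf_kernel(X, X, gamma)
    Q = K * np.outer(y, y)
    alpha = np.zeros(n)
    grad = -np.ones(n)          # gradient of the (minimized) 1/2 aQa - e.a

    for _ in range(max_iter):
        # I_up: a_i < C for y=+1, a_i > 0 for y=-1 ; I_low symmetric
        up = ((y > 0) & (alpha < C - 1e-12)) | ((y < 0) & (alpha > 1e-12))
        low = ((y > 0) & (alpha > 1e-12)) | ((y < 0) & (alpha < C - 1e-12))
        if not up.any() or not low.any():
            break
        yg = -y * grad
        i = np.flatnonzero(up)[np.argmax(yg[up])]
        j = np.flatnonzero(low)[np.argmin(yg[low])]
        if yg[i] - yg[j] <= tol:
            break
        # pair update on (i, j): step lam >= 0 along the feasible
        # direction da_i = y_i lam, da_j = -y_j lam
        quad = max(Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j], 1e-12)
        lam = (yg[i] - yg[j]) / quad
        lam = min(lam,
                  C - alpha[i] if y[i] > 0 else alpha[i],
                  alpha[j] if y[j] > 0 else C - alpha[j])
        dai = y[i] * lam
        daj = -y[j] * lam
        alpha[i] = min(max(alpha[i] + dai, 0.0), C)
        alpha[j] = min(max(alpha[j] + daj, 0.0), C)
        grad += Q[:, i] * dai + Q[:, j] * daj

    yg = -y * grad
    up = ((y > 0) & (alpha < C - 1e-12)) | ((y < 0) & (alpha > 1e-12))
    low = ((y > 0) & (alpha > 1e-12)) | ((y < 0) & (alpha < C - 1e-12))
    if up.any() and low.any():
        b = (yg[up].max() + yg[low].min()) / 2.0
    else:
        b = 0.0

    dual_obj = float(alpha.sum() - 0.5 * alpha @ Q @ alpha)
    sv = alpha > 1e-8
    return SVMModel(
        support_vectors=X[sv].copy(),
        dual_coefs=(alpha * y)[sv].copy(),
        bias=float(b),
        gamma=float(gamma), C=float(C),
        dual_objective=dual_obj)


def platt_calibrate(decision_values, labels,
                    max_iter: int = 100) -> tuple[float, float]:
    """Fit Platt's sigmoid p = 1/(1+exp(A f + B)) by regularized ML.

    Uses the target-smoothing priors t+ = (N+ + 1)/(N+ + 2),
    t- = 1/(N- + 2) and Newton iterations with backtracking.  Returns
    (A, B); A < 0 whenever the decision values are positively associated
    with the positive class.
    """
    f = np.asarray(decision_values, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate labels: both classes required")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    a, b = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    sigma = 1e-12

    def objective(a_, b_):
        # F = sum t_i z_i + log(1 + exp(-z_i)), stable in both tails
        z = a_ * f + b_
        return float(np.sum(t * z + np.logaddexp(0.0, -z)))

    val = objective(a, b)
    for _ in range(max_iter):
        z = np.clip(a * f + b, -500, 500)
        p = 1.0 / (1.0 + np.exp(z))          # P(y=1) under the sigmoid
        w = p * (1.0 - p)
        d1 = t - p
        g_a = float(np.sum(f * d1))
        g_b = float(np.sum(d1))
        if abs(g_a) < 1e-9 and abs(g_b) < 1e-9:
            break
        h_aa = float(np.sum(f * f * w)) + sigma
        h_bb = float(np.sum(w)) + sigma
        h_ab = float(np.sum(f * w))
        det = h_aa * h_bb - h_ab * h_ab
        if det <= 0:
            break
        da = -(h_bb * g_a - h_ab * g_b) / det
        db = -(h_aa * g_b - h_ab * g_a) / det
        step = 1.0
        while step >= 1e-10:
            na, nb = a + step * da, b + step * db
            nv = objective(na, nb)
            if nv < val + 1e-12:
                a, b, val = na, nb, nv
                break
            step /= 2.0
        else:
            break
    return float(a), float(b)


@dataclass(frozen=True)
class SplitProtocol:
    """Train/test split and cross-validation protocol."""

    train_fraction: float = 2.0 / 3.0
    cv_folds: int = 3
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _stratified_split(y, fraction, rng, stratified=True):
    n = len(y)
    idx = np.arange(n)
    if stratified:
        train = []
        for cls in np.unique(y):
            members = idx[y == cls]
            members = members[rng.permutation(len(members))]
            k = int(round(fraction * len(members)))
            train.append(members[:k])
        train_idx = np.sort(np.concatenate(train))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:int(round(fraction * n))])
    test_idx = np.setdiff1d(idx, train_idx)
    return train_idx, test_idx


def _stratified_folds(y, k, rng):
    n = len(y)
    folds = [[] for _ in range(k)]
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        members = members[rng.permutation(len(members))]
        for i, m in enumerate(members):
            folds[i % k].append(m)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _features_and_labels(staged, baseline_year, comparison_year,
                         final_year, outcome_rule, encoding="ordinal"):
    pairs = year_pair(staged, baseline_year, comparison_year)
    finals = staged.loc[staged["year"] == final_year,
                        ["subject_id", "category"]] \
        .set_index("subject_id")["category"]
    pairs = pairs[pairs["subject_id"].isin(finals.index)]
    if pairs.empty:
        raise ValueError("no complete cases with outcome data")
    y = np.array([1 if outcome(PrognosticCategory(int(c0)),
                               PrognosticCategory(int(finals[sid])),
                               outcome_rule) else -1
                  for sid, c0 in zip(pairs["subject_id"], pairs["cat0"])])
    raw = pairs[["cat0", "cat1"]].to_numpy(dtype=float)
    if encoding == "ordinal":
        X = raw
    elif encoding == "onehot":
        X = np.zeros((len(raw), 8))
        X[np.arange(len(raw)), raw[:, 0].astype(int)] = 1.0
        X[np.arange(len(raw)), 4 + raw[:, 1].astype(int)] = 1.0
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return X, y, pairs["subject_id"].to_numpy()


def run_model_year(staged: pd.DataFrame, baseline_year: int,
                   comparison_year: int,
                   protocol: SplitProtocol | None = None,
                   C: float = 1.0, gamma: float | None = None,
                   final_year: int | None = None,
                   outcome_rule: str = "very_high_at_end",
                   encoding: str = "ordinal",
                   ) -> tuple[float, float, SVMModel]:
    """Train and evaluate one year-pair SVM model.

    Features are the prognostic categories at ``baseline_year`` and
    ``comparison_year``; the label is the study outcome judged against
    ``final_year`` (default: last staged year).  Returns
    ``(training_error, test_error, model)`` where the training error is
    the mean 3-fold CV misclassification rate on the 2/3 training split
    and the test error is measured on the held-out 1/3.  The returned
    model is trained on the full training split and Platt-calibrated on
    its decision values.
    """
    protocol = protocol or SplitProtocol()
    if final_year is None:
        final_year = int(staged["year"].max())
    X, y, _ = _features_and_labels(staged, baseline_year, comparison_year,
                                   final_year, outcome_rule, encoding)
    rng = np.random.default_rng(protocol.seed)
    train_idx, test_idx = _stratified_split(
        y, protocol.train_fraction, rng, protocol.stratified)
    Xtr, ytr = X[train_idx], y[train_idx]
    Xte, yte = X[test_idx], y[test_idx]

    folds = _stratified_folds(ytr, protocol.cv_folds, rng)
    cv_errors = []
    for held in folds:
        mask = np.ones(len(ytr), dtype=bool)
        mask[held] = False
        m = smo_train(Xtr[mask], ytr[mask], C=C, gamma=gamma)
        cv_errors.append(float(np.mean(m.predict(Xtr[held]) != ytr[held])))
    training_error = float(np.mean(cv_errors))

    model = smo_train(Xtr, ytr, C=C, gamma=gamma)
    a, b = platt_calibrate(model.decision_function(Xtr), ytr)
    model.platt_a, model.platt_b = a, b
    test_error = float(np.mean(model.predict(Xte) != yte))
    return training_error, test_error, model


def possibility_heatmap(model: SVMModel, encoding: str = "ordinal",
                        ) -> np.ndarray:
    """4 x 4 grid of calibrated outcome possibilities.

    Cell [i, j] is the Platt probability at baseline category i and
    comparison-year category j (0 = low ... 3 = very high).
    """
    combos = np.array([[i, j] for i in range(4) for j in range(4)],
                      dtype=float)
    if encoding == "onehot":
        X = np.zeros((16, 8))
        X[np.arange(16), combos[:, 0].astype(int)] = 1.0
        X[np.arange(16), 4 + combos[:, 1].astype(int)] = 1.0
    else:
        X = combos
    return model.predict_possibility(X).reshape(4, 4)


# ---------------------------------------------------------------------------
# Model / Results wrappers


class RiskSVM:
    """Risk-aggravation SVM over a staged cohort, statsmodels-style.

    Built from a staged cohort table and a (baseline, comparison) year
    pair; ``fit()`` runs the split/CV protocol and returns a results
    object carrying errors, the trained model and the possibility grid.
    """

    def __init__(self, staged: pd.DataFrame, baseline_year: int,
                 comparison_year: int, final_year: int | None = None,
                 protocol: SplitProtocol | None = None,
                 C: float = 1.0, gamma: float | None = None,
                 outcome_rule: str = "very_high_at_end",
                 encoding: str = "ordinal"):
        self.staged = staged
        self.baseline_year = baseline_year
        self.comparison_year = comparison_year
        self.final_year = final_year
        self.protocol = protocol or SplitProtocol()
        self.C = C
        self.gamma = gamma
        self.outcome_rule = outcome_rule
        self.encoding = encoding

    def fit(self) -> "RiskSVMResults":
        tr, te, model = run_model_year(
            self.staged, self.baseline_year, self.comparison_year,
            self.protocol, self.C, self.gamma, self.final_year,
            self.outcome_rule, self.encoding)
        grid = possibility_heatmap(model, self.encoding)
        return RiskSVMResults(self, tr, te, model, grid)


@dataclass
class RiskSVMResults:
    model_spec: RiskSVM
    training_error: float
    test_error: float
    svm: SVMModel
    possibility_grid: np.ndarray

    def summary(self) -> str:
        ms = self.model_spec
        lines = [
            f"SVM model {ms.baseline_year} + {ms.comparison_year} "
            f"(RBF C-SVC, Platt-calibrated)",
            f"  C = {ms.C}, gamma = {self.svm.gamma:.6g}, "
            f"support vectors = {len(self.svm.support_vectors)}",
            f"  training error (mean {ms.protocol.cv_folds}-fold CV): "
            f"{self.training_error:.7f}",
            f"  test error (held-out {1 - ms.protocol.train_fraction:.0%}): "
            f"{self.test_error:.7f}",
            "",
            "  possibility of outcome by (baseline, comparison) category:",
        ]
        cats = [c.name for c in PrognosticCategory]
        lines.append("           " + " ".join(f"{c:>10}" for c in cats))
        for i, row in enumerate(self.possibility_grid):
            lines.append(f"{cats[i]:>10} "
                         + " ".join(f"{v:10.3f}" for v in row))
        return "\n".join(lines)
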