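"""Classifiers: linear Twin SVM, kernel SVMs, LDA/QDA, ensemble random
under-sampling (ERUS) and stratified cross-validation.

The Twin SVM fits two non-parallel hyperplanes, one passing close to each
class while staying at least a margin away from the other; a test point
takes the class of the nearer plane.  Each plane solves a small convex QP:

    min_(w,b,q)  1/2 ||X_k w + eps_k 1 b||^2 + C_k eps_k 1'q
    s.t.         -(X_other w + eps_other 1 b) + q >= eps_other 1,  q >= 0

which reduces to the textbook formulation at eps_1 = eps_2 = 1.  The dual is
a box-constrained QP solved with L-BFGS-B; the primal matrix inversion uses
a small Tikhonov ridge (1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: classifier parameter defaults (the values at which each performed best)
DEFAULT_PARAMS = {
    "twinsvm": {"C1": 6.0, "C2": 6.14, "eps1": 0.2, "eps2": 0.1},
    "svm-linear": {"C": 4.0},
    "svm-poly": {"gamma": 0.9, "degree": 1, "C": 1.0},
    "svm-rbf": {"gamma": 0.05, "C": 4.0},
    "svm-sigmoid": {"gamma": 0.05, "coef0": 1.0, "C": 1.0},
    "lda": {},
    "qda": {},
}


def _box_qp(q_mat: np.ndarray, lin: np.ndarray, upper: float) -> np.ndarray:
    """Minimise 1/2 a'Qa - lin'a subject to 0 <= a <= upper."""
    n = len(lin)

    def fun(a):
        qa = q_mat @ a
        return 0.5 * a @ qa - lin @ a, qa - lin

    res = minimize(fun, np.full(n, min(upper, 1.0) / 2.0), jac=True,
                   method="L-BFGS-B", bounds=[(0.0, upper)] * n,
                   options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    return res.x


def _twin_plane(x_own, x_other, c, eps_own, eps_other, delta=1e-6):
    """Solve one Twin SVM QP; returns (w, b)."""
    g = np.column_stack([x_own, np.full(len(x_own), eps_own)])
    h = np.column_stack([x_other, np.full(len(x_other), eps_other)])
    gram = g.T @ g + delta * np.eye(g.shape[1])
    inv_ht = np.linalg.solve(gram, h.T)  # (d+1, n_other)
    q_mat = h @ inv_ht
    alpha = _box_qp(q_mat, np.full(len(x_other), eps_other), c * eps_own)
    u = -inv_ht @ alpha
    return u[:-1], float(u[-1])


@dataclass
class TwinSVM:
    """Linear Twin SVM binary classifier.

    Classes are taken from the sorted unique labels; ``classes_[0]`` is
    "class 1" (first plane).  Prediction assigns the class of the nearer
    hyperplane, distances normalised by ||w||.
    """

    C1: float = 6.0
    C2: float = 6.14
    eps1: float = 0.2
    eps2: float = 0.1
    delta: float = 1e-6

    def fit(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("TwinSVM is a binary classifier")
        if self.eps1 <= 0 or self.eps2 <= 0:
            raise ValueError("eps1 and eps2 must be positive")
        x1 = x[y == self.classes_[0]]
        x2 = x[y == self.classes_[1]]
        self.w1_, self.b1_ = _twin_plane(x1, x2, self.C1, self.eps1, self.eps2,
                                         self.delta)
        self.w2_, self.b2_ = _twin_plane(x2, x1, self.C2, self.eps2, self.eps1,
                                         self.delta)
        return self

    def _plane_distances(self, x):
        x = np.atleast_2d(np.asarray(x, float))
        d1 = np.abs(x @ self.w1_ + self.eps1 * self.b1_)
        d2 = np.abs(x @ self.w2_ + self.eps2 * self.b2_)
        n1 = max(np.linalg.norm(self.w1_), 1e-12)
        n2 = max(np.linalg.norm(self.w2_), 1e-12)
        return d1 / n1, d2 / n2

    def decision_function(self, x):
        """Positive favours class 2 (the second label)."""
        d1, d2 = self._plane_distances(x)
        return d2 - d1  # small d2 => near plane 2 => class 2... sign below

    def predict(self, x):
        d1, d2 = self._plane_distances(x)
        return np.where(d1 <= d2, self.classes_[0], self.classes_[1])


def make_classifier(name: str, params: dict | None = None):
    """Factory for the supported classifiers (fresh, unfitted estimator)."""
    p = dict(DEFAULT_PARAMS[name])
    if params:
        p.update(params)
    if name == "twinsvm":
        return TwinSVM(**p)
    if name == "svm-linear":
        return SVC(kernel="linear", **p)
    if name == "svm-poly":
        return SVC(kernel="poly", coef0=0.0, **p)
    if name == "svm-rbf":
        return SVC(kernel="rbf", **p)
    if name == "svm-sigmoid":
        return SVC(kernel="sigmoid", **p)
    if name == "lda":
        return LinearDiscriminantAnalysis(**p)
    if name == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=1e-6, **p)
    raise ValueError(f"unknown classifier {name!r}")


# ---------------------------------------------------------------------------
# ERUS: ensemble random under-sampling
# ---------------------------------------------------------------------------

@dataclass
class ERUSEnsemble:
    """Balanced-subset ensemble for class-imbalanced training.

    Each of ``B`` members trains on all minority samples plus an
    equal-sized majority subsample (without replacement within a member);
    prediction is by majority vote.  Balanced input degenerates to a single
    base classifier.
    """

    base_factory: object  # callable -> fresh classifier
    B: int = 11
    seed: int = 0

    def fit(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        counts = {c: int((y == c).sum()) for c in self.classes_}
        minority = min(counts, key=counts.get)
        majority = max(counts, key=counts.get)
        if counts[minority] == counts[majority]:
            self.members_ = [self.base_factory().fit(x, y)]
            return self
        rng = np.random.default_rng(self.seed)
        min_idx = np.nonzero(y == minority)[0]
        maj_idx = np.nonzero(y == majority)[0]
        self.members_ = []
        for _ in range(self.B):
            pick = rng.choice(maj_idx, size=len(min_idx), replace=False)
            idx = np.concatenate([min_idx, pick])
            self.members_.append(self.base_factory().fit(x[idx], y[idx]))
        return self

    def predict(self, x):
        votes = np.stack([m.predict(x) for m in self.members_])
        out = []
        for col in votes.T:
            vals, cnt = np.unique(col, return_counts=True)
            out.append(vals[np.argmax(cnt)])
        return np.asarray(out)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_accuracies: list
    confusion: dict  # pooled TP/FN/TN/FP, positive = second sorted class
    predictions: np.ndarray
    labels: np.ndarray

    @property
    def accuracy(self) -> float:
        c = self.confusion
        return (c["TP"] + c["TN"]) / max(sum(c.values()), 1)


def pooled_confusion(y_true, y_pred, positive) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return {
        "TP": int((pos_t & pos_p).sum()),
        "FN": int((pos_t & ~pos_p).sum()),
        "TN": int((~pos_t & ~pos_p).sum()),
        "FP": int((~pos_t & pos_p).sum()),
    }


def cross_validate(values, labels, classifier_factory, k: int = 5,
                   seed: int = 0, standardize: bool = True,
                   positive=None) -> CVResult:
    """Stratified k-fold CV with leak-free per-fold standardisation.

    ``classifier_factory`` returns a fresh estimator per fold (so ERUS or
    any resampling happens inside the training fold only).
    """
    x = np.asarray(values, float)
    y = np.asarray(labels)
    if positive is None:
        positive = np.unique(y)[-1]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    fold_acc = []
    for tr, te in skf.split(x, y):
        xtr, xte = x[tr], x[te]
        if standardize:
            mu = xtr.mean(axis=0)
            sd = xtr.std(axis=0)
            sd[sd == 0] = 1.0
            xtr = (xtr - mu) / sd
            xte = (xte - mu) / sd
        model = classifier_factory()
        model.fit(xtr, y[tr])
        p = model.predict(xte)
        preds[te] = p
        fold_acc.append(float((p == y[te]).mean()))
    return CVResult(
        fold_accuracies=fold_acc,
        confusion=pooled_confusion(y, preds, positive),
        predictions=preds,
        labels=y,
    )
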