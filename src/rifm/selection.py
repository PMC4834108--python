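"""Two-stage feature selection.

Stage 1 keeps features whose class difference is statistically significant
(per-column two-sided Welch t-test, p <= alpha, no multiplicity correction).
Stage 2 is greedy wrapper forward selection: at each step the feature that
maximises the mean stratified k-fold criterion — ROC AUC of linear
discriminant scores, LDA accuracy, or QDA accuracy — is added, until the
improvement drops below a tolerance or a feature cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold


def significance_filter(values: np.ndarray, labels: np.ndarray,
                        alpha: float = 0.05, test: str = "welch") -> np.ndarray:
    """Indices of columns with two-sided p <= alpha between the classes.

    ``test`` is ``"welch"`` (two-sample t, unequal variances) or
    ``"mannwhitney"``.  Columns with undefined statistics (constant in both
    classes) are dropped.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("significance filter needs exactly two classes")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 samples per class")
    if test == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = sps.ttest_ind(a, b, equal_var=False, axis=0)
    elif test == "mannwhitney":
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = sps.mannwhitneyu(a, b, axis=0)
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.asarray(p)
    return np.nonzero(np.nan_to_num(p, nan=1.0) <= alpha)[0]


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formulation,
    which handles ties by midranks."""
    scores = np.asarray(scores, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("AUC needs both classes present")
    pos = y == classes.max() if classes.dtype.kind in "biuf" else y == classes[1]
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    ranks = sps.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# -- fast closed-form discriminants used inside the wrapper ------------------

def _lda_fit(x, y01, ridge=1e-6):
    m0 = x[y01 == 0].mean(axis=0)
    m1 = x[y01 == 1].mean(axis=0)
    d0 = x[y01 == 0] - m0
    d1 = x[y01 == 1] - m1
    cov = (d0.T @ d0 + d1.T @ d1) / len(x)
    cov = cov + ridge * np.trace(cov) / max(len(cov), 1) * np.eye(x.shape[1])
    w = np.linalg.solve(cov, m1 - m0)
    thresh = 0.5 * (m0 + m1) @ w + np.log(
        max((y01 == 0).sum(), 1) / max((y01 == 1).sum(), 1)
    )
    return w, thresh


def _lda_scores(xtr, ytr, xte):
    w, thresh = _lda_fit(xtr, ytr)
    return xte @ w - thresh


def _qda_predict(xtr, ytr, xte, ridge=1e-6):
    out = np.zeros((len(xte), 2))
    for c in (0, 1):
        xc = xtr[ytr == c]
        mu = xc.mean(axis=0)
        d = xc - mu
        cov = d.T @ d / max(len(xc), 1)
        cov = cov + (ridge * np.trace(cov) / max(len(cov), 1) + 1e-12) * np.eye(
            xtr.shape[1]
        )
        sign, logdet = np.linalg.slogdet(cov)
        diff = xte - mu
        maha = np.einsum("ij,ij->i", diff @ np.linalg.inv(cov), diff)
        prior = np.log(max(len(xc), 1) / len(xtr))
        out[:, c] = -0.5 * (logdet + maha) + prior
    return (out[:, 1] > out[:, 0]).astype(int)


@dataclass
class SelectionResult:
    """Wrapper-selection outcome: ordered indices and the criterion trace."""

    selected: list
    criterion: str
    trace: list
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "selected": [int(i) for i in self.selected],
            "criterion": self.criterion,
            "trace": [float(t) for t in self.trace],
            "k": self.k,
            "seed": self.seed,
        }


def _fold_criterion(x, y01, folds, criterion):
    vals = []
    for tr, te in folds:
        if criterion == "auc":
            s = _lda_scores(x[tr], y01[tr], x[te])
            vals.append(auc(s, y01[te]))
        elif criterion == "lda":
            s = _lda_scores(x[tr], y01[tr], x[te])
            vals.append(float(((s > 0).astype(int) == y01[te]).mean()))
        elif criterion == "qda":
            pred = _qda_predict(x[tr], y01[tr], x[te])
            vals.append(float((pred == y01[te]).mean()))
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
    return float(np.mean(vals))


def wrapper_select(values: np.ndarray, labels: np.ndarray,
                   criterion: str = "auc", k: int = 5, seed: int = 0,
                   tol: float = 1e-3, max_features: int = 30,
                   min_features: int = 5) -> SelectionResult:
    """Greedy forward selection maximising the mean k-fold criterion.

    Folds are stratified and fixed by ``seed``; selection is deterministic.
    The trace records the criterion after each accepted feature and is
    non-decreasing up to the stopping iteration.

    Selection stops when the best improvement falls below ``tol`` — but not
    before ``min_features`` have been accepted (capped by ``max_features``
    and the column count).  On small samples the fold criterion saturates
    quickly (a single lucky column can separate thirty training eyes), and
    a one-feature classifier is fragile; the floor keeps accepting the best
    candidates, breaking criterion ties by the per-column Welch statistic,
    so the final set mixes the strongest complementary signals.
    """
    x = np.asarray(values, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("wrapper selection needs exactly two classes")
    y01 = (y == classes[1]).astype(int)
    # every test fold must contain both classes for AUC to exist
    k_eff = int(min(k, np.bincount(y01).min()))
    if k_eff < 2:
        raise ValueError("need at least 2 samples per class for CV folds")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(x, y01)]
    # per-column |t| used only to order criterion ties
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat, _ = sps.ttest_ind(x[y01 == 0], x[y01 == 1], equal_var=False,
                                 axis=0)
    tstat = np.abs(np.nan_to_num(np.atleast_1d(tstat), nan=0.0))
    selected: list = []
    trace: list = []
    best_so_far = -np.inf
    remaining = list(range(x.shape[1]))
    floor = min(min_features, max_features, x.shape[1])
    while remaining and len(selected) < max_features:
        scores = np.full(len(remaining), -np.inf)
        for idx, j in enumerate(remaining):
            cols = selected + [j]
            scores[idx] = _fold_criterion(x[:, cols], y01, folds, criterion)
        top = scores.max()
        tied = np.nonzero(scores >= top - 1e-12)[0]
        best_idx = int(tied[np.argmax(tstat[[remaining[i] for i in tied]])])
        if trace and top - best_so_far < tol and len(selected) >= floor:
            break
        selected.append(remaining.pop(best_idx))
        trace.append(float(top))
        best_so_far = top
    return SelectionResult(selected=selected, criterion=criterion,
                           trace=trace, k=k, seed=seed)
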