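import numpy as np
import pytest

from rifm.classify import (
    DEFAULT_PARAMS,
    ERUSEnsemble,
    TwinSVM,
    cross_validate,
    make_classifier,
    pooled_confusion,
)

from oracles import twin_plane_activeset


@pytest.fixture
def parallel_lines():
    # class 1 on y = x, class 2 on y = x + 2
    x1 = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
    x2 = np.array([[0.0, 2.0], [1.0, 3.0], [2.0, 4.0]])
    return x1, x2


class TestTwinSVM:
    def test_plane_one_passes_through_class_one(self, parallel_lines):
        x1, x2 = parallel_lines
        x = np.vstack([x1, x2])
        y = np.array([1, 1, 1, 2, 2, 2])
        m = TwinSVM().fit(x, y)
        vals = np.abs(x1 @ m.w1_ + m.eps1 * m.b1_) / np.linalg.norm(m.w1_)
        assert np.all(vals < 0.1)

    def test_points_on_lines_classified(self, parallel_lines):
        x1, x2 = parallel_lines
        x = np.vstack([x1, x2])
        y = np.array([1, 1, 1, 2, 2, 2])
        m = TwinSVM().fit(x, y)
        assert m.predict([[0.5, 0.5]])[0] == 1
        assert m.predict([[0.5, 2.5]])[0] == 2

    def test_matches_activeset_oracle(self, parallel_lines):
        x1, x2 = parallel_lines
        p = DEFAULT_PARAMS["twinsvm"]
        m = TwinSVM().fit(np.vstack([x1, x2]), np.array([1, 1, 1, 2, 2, 2]))
        w_ref, b_ref = twin_plane_activeset(x1, x2, p["C1"], p["eps1"], p["eps2"])
        assert np.allclose(m.w1_, w_ref, atol=1e-6)
        assert np.allclose(m.b1_, b_ref, atol=1e-6)

    def test_swapping_classes_swaps_planes(self, parallel_lines):
        x1, x2 = parallel_lines
        x = np.vstack([x1, x2])
        m = TwinSVM(C1=4.0, C2=4.0, eps1=0.3, eps2=0.3)
        a = m.fit(x, np.array([1, 1, 1, 2, 2, 2]))
        w1a, b1a = a.w1_.copy(), a.b1_
        b = TwinSVM(C1=4.0, C2=4.0, eps1=0.3, eps2=0.3).fit(
            x, np.array([2, 2, 2, 1, 1, 1])
        )
        assert np.allclose(w1a, b.w2_, atol=1e-6)
        assert np.allclose(b1a, b.b2_, atol=1e-6)

    def test_agrees_with_linear_svm_on_separated_gaussians(self):
        diffs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = np.vstack([r.normal(-2, 1, (30, 3)), r.normal(2, 1, (30, 3))])
            y = np.repeat([0, 1], 30)
            xt = np.vstack([r.normal(-2, 1, (25, 3)), r.normal(2, 1, (25, 3))])
            yt = np.repeat([0, 1], 25)
            acc_t = (TwinSVM().fit(x, y).predict(xt) == yt).mean()
            acc_l = (make_classifier("svm-linear").fit(x, y).predict(xt) == yt).mean()
            diffs.append(abs(acc_t - acc_l))
        assert np.mean(diffs) <= 0.02

    def test_binary_only(self, rng):
        with pytest.raises(ValueError):
            TwinSVM().fit(rng.normal(size=(9, 2)), np.array([0, 1, 2] * 3))


class TestKernelSVMs:
    def test_poly_degree_one_matches_linear_boundary(self, rng):
        x = np.vstack([rng.normal(-1.5, 1, (40, 2)), rng.normal(1.5, 1, (40, 2))])
        y = np.repeat([0, 1], 40)
        xt = rng.normal(0, 2, (60, 2))
        lin = make_classifier("svm-linear", {"C": 1.0}).fit(x, y)
        poly = make_classifier("svm-poly", {"gamma": 1.0, "degree": 1, "C": 1.0}).fit(x, y)
        assert (lin.predict(xt) == poly.predict(xt)).mean() >= 0.95

    def test_dual_constraints_hold(self, rng):
        x = np.vstack([rng.normal(-1, 1, (20, 2)), rng.normal(1, 1, (20, 2))])
        y = np.repeat([-1, 1], 20)
        m = make_classifier("svm-rbf").fit(x, y)
        alpha = np.abs(m.dual_coef_).ravel()
        assert np.all(alpha <= DEFAULT_PARAMS["svm-rbf"]["C"] + 1e-6)
        assert abs(m.dual_coef_.sum()) < 1e-6

    def test_separable_perfect_training_accuracy(self):
        x = np.array([[0.0, 0.0], [2.0, 2.0]])
        y = np.array([0, 1])
        m = make_classifier("svm-linear").fit(x, y)
        assert (m.predict(x) == y).all()


class TestDiscriminants:
    def test_lda_boundary_perpendicular_midpoint(self, rng):
        x = np.vstack([rng.normal(-2, 1, (400, 2)), rng.normal(2, 1, (400, 2))])
        y = np.repeat([0, 1], 400)
        m = make_classifier("lda").fit(x, y)
        # decision value at the midpoint of the class means is ~0
        mid = 0.5 * (x[y == 0].mean(axis=0) + x[y == 1].mean(axis=0))
        assert abs(m.decision_function([mid])[0]) < 0.2

    def test_qda_equals_lda_under_equal_covariance(self, rng):
        x = np.vstack([rng.normal(-2, 1, (200, 2)), rng.normal(2, 1, (200, 2))])
        y = np.repeat([0, 1], 200)
        xt = rng.normal(0, 2, (100, 2))
        agree = (make_classifier("lda").fit(x, y).predict(xt)
                 == make_classifier("qda").fit(x, y).predict(xt)).mean()
        assert agree >= 0.9

    def test_identical_means_near_chance(self, rng):
        x = rng.normal(size=(200, 4))
        y = np.repeat([0, 1], 100)
        xt = rng.normal(size=(200, 4))
        yt = np.repeat([0, 1], 100)
        acc = (make_classifier("lda").fit(x, y).predict(xt) == yt).mean()
        assert 0.35 <= acc <= 0.65


class TestERUS:
    def test_balanced_input_single_member(self, rng):
        x = rng.normal(size=(20, 2))
        y = np.repeat([0, 1], 10)
        e = ERUSEnsemble(lambda: make_classifier("lda"), B=7, seed=0).fit(x, y)
        assert len(e.members_) == 1

    def test_each_subset_balanced(self, rng):
        x = rng.normal(size=(100, 2))
        y = np.array([0] * 80 + [1] * 20)
        calls = []

        class Recorder:
            def fit(self, xs, ys):
                calls.append(np.bincount(ys))
                return self

        ERUSEnsemble(Recorder, B=11, seed=0).fit(x, y)
        assert len(calls) == 11
        for c in calls:
            assert c[0] == c[1] == 20

    def test_improves_minority_recall(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(-1, 1.2, (90, 2)), rng.normal(1, 1.2, (12, 2))])
        y = np.array([0] * 90 + [1] * 12)
        xt = np.vstack([rng.normal(-1, 1.2, (50, 2)), rng.normal(1, 1.2, (50, 2))])
        yt = np.repeat([0, 1], 50)
        base = make_classifier("lda").fit(x, y).predict(xt)
        erus = ERUSEnsemble(lambda: make_classifier("lda"), B=11, seed=1).fit(
            x, y).predict(xt)
        rec = lambda p: ((p == 1) & (yt == 1)).sum() / 50
        assert rec(erus) >= rec(base)


class TestCrossValidate:
    def test_leave_one_out_fold_sizes(self, rng):
        x = rng.normal(size=(6, 2))
        y = np.array([0, 1, 0, 1, 0, 1])
        res = cross_validate(x, y, lambda: make_classifier("lda"), k=3, seed=0)
        assert sum(c for c in res.confusion.values()) == 6

    def test_deterministic(self, rng):
        x = rng.normal(size=(30, 3))
        y = np.repeat([0, 1], 15)
        a = cross_validate(x, y, lambda: make_classifier("qda"), k=5, seed=2)
        b = cross_validate(x, y, lambda: make_classifier("qda"), k=5, seed=2)
        assert a.confusion == b.confusion
        assert a.fold_accuracies == b.fold_accuracies

    def test_pooled_confusion_counts(self):
        c = pooled_confusion([1, 1, 0, 0], [1, 0, 0, 1], positive=1)
        assert c == {"TP": 1, "FN": 1, "TN": 1, "FP": 1}
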