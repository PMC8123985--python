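import json

import numpy as np
import pytest

from pscpred.svm_eval import (
    EvalReport,
    SvmParams,
    grid_search_params,
    jackknife_evaluate,
    make_jackknife_eval,
    metrics_from_confusion,
)


def blobs(n_per_class, n_classes, sep, seed, d=5):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        center = np.zeros(d)
        center[c % d] = sep
        X.append(rng.normal(size=(n_per_class, d)) + center)
        y += [f"c{c}"] * n_per_class
    return np.vstack(X), y


class TestSvmParams:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            SvmParams(C=0.0, gamma=1.0)

    def test_dyadic_grid_membership(self):
        X, y = blobs(15, 2, 6.0, 0)
        params = grid_search_params(X, y, seed=0, exponents=range(-4, 5))
        exps = {2.0**i for i in range(-4, 5)}
        assert params.C in exps and params.gamma in exps


class TestGridSearch:
    def test_separable_blobs_reach_perfect_cv(self):
        X, y = blobs(20, 2, 8.0, 1)
        params = grid_search_params(X, y, seed=0)
        # independently re-score the returned params with the same CV scheme
        from sklearn.model_selection import StratifiedKFold
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        correct = 0
        for tr, te in skf.split(X, y):
            clf = make_pipeline(
                StandardScaler(), SVC(C=params.C, gamma=params.gamma)
            )
            clf.fit(X[tr], np.asarray(y)[tr])
            correct += (clf.predict(X[te]) == np.asarray(y)[te]).sum()
        assert correct == len(y)

    def test_constant_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError):
            grid_search_params(X, ["a"] * 20, seed=0)

    def test_determinism(self):
        X, y = blobs(10, 3, 3.0, 2)
        p1 = grid_search_params(X, y, seed=7, exponents=range(-3, 4))
        p2 = grid_search_params(X, y, seed=7, exponents=range(-3, 4))
        assert p1 == p2

    def test_small_class_reduces_folds_with_warning(self):
        X, y = blobs(4, 2, 5.0, 3)
        with pytest.warns(UserWarning, match="fold"):
            grid_search_params(X, y, seed=0, exponents=range(-2, 3))


class TestMetrics:
    def test_formula_arithmetic(self):
        conf = np.array([[9, 1], [1, 9]])
        rep = metrics_from_confusion(conf, ["a", "b"])
        assert rep.sens["a"] == pytest.approx(0.9)
        assert rep.spec["a"] == pytest.approx(0.9)
        assert rep.f1["a"] == pytest.approx(0.9)

    def test_perfect_diagonal(self):
        rep = metrics_from_confusion(np.diag([3, 4, 5, 6]), list("abcd"))
        for cls in "abcd":
            assert rep.sens[cls] == 1.0
            assert rep.spec[cls] == 1.0
            assert rep.f1[cls] == 1.0
        assert rep.overall_accuracy == 1.0

    def test_zero_over_zero_flagged(self):
        conf = np.array([[0, 0], [0, 5]])
        rep = metrics_from_confusion(conf, ["a", "b"])
        assert rep.sens["a"] == 0.0
        assert any("sens[a]" in f for f in rep.flags)

    def test_overall_is_weighted_mean_of_per_class(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            conf = rng.integers(0, 20, size=(4, 4))
            conf[0, 0] += 1  # avoid an all-zero matrix
            rep = metrics_from_confusion(conf, list("abcd"))
            sizes = conf.sum(axis=1)
            weighted = sum(
                rep.per_class_accuracy[c] * s
                for c, s in zip("abcd", sizes)
            ) / sizes.sum()
            assert rep.overall_accuracy == pytest.approx(weighted, abs=1e-12)
            # one-vs-rest bookkeeping identities
            assert np.trace(conf) == sum(
                rep.sens[c] * s for c, s in zip("abcd", sizes)
            ) == pytest.approx(np.trace(conf))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.array([[1, -1], [0, 2]]), ["a", "b"])


class TestJackknife:
    def test_well_separated_four_class(self):
        X, y = blobs(12, 4, 7.0, 4)
        report = jackknife_evaluate(X, y, SvmParams(C=4.0, gamma=0.125))
        assert report.overall_accuracy >= 0.95
        assert report.confusion.sum() == len(y)

    def test_minimal_bookkeeping(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 3))
        y = ["a", "b", "c", "d"]
        report = jackknife_evaluate(X, y, SvmParams(C=1.0, gamma=1.0))
        assert report.confusion.sum() == 4
        assert len(report.flags) >= 4  # every class is a flagged singleton

    def test_duplicated_separable_dataset_is_perfect(self):
        X, y = blobs(8, 3, 8.0, 6)
        X2 = np.vstack([X, X])
        y2 = y + y
        report = jackknife_evaluate(X2, y2, SvmParams(C=8.0, gamma=0.25))
        assert report.overall_accuracy == 1.0

    def test_report_json_round_trip(self, tmp_path):
        X, y = blobs(6, 2, 5.0, 7)
        report = jackknife_evaluate(X, y, SvmParams(C=2.0, gamma=0.5))
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = EvalReport.from_json(path)
        assert loaded.to_json_dict() == report.to_json_dict()
        # serialization is deterministic
        path2 = tmp_path / "report2.json"
        loaded.to_json(path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_eval_fn_returns_overall_accuracy(self):
        X, y = blobs(8, 2, 8.0, 8)
        fn = make_jackknife_eval(SvmParams(C=4.0, gamma=0.25))
        assert fn(X, y) == jackknife_evaluate(
            X, y, SvmParams(C=4.0, gamma=0.25)
        ).overall_accuracy
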