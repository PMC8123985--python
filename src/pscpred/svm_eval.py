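"""One-vs-one RBF-SVM classification, grid search and jackknife evaluation.

The SVM itself is scikit-learn's :class:`~sklearn.svm.SVC` (natively
one-vs-one for multiclass).  (C, gamma) are picked from the dyadic grid
2^-10 ... 2^10 by stratified 10-fold cross-validated overall accuracy;
evaluation is leave-one-out with per-fold standardization refit on the
training samples only.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from pscpred.assembly import FeatureMatrix
from pscpred.riforest import confusion_counts

_TIE_TOL = 1e-12

DEFAULT_EXPONENTS = tuple(range(-10, 11))


@dataclass(frozen=True)
class SvmParams:
    """RBF-SVM hyper-parameters."""

    C: float
    gamma: float
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")

    def to_json_dict(self) -> dict:
        return {"C": self.C, "gamma": self.gamma, "kernel": self.kernel}


def _values(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def grid_search_params(
    X,
    y: Sequence[Hashable],
    seed: int = 0,
    *,
    exponents: Sequence[int] = DEFAULT_EXPONENTS,
    n_folds: int = 10,
    standardize: bool = True,
) -> SvmParams:
    """(C, gamma) maximizing mean stratified-CV overall accuracy.

    Both parameters range over ``2**e`` for the integer exponents given.
    Ties go to the smallest C, then the smallest gamma.  If the rarest
    class has fewer members than ``n_folds`` the fold count is reduced
    (with a warning), never below 2.
    """
    Xv = _values(X)
    y = np.asarray(y, dtype=object)
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if len(classes) < 2:
        raise ValueError("grid search needs at least 2 classes")
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("every class needs >= 2 members for stratified CV")
    if min_count < n_folds:
        n_folds = max(2, min_count)
        warnings.warn(
            f"rarest class has {min_count} members; using {n_folds}-fold CV",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(Xv, y.astype(str)):
        Xtr, Xte = Xv[train_idx], Xv[test_idx]
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        folds.append((Xtr, y[train_idx], Xte, y[test_idx]))
    best: tuple[float, SvmParams] | None = None
    for ce in exponents:
        for ge in exponents:
            params = SvmParams(C=2.0**ce, gamma=2.0**ge)
            correct = total = 0
            for Xtr, ytr, Xte, yte in folds:
                clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
                clf.fit(Xtr, ytr.astype(str))
                correct += int((clf.predict(Xte) == yte.astype(str)).sum())
                total += len(yte)
            acc = correct / total
            if best is None or acc > best[0] + _TIE_TOL:
                best = (acc, params)
    return best[1]


@dataclass
class EvalReport:
    """Confusion matrix plus the derived per-class and overall metrics."""

    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = true class
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    sens: dict[str, float]
    spec: dict[str, float]
    f1: dict[str, float]
    flags: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": np.asarray(self.confusion).tolist(),
            "per_class_accuracy": dict(self.per_class_accuracy),
            "overall_accuracy": self.overall_accuracy,
            "sens": dict(self.sens),
            "spec": dict(self.spec),
            "f1": dict(self.f1),
            "flags": list(self.flags),
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "EvalReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            classes=tuple(d["classes"]),
            confusion=np.array(d["confusion"], dtype=int),
            per_class_accuracy=d["per_class_accuracy"],
            overall_accuracy=d["overall_accuracy"],
            sens=d["sens"],
            spec=d["spec"],
            f1=d["f1"],
            flags=d.get("flags", []),
        )

    def confusion_to_csv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("true\\pred," + ",".join(self.classes) + "\n")
            for cls, row in zip(self.classes, np.asarray(self.confusion)):
                fh.write(cls + "," + ",".join(str(int(v)) for v in row) + "\n")


def metrics_from_confusion(
    confusion: np.ndarray, classes: Sequence[str]
) -> EvalReport:
    """One-vs-rest Sens/Spec/F1 and accuracies from a count matrix.

    0/0 ratios are reported as 0 and flagged.
    """
    confusion = np.asarray(confusion, dtype=int)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(confusion < 0):
        raise ValueError("confusion counts must be non-negative")
    c = confusion.shape[0]
    if len(classes) != c:
        raise ValueError("one class name per confusion row required")
    n = int(confusion.sum())
    flags: list[str] = []

    def ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            flags.append(f"{what}: 0/0 reported as 0")
            return 0.0
        return num / den

    per_acc, sens, spec, f1 = {}, {}, {}, {}
    for i, cls in enumerate(classes):
        tp = int(confusion[i, i])
        fn = int(confusion[i].sum()) - tp
        fp = int(confusion[:, i].sum()) - tp
        tn = n - tp - fn - fp
        per_acc[cls] = ratio(tp, tp + fn, f"accuracy[{cls}]")
        sens[cls] = ratio(tp, tp + fn, f"sens[{cls}]")
        spec[cls] = ratio(tn, fp + tn, f"spec[{cls}]")
        f1[cls] = ratio(2 * tp, 2 * tp + fn + fp, f"f1[{cls}]")
    overall = ratio(float(np.trace(confusion)), float(n), "overall_accuracy")
    return EvalReport(
        classes=tuple(classes),
        confusion=confusion,
        per_class_accuracy=per_acc,
        overall_accuracy=overall,
        sens=sens,
        spec=spec,
        f1=f1,
        flags=flags,
    )


def jackknife_evaluate(
    X,
    y: Sequence[Hashable],
    params: SvmParams,
    *,
    standardize: bool = True,
    classes: Sequence[str] | None = None,
) -> EvalReport:
    """Leave-one-out evaluation: n fits, each predicting its held-out sample.

    Standardization statistics are refit on each fold's n-1 training
    samples.  A singleton class still gets predicted (its fold trains
    without the class) and is flagged in the report.
    """
    Xv = _values(X)
    y = np.asarray([str(v) for v in y], dtype=object)
    n = len(y)
    if n < 4:
        raise ValueError("jackknife needs at least 4 samples")
    if len(set(y.tolist())) < 2:
        raise ValueError("need at least 2 classes")
    if classes is None:
        classes = sorted(set(y.tolist()))
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, Xte = Xv[mask], Xv[i : i + 1]
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
        clf.fit(Xtr, y[mask])
        preds.append(str(clf.predict(Xte)[0]))
    confusion = confusion_counts(y.tolist(), preds, list(classes))
    report = metrics_from_confusion(confusion, classes)
    for cls in classes:
        if int((y == cls).sum()) == 1:
            report.flags.append(f"class {cls!r} has a single sample")
    return report


def jackknife_evaluate_nested(
    X,
    y: Sequence[Hashable],
    seed: int = 0,
    *,
    exponents: Sequence[int] = DEFAULT_EXPONENTS,
    n_folds: int = 10,
    standardize: bool = True,
    classes: Sequence[str] | None = None,
) -> EvalReport:
    """Leave-one-out with (C, gamma) re-tuned inside every fold.

    Avoids the tuning leak of grid-search-then-jackknife at the price of
    n full grid searches; intended for small problems.
    """
    Xv = _values(X)
    y = np.asarray([str(v) for v in y], dtype=object)
    n = len(y)
    if n < 4:
        raise ValueError("jackknife needs at least 4 samples")
    if classes is None:
        classes = sorted(set(y.tolist()))
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        params = grid_search_params(
            Xv[mask],
            y[mask],
            seed=seed,
            exponents=exponents,
            n_folds=n_folds,
            standardize=standardize,
        )
        Xtr, Xte = Xv[mask], Xv[i : i + 1]
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf = SVC(C=params.C, gamma=params.gamma, kernel="rbf")
        clf.fit(Xtr, y[mask])
        preds.append(str(clf.predict(Xte)[0]))
    confusion = confusion_counts(y.tolist(), preds, list(classes))
    return metrics_from_confusion(confusion, classes)


def make_jackknife_eval(params: SvmParams, *, standardize: bool = True):
    """eval_fn for subset selection: jackknife overall accuracy."""

    def eval_fn(X, y) -> float:
        return jackknife_evaluate(
            X, y, params, standardize=standardize
        ).overall_accuracy

    return eval_fn
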