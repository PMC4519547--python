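"""Two-class subsequent-memory decoding.

A linear soft-margin SVM discriminates remembered from forgotten trials.
Because whole-brain feature spaces are much larger than the trial count,
each training fold first scores every voxel with a one-way two-group
ANOVA F statistic (remembered vs forgotten) and keeps the top k = 100;
selection is strictly nested — recomputed inside every cross-validation
fold from the training portion only. Validation is leave-one-run-out
within subject (3 folds) or leave-one-subject-out across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .preprocess import SampleSet

DEFAULT_K = 100
DEFAULT_C = 1.0

LEAVE_ONE_RUN_OUT = "leave_one_run_out"
LEAVE_ONE_SUBJECT_OUT = "leave_one_subject_out"


@dataclass
class FoldPlan:
    folds: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)
    scheme: str

    def __post_init__(self) -> None:
        tested: list[int] = []
        for train, test in self.folds:
            if len(test) == 0:
                raise ValueError("fold with empty test set")
            if np.intersect1d(train, test).size:
                raise ValueError("train and test overlap")
            tested.extend(test.tolist())
        if len(tested) != len(set(tested)):
            raise ValueError("a sample is tested more than once")


def make_fold_plan(samples: SampleSet, scheme: str) -> FoldPlan:
    """Group folds by run (within-subject) or by subject (cross-subject)."""
    if scheme == LEAVE_ONE_RUN_OUT:
        groups = [
            (s, r) for s, r in zip(samples.subjects.tolist(), samples.runs.tolist())
        ]
    elif scheme == LEAVE_ONE_SUBJECT_OUT:
        groups = samples.subjects.tolist()
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    keys = sorted(set(groups), key=str)
    arr = np.array([keys.index(g) for g in groups])
    folds = []
    for i, _ in enumerate(keys):
        test = np.flatnonzero(arr == i)
        train = np.flatnonzero(arr != i)
        folds.append((train, test))
    return FoldPlan(folds=folds, scheme=scheme)


@dataclass
class ConfusionMatrix:
    """Counts with remembered as the positive class."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


def precision(cm: ConfusionMatrix) -> float:
    """True-positive accuracy: tp / (tp + fp)."""
    if cm.tp + cm.fp == 0:
        raise ZeroDivisionError("no positive predictions; precision undefined")
    return cm.tp / (cm.tp + cm.fp)


def f_score(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and sensitivity: 2*tp / (2*tp + fp + fn)."""
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        raise ZeroDivisionError("no positive labels or predictions; F undefined")
    return 2 * cm.tp / denom


@dataclass
class LinearModel:
    weights: np.ndarray
    bias: float
    selected_voxels: np.ndarray

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.selected_voxels] @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """True where the decision function favors the remembered class."""
        return self.decision(X) > 0


@dataclass
class DecodingResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: ConfusionMatrix
    scheme: str
    feature_k: int | None


def anova_f_per_voxel(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way two-group ANOVA F per feature, df = (1, n-2).

    Features with zero within-group variance but distinct group means get a
    +inf sentinel (always selected); features that are globally constant
    score 0.
    """
    y = np.asarray(y, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per class for ANOVA")
    g1, g0 = X[y], X[~y]
    m1, m0 = g1.mean(axis=0), g0.mean(axis=0)
    grand = X.mean(axis=0)
    ssb = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    ssw = ((g1 - m1) ** 2).sum(axis=0) + ((g0 - m0) ** 2).sum(axis=0)
    df_w = n1 + n0 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / df_w)
    f = np.where(ssw == 0, np.where(ssb > 0, np.inf, 0.0), f)
    return f


def select_top_k(f_values: np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """Indices of the k largest F values, ties broken toward lower indices."""
    n = len(f_values)
    if k > n:
        warnings.warn(f"k={k} exceeds {n} features; clamping", stacklevel=2)
        k = n
    # sort by (-F, index); stable and deterministic
    order = np.lexsort((np.arange(n), -np.asarray(f_values, dtype=float)))
    return np.sort(order[:k])


def fit_linear_classifier(
    X: np.ndarray,
    y: np.ndarray,
    selected: np.ndarray | None = None,
    C: float = DEFAULT_C,
) -> LinearModel:
    """Soft-margin linear SVM on the selected features (fixed C, no tuning)."""
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training data contains a single class")
    if selected is None:
        selected = np.arange(X.shape[1])
    # tight solver tolerance: the fitted boundary must not depend on the
    # incidental ordering of training samples
    clf = SVC(kernel="linear", C=C, tol=1e-9)
    clf.fit(X[:, selected], y.astype(int))
    w = np.asarray(clf.coef_).ravel()
    return LinearModel(weights=w, bias=float(clf.intercept_[0]), selected_voxels=selected)


def cross_validate(
    samples: SampleSet,
    plan: FoldPlan,
    k: int | None = DEFAULT_K,
    C: float = DEFAULT_C,
    selection: str = "nested",
) -> DecodingResult:
    """Nested-selection cross-validated accuracy plus pooled confusion matrix.

    ``selection='nested'`` recomputes the ANOVA-F top-k inside each training
    fold (the correct procedure); ``'global'`` selects once on all data — a
    deliberate leakage mode kept for regression tests; ``'none'`` uses every
    feature (searchlight mode).
    """
    if selection not in ("nested", "global", "none"):
        raise ValueError(f"unknown selection mode {selection!r}")
    global_sel = None
    if selection == "global" and k is not None:
        global_sel = select_top_k(anova_f_per_voxel(samples.X, samples.y), k)
    fold_acc: list[float] = []
    cm = ConfusionMatrix()
    for train, test in plan.folds:
        if selection == "nested" and k is not None:
            f = anova_f_per_voxel(samples.X[train], samples.y[train])
            sel = select_top_k(f, k)
        elif selection == "global":
            sel = global_sel
        else:
            sel = np.arange(samples.n_features)
        model = fit_linear_classifier(samples.X[train], samples.y[train], sel, C=C)
        pred = model.predict(samples.X[test])
        truth = samples.y[test]
        fold_cm = ConfusionMatrix(
            tp=int((pred & truth).sum()),
            fp=int((pred & ~truth).sum()),
            fn=int((~pred & truth).sum()),
            tn=int((~pred & ~truth).sum()),
        )
        cm = cm + fold_cm
        fold_acc.append(fold_cm.accuracy)
    return DecodingResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(np.mean(fold_acc)),
        confusion=cm,
        scheme=plan.scheme,
        feature_k=k if selection != "none" else None,
    )


def within_subject_decode(
    subject_samples: dict[str, SampleSet],
    k: int | None = DEFAULT_K,
    C: float = DEFAULT_C,
) -> tuple[dict[str, DecodingResult], float]:
    """Leave-one-run-out decoding per subject; group value is the subject mean."""
    results = {}
    for sub, samples in subject_samples.items():
        plan = make_fold_plan(samples, LEAVE_ONE_RUN_OUT)
        results[sub] = cross_validate(samples, plan, k=k, C=C)
    mean = float(np.mean([r.mean_accuracy for r in results.values()]))
    return results, mean
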