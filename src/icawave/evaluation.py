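"""Classifier harness, subject-aware CV, imbalance metrics and paired tests.

Metrics follow the standard confusion-derived definitions, reported as
percentages; balanced accuracy (BAC) — the mean of recall and specificity —
is the primary score under class imbalance.  Cross-validation folds never
split one subject's beats between train and test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from icawave.records import AAMI_CLASSES

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    """One-vs-rest confusion counts for a named positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    tp = int(np.sum((y_true == positive_class) & (y_pred == positive_class)))
    fn = int(np.sum((y_true == positive_class) & (y_pred != positive_class)))
    fp = int(np.sum((y_true != positive_class) & (y_pred == positive_class)))
    tn = int(np.sum((y_true != positive_class) & (y_pred != positive_class)))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, recall, precision, specificity and BAC in percent.

    Undefined ratios (empty denominator) are reported as ``None`` — missing,
    not zero — so macro averages over small sets are not silently deflated.
    """
    if c.total <= 0:
        raise ValueError("empty confusion table")
    out: dict[str, float | None] = {
        "accuracy": 100.0 * (c.TP + c.TN) / c.total,
        "recall": 100.0 * c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None,
        "specificity": 100.0 * c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else None,
        "precision": 100.0 * c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None,
    }
    if out["recall"] is not None and out["specificity"] is not None:
        out["bac"] = (out["recall"] + out["specificity"]) / 2.0
    else:
        out["bac"] = None
    return out


@dataclass
class MetricsReport:
    """Per-class and macro confusion-derived metrics (percent)."""

    per_class: dict[str, dict[str, float | None]]
    macro: dict[str, float | None]
    n_per_class: dict[str, int]

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=None) -> "MetricsReport":
        y_true = np.asarray(y_true)
        if classes is None:
            classes = [c for c in AAMI_CLASSES if c in set(y_true)] or sorted(set(y_true))
        per_class = {c: metrics_from_counts(confusion(y_true, y_pred, c)) for c in classes}
        macro = {}
        for key in ("accuracy", "recall", "specificity", "precision", "bac"):
            vals = [m[key] for m in per_class.values() if m[key] is not None]
            macro[key] = float(np.mean(vals)) if vals else None
        n = {c: int(np.sum(y_true == c)) for c in classes}
        return cls(per_class=per_class, macro=macro, n_per_class=n)

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro": self.macro,
            "n_per_class": self.n_per_class,
        }


def metrics_report(y_true, y_pred, classes=None) -> MetricsReport:
    return MetricsReport.from_predictions(y_true, y_pred, classes)


# ---------------------------------------------------------------------------
# subject-aware stratified folds


@dataclass
class FoldPlan:
    """Partition of subjects into k folds; no subject appears twice."""

    folds: list[list[str]]
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.folds:
            if seen & set(f):
                raise ValueError("a subject appears in more than one fold")
            seen |= set(f)

    @property
    def k(self) -> int:
        return len(self.folds)


def make_folds(subjects, labels, k: int = 5, seed: int | None = None) -> FoldPlan:
    """Greedy subject-to-fold assignment balancing class proportions.

    Subjects are processed largest-first (ties broken by a seeded shuffle);
    each goes to the fold where the resulting class distribution diverges
    least from the global one, with a size-balance penalty.  Deterministic
    for a fixed seed.
    """
    subjects = np.asarray(subjects)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    uniq = sorted(set(subjects))
    if len(uniq) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(uniq)}")
    counts = {
        s: np.array([np.sum((subjects == s) & (labels == c)) for c in classes], dtype=float)
        for s in uniq
    }
    global_counts = np.array([np.sum(labels == c) for c in classes], dtype=float)
    global_frac = global_counts / global_counts.sum()

    rng = np.random.default_rng(seed)
    order = list(uniq)
    rng.shuffle(order)
    order.sort(key=lambda s: -counts[s].sum())

    fold_counts = [np.zeros(len(classes)) for _ in range(k)]
    fold_sizes = np.zeros(k)
    folds: list[list[str]] = [[] for _ in range(k)]
    target = sum(c.sum() for c in counts.values()) / k
    for si, s in enumerate(order):
        # the first k subjects seed one fold each, so no fold stays empty
        candidates = [f for f in range(k) if not folds[f]] if si < k else range(k)
        best, best_cost = None, np.inf
        for f in candidates:
            cand = fold_counts[f] + counts[s]
            tot = cand.sum()
            frac = cand / tot if tot > 0 else cand
            div = float(np.abs(frac - global_frac).sum())
            size_pen = max(0.0, (fold_sizes[f] + counts[s].sum()) / target - 1.0)
            cost = div + size_pen
            if cost < best_cost - 1e-12:
                best, best_cost = f, cost
        folds[best].append(s)
        fold_counts[best] += counts[s]
        fold_sizes[best] += counts[s].sum()
    return FoldPlan(folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# classifiers


@dataclass
class ClassifierSpec:
    """A classifier family plus the hyperparameter grid searched per fold."""

    family: str = "knn"
    grid: dict[str, list] = field(default_factory=dict)
    seed: int = 0

    DEFAULT_GRIDS = {
        "knn": {"n_neighbors": [3, 5, 7], "metric": ["minkowski", "euclidean", "manhattan"]},
        "svc": {"C": [0.1, 1, 10, 100], "kernel": ["linear", "rbf", "poly", "sigmoid"],
                "gamma": ["scale", "auto"]},
        "cart": {"criterion": ["gini", "entropy"], "splitter": ["best", "random"],
                 "max_depth": list(range(1, 11))},
        "gnb": {},
        # cleaned MLP grid: hidden depth 3-10, standard activations, the
        # printed alpha/momentum sets
        "mlp": {"n_layers": [3, 4, 5], "activation": ["logistic", "tanh", "relu"],
                "alpha": [1e-5, 1e-4, 1e-3, 1e-2, 1e-1],
                "momentum": [0, 0.2, 0.4, 0.6, 0.8]},
    }

    def __post_init__(self) -> None:
        self.family = self.family.lower()
        if self.family not in self.DEFAULT_GRIDS:
            raise ValueError(f"unknown classifier family {self.family!r}")

    def param_grid(self) -> list[dict]:
        grid = self.grid or {}
        keys = list(grid)
        if not keys:
            return [{}]
        out = [{}]
        for key in keys:
            out = [dict(d, **{key: v}) for d in out for v in grid[key]]
        return out

    def build(self, params: dict):
        p = dict(params)
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=p.get("n_neighbors", 3),
                                        metric=p.get("metric", "minkowski"))
        if self.family == "svc":
            return SVC(C=p.get("C", 1.0), kernel=p.get("kernel", "rbf"),
                       gamma=p.get("gamma", "scale"), random_state=self.seed)
        if self.family == "cart":
            return DecisionTreeClassifier(criterion=p.get("criterion", "gini"),
                                          splitter=p.get("splitter", "best"),
                                          max_depth=p.get("max_depth"),
                                          random_state=self.seed)
        if self.family == "gnb":
            return GaussianNB()
        if self.family == "mlp":
            width = p.get("width", 32)
            hidden = tuple([width] * p.get("n_layers", 3))
            return MLPClassifier(hidden_layer_sizes=hidden,
                                 activation=p.get("activation", "tanh"),
                                 alpha=p.get("alpha", 1e-4),
                                 momentum=p.get("momentum", 0.9),
                                 max_iter=p.get("max_iter", 300),
                                 random_state=self.seed)
        raise AssertionError(self.family)


def _fit_predict(spec: ClassifierSpec, params, Xtr, ytr, Xte):
    clf = spec.build(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Xtr, ytr)
        return clf.predict(Xte), getattr(clf, "n_iter_", None)


def cross_validate(
    features: np.ndarray,
    labels,
    subjects,
    spec: ClassifierSpec,
    plan: FoldPlan,
) -> list[MetricsReport]:
    """Per-fold fit/predict with hyperparameters chosen inside the train fold.

    When the grid has more than one point, an inner subject-aware split of
    the training fold selects the combination with the best macro BAC.
    Non-converged fits are flagged in the log, never silently dropped.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    if not len(features) == len(labels) == len(subjects):
        raise ValueError("features, labels and subjects must have equal length")
    reports = []
    for fi, test_subjects in enumerate(plan.folds):
        te = np.isin(subjects, list(test_subjects))
        tr = ~te
        if te.sum() == 0 or tr.sum() == 0:
            raise ValueError(f"fold {fi} leaves an empty train or test split")
        grid = spec.param_grid()
        params = grid[0]
        if len(grid) > 1:
            params = _select_params(features[tr], labels[tr], subjects[tr], spec, grid)
        y_pred, n_iter = _fit_predict(spec, params, features[tr], labels[tr], features[te])
        if spec.family == "mlp" and n_iter is not None and n_iter >= params.get("max_iter", 300):
            logger.warning("fold %d: MLP hit the iteration cap (flagged, kept)", fi)
        reports.append(MetricsReport.from_predictions(labels[te], y_pred))
    return reports


def _select_params(X, y, subj, spec: ClassifierSpec, grid: list[dict]) -> dict:
    inner = make_folds(subj, y, k=min(3, len(set(subj))), seed=spec.seed)
    best, best_score = grid[0], -np.inf
    for params in grid:
        scores = []
        for test_subjects in inner.folds:
            te = np.isin(subj, list(test_subjects))
            if te.sum() == 0 or (~te).sum() == 0:
                continue
            y_pred, _ = _fit_predict(spec, params, X[~te], y[~te], X[te])
            bac = MetricsReport.from_predictions(y[te], y_pred).macro["bac"]
            if bac is not None:
                scores.append(bac)
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score + 1e-12:
            best, best_score = params, score
    return best


# ---------------------------------------------------------------------------
# paired comparison


def wilcoxon_compare(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired score vectors.

    Exact null distribution for n <= 25 pairs, normal approximation above;
    zero differences are dropped (Wilcoxon's convention).  All-identical
    pairs give ``(0.0, 1.0)`` with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must be paired (equal length)")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired scores identical; no evidence either way")
        return 0.0, 1.0
    n_nonzero = int(np.sum(diffs != 0))
    method = "exact" if n_nonzero <= 25 else "approx"
    res = sstats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
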